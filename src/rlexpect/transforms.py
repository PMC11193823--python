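"""Bijections between the unconstrained sampling scale and constrained parameter ranges.

Learning-rate-like parameters live on a logit scale, the inverse gain on a log
scale, and box-bounded parameters (inverse temperature, choice inverse
temperature) on a scaled-logit scale ``lo + (hi - lo) * logistic(x)``.
Every transform is a strictly monotone bijection from the real line onto its
constrained range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit


@dataclass(frozen=True)
class Transform:
    """Monotone bijection R -> (lo, hi) (hi may be inf for the log family)."""

    family: str  # "logit" | "log" | "scaled_logit"
    lo: float
    hi: float

    def constrain(self, x):
        x = np.asarray(x, dtype=float)
        if self.family == "log":
            return np.exp(x)
        if self.family == "logit":
            return expit(x)
        return self.lo + (self.hi - self.lo) * expit(x)

    def unconstrain(self, v):
        v = np.asarray(v, dtype=float)
        if self.family == "log":
            return np.log(v)
        if self.family == "logit":
            return logit(v)
        return logit((v - self.lo) / (self.hi - self.lo))

    @property
    def bounds(self):
        return (self.lo, self.hi)


LOGIT = Transform("logit", 0.0, 1.0)
LOG = Transform("log", 0.0, np.inf)


def scaled_logit(lo: float, hi: float) -> Transform:
    if not hi > lo:
        raise ValueError(f"scaled_logit requires hi > lo, got [{lo}, {hi}]")
    return Transform("scaled_logit", float(lo), float(hi))
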