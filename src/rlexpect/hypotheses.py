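"""Posterior hypothesis statistics over group-level draws.

Two bespoke statistics distinguish the competing hypotheses about how the
purported treatment-efficacy probability moderates a parameter:

* *pattern fractions* — the proportion of posterior draws in which the five
  group-level means satisfy a strict inequality chain (monotonic increase vs.
  an inverted-U peaking at the 50% group), optionally after omitting the 25%
  and 75% conditions;
* *ROPE contrasts* — for each pair of groups the posterior mean difference,
  equal-tailed 95% interval, probability of direction (pd), practical
  significance (ps, mass beyond the ROPE in the median's direction) and the
  percentage of draws inside the region of practical equivalence [-0.1, 0.1].

A quadratic trend regression (centered efficacy coding -50..50) and the
BIC-based Bayes factor complete the surface.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

GROUP_LABELS = (0, 25, 50, 75, 100)


@dataclass(frozen=True)
class PatternSpec:
    """Strict inequality chain over ordered group labels.

    ``directions[i]`` is +1 if the chain requires mu(labels[i]) < mu(labels[i+1])
    and -1 for mu(labels[i]) > mu(labels[i+1]).
    """

    name: str
    labels: tuple
    directions: tuple

    def __post_init__(self):
        if len(self.labels) < 3:
            raise ValueError("a pattern must span at least three groups")
        if len(self.directions) != len(self.labels) - 1:
            raise ValueError("need one direction per adjacent label pair")
        if any(d not in (-1, 1) for d in self.directions):
            raise ValueError("directions must be +1 or -1 (strict inequalities)")


PATTERNS = {
    "monotonic5": PatternSpec("monotonic5", GROUP_LABELS, (1, 1, 1, 1)),
    "inverted_u5": PatternSpec("inverted_u5", GROUP_LABELS, (1, 1, -1, -1)),
    "monotonic3": PatternSpec("monotonic3", (0, 50, 100), (1, 1)),
    "inverted_u3": PatternSpec("inverted_u3", (0, 50, 100), (1, -1)),
}


def resolve_pattern(pattern) -> PatternSpec:
    if isinstance(pattern, PatternSpec):
        return pattern
    try:
        return PATTERNS[pattern]
    except KeyError:
        raise ValueError(
            f"unknown pattern {pattern!r}; presets: {sorted(PATTERNS)}"
        ) from None


def group_level_mean_draws(draws, param: str) -> np.ndarray:
    """(n_draws, 5) group-level means mu + delta_j; baseline column is mu."""
    return draws.group_mean_draws(param)


def pattern_fraction(mu_draws, pattern, group_labels=GROUP_LABELS) -> float:
    """Fraction of draws whose group means satisfy every strict inequality."""
    spec = resolve_pattern(pattern)
    mu_draws = np.asarray(mu_draws, dtype=float)
    if mu_draws.ndim != 2 or mu_draws.shape[1] != len(group_labels):
        raise ValueError(
            f"mu_draws must be (n, {len(group_labels)}) with columns ordered as "
            f"{group_labels}"
        )
    try:
        cols = [group_labels.index(lab) for lab in spec.labels]
    except ValueError:
        raise ValueError(
            f"pattern labels {spec.labels} not all present in {group_labels}"
        ) from None
    ok = np.ones(mu_draws.shape[0], dtype=bool)
    for (a, b), d in zip(zip(cols[:-1], cols[1:]), spec.directions):
        if d == 1:
            ok &= mu_draws[:, a] < mu_draws[:, b]
        else:
            ok &= mu_draws[:, a] > mu_draws[:, b]
    return float(ok.mean())


@dataclass(frozen=True)
class ContrastSummary:
    mean: float
    ci_low: float
    ci_high: float
    pd: float  # probability of direction, in [0.5, 1] for nondegenerate draws
    ps: float  # practical significance (mass beyond the ROPE, median direction)
    pct_rope: float  # percentage of draws inside the ROPE


def contrast_summary(draws_j, draws_k, rope=(-0.1, 0.1)) -> ContrastSummary:
    """Summaries of the posterior difference d = draws_j - draws_k."""
    draws_j = np.asarray(draws_j, dtype=float)
    draws_k = np.asarray(draws_k, dtype=float)
    if draws_j.size == 0 or draws_j.shape != draws_k.shape:
        raise ValueError("draw vectors must be nonempty and equally long")
    d = draws_j - draws_k
    lo, hi = rope
    p_pos = float(np.mean(d > 0))
    p_neg = float(np.mean(d < 0))
    if p_pos == 0.0 and p_neg == 0.0:
        warnings.warn("all differences are exactly zero; pd is undefined")
        pd_val = math.nan
        ps = math.nan
    else:
        pd_val = max(p_pos, p_neg)
        med = float(np.median(d))
        direction = np.sign(med) or np.sign(np.mean(d))
        if direction > 0:
            ps = float(np.mean(d > hi))
        elif direction < 0:
            ps = float(np.mean(d < lo))
        else:
            ps = float(max(np.mean(d > hi), np.mean(d < lo)))
    return ContrastSummary(
        mean=float(d.mean()),
        ci_low=float(np.percentile(d, 2.5)),
        ci_high=float(np.percentile(d, 97.5)),
        pd=pd_val,
        ps=ps,
        pct_rope=float(100.0 * np.mean((d >= lo) & (d <= hi))),
    )


def pairwise_contrasts(mu_draws, rope=(-0.1, 0.1), group_labels=GROUP_LABELS):
    """All 10 pairwise contrasts mu_j - mu_k (j before k in group order)."""
    mu_draws = np.asarray(mu_draws, dtype=float)
    rows = []
    for a in range(len(group_labels)):
        for b in range(a + 1, len(group_labels)):
            c = contrast_summary(mu_draws[:, a], mu_draws[:, b], rope=rope)
            rows.append(
                {
                    "contrast": f"{group_labels[a]}-{group_labels[b]}",
                    "mean": c.mean,
                    "ci_low": c.ci_low,
                    "ci_high": c.ci_high,
                    "pd": c.pd,
                    "ps": c.ps,
                    "pct_rope": c.pct_rope,
                }
            )
    return pd.DataFrame(rows)


def quadratic_trend(y, group_percent) -> dict:
    """OLS of y on centered efficacy and its square; nested-model delta R^2.

    Groups {0, 25, 50, 75, 100} are coded as centered values {-50..50}.
    Returns b_linear and b_quadratic from the full model, the linear-only and
    full R^2, and their difference.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    g = np.asarray(group_percent, dtype=float)
    if y.shape != g.shape or y.ndim != 1:
        raise ValueError("y and group_percent must be equally long 1-d arrays")
    x = g - 50.0
    if np.ptp(y) == 0.0:
        return {
            "b_linear": 0.0,
            "b_quadratic": 0.0,
            "r2_linear": 0.0,
            "r2_full": 0.0,
            "delta_r2": 0.0,
        }
    if len(np.unique(x)) < 3:
        raise ValueError("the quadratic term requires at least 3 distinct groups")
    lin = sm.OLS(y, sm.add_constant(x)).fit()
    full = sm.OLS(y, sm.add_constant(np.column_stack([x, x**2]))).fit()
    return {
        "b_linear": float(full.params[1]),
        "b_quadratic": float(full.params[2]),
        "r2_linear": float(lin.rsquared),
        "r2_full": float(full.rsquared),
        "delta_r2": float(full.rsquared - lin.rsquared),
    }


def bic_bayes_factor(bic_null, bic_alt, orientation: str = "conventional") -> float:
    """BIC-approximated Bayes factor BF10.

    The conventional orientation is exp((BIC_null - BIC_alt) / 2), so values
    above 1 favor the alternative; ``orientation="as_printed"`` flips the sign
    of the exponent to match the alternative convention occasionally printed
    in reports.
    """
    if not (np.isfinite(bic_null) and np.isfinite(bic_alt)):
        raise ValueError("BIC values must be finite")
    if orientation == "conventional":
        return float(np.exp((bic_null - bic_alt) / 2.0))
    if orientation == "as_printed":
        return float(np.exp((bic_alt - bic_null) / 2.0))
    raise ValueError(f"unknown orientation {orientation!r}")


def hypothesis_report(draws, params=None, rope=(-0.1, 0.1)) -> dict:
    """JSON-able report: pattern fractions (four presets) and the 10 contrasts."""
    if params is None:
        params = list(draws.param_names)
    report = {}
    for param in params:
        mu_draws = draws.group_mean_draws(param)
        report[param] = {
            "pattern_fractions": {
                name: pattern_fraction(mu_draws, spec)
                for name, spec in PATTERNS.items()
            },
            "contrasts": pairwise_contrasts(mu_draws, rope=rope).to_dict(
                orient="records"
            ),
        }
    return report
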