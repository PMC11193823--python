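"""Fast per-subject maximum-likelihood estimation.

Used as the light-weight fitting path for parameter-recovery studies and
tests.  Optimization is multi-start Nelder–Mead on the unconstrained scale,
so the family's parameter bounds are enforced by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .agents import pack_trials, trialwise_logprob
from .families import get_family
from .params import params_from_array
from .task import TaskDesign, default_design
from .transforms import scaled_logit


@dataclass
class MLEResult:
    model_id: str
    params: object  # constrained container
    x: np.ndarray  # unconstrained optimum
    loglik: float
    n_trials: int


def _transforms_for(fam, bounds):
    if bounds is None:
        return fam.transforms
    out = []
    for name, tr in zip(fam.param_names, fam.transforms):
        if name in bounds:
            lo, hi = bounds[name]
            lo = max(lo, tr.lo)
            hi = min(hi, tr.hi)
            if not np.isfinite(hi):
                raise ValueError(f"bounds for {name} must be finite")
            out.append(scaled_logit(lo, hi))
        else:
            out.append(tr)
    return tuple(out)


def fit_mle(
    trials: pd.DataFrame,
    model_id: str,
    bounds: dict | None = None,
    design: TaskDesign | None = None,
    n_starts: int = 4,
    seed: int = 0,
    maxiter: int = 2000,
) -> MLEResult:
    """Maximize one subject's sequence likelihood within the parameter bounds.

    ``bounds`` optionally narrows a parameter's range as {name: (lo, hi)}.
    Multi-start (origin plus ``n_starts - 1`` random starts) guards against
    local optima; flat likelihood directions (e.g. a single trial) simply
    leave the corresponding parameter near its starting point.
    """
    if trials is None or len(trials) == 0:
        raise ValueError("fit_mle requires at least one trial")
    fam = get_family(model_id)
    if design is None:
        design = default_design()
    trials = trials.copy()
    if "subject_id" not in trials.columns:
        trials["subject_id"] = 0
    if trials["subject_id"].nunique() > 1:
        raise ValueError("fit_mle fits a single subject; got several subject_ids")
    packed = pack_trials(trials, design)
    transforms = _transforms_for(fam, bounds)

    def constrain(x):
        return np.array([tr.constrain(v) for tr, v in zip(transforms, x)])

    def negloglik(x):
        theta = constrain(x)
        return -float(trialwise_logprob(packed, theta, model_id).sum())

    rng = np.random.default_rng(seed)
    starts = [np.zeros(fam.n_params)]
    starts += [rng.normal(0.0, 1.0, size=fam.n_params) for _ in range(n_starts - 1)]

    best_x, best_val = None, np.inf
    for x0 in starts:
        res = minimize(
            negloglik,
            x0,
            method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-6},
        )
        if res.fun < best_val:
            best_val, best_x = res.fun, res.x
    return MLEResult(
        model_id=model_id,
        params=params_from_array(model_id, constrain(best_x)),
        x=np.asarray(best_x, dtype=float),
        loglik=-best_val,
        n_trials=packed.n_trials,
    )
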