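"""Model evaluation: accuracy, posterior predictive simulation, PSIS-LOO,
and parameter recovery."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .agents import pack_trials, simulate_choices, trialwise_logprob
from .families import get_family
from .params import params_to_array
from .task import TaskDesign, build_schedule, default_design


def _theta_matrix(packed, subject_params, model_id):
    """Align per-subject constrained parameters with the packed subject order."""
    fam = get_family(model_id)
    if isinstance(subject_params, pd.DataFrame):
        lookup = subject_params.set_index("subject_id")
        theta = np.empty((packed.n_subjects, fam.n_params))
        for s, sid in enumerate(packed.subject_ids):
            if sid not in lookup.index:
                raise ValueError(f"no parameters supplied for subject {sid}")
            theta[s] = [float(lookup.loc[sid, name]) for name in fam.param_names]
        return theta
    if isinstance(subject_params, dict):
        theta = np.empty((packed.n_subjects, fam.n_params))
        for s, sid in enumerate(packed.subject_ids):
            if sid not in subject_params:
                raise ValueError(f"no parameters supplied for subject {sid!r}")
            theta[s] = params_to_array(model_id, subject_params[sid])
        return theta
    raise TypeError("subject_params must be a DataFrame or a {subject_id: params} dict")


def model_accuracy(dataset, subject_params, model_id, design=None) -> float:
    """Mean model likelihood assigned to the observed choices.

    Evaluated at per-subject point parameters (canonically the subject
    posterior means); chance level for a two-option task is 0.5.
    """
    if design is None:
        design = default_design()
    packed = pack_trials(dataset, design)
    theta = _theta_matrix(packed, subject_params, model_id)
    lp = trialwise_logprob(packed, theta, model_id)
    return float(np.exp(lp[packed.valid]).mean())


@dataclass
class PredictiveResult:
    """Posterior predictive simulations and trial-wise optimal-choice curves."""

    tables: list  # one simulated TrialTable per repeat
    curve: pd.DataFrame  # within-pair trial index -> mean optimal-choice rate
    repeats: int


def posterior_predictive(
    dataset,
    subject_params,
    model_id,
    repeats: int = 20,
    seed=None,
    design: TaskDesign | None = None,
) -> PredictiveResult:
    """Re-simulate every subject's choices ``repeats`` times on fresh schedules.

    The repetition compensates for the uniform-threshold sampling (plus the
    fair-coin rule at exact probability ties) in the choice simulation.
    Per within-pair trial index the mean optimal-choice rate is averaged over
    subjects and repeats.  Deterministic given the seed.
    """
    if repeats < 1:
        raise ValueError("repeats must be at least 1")
    if design is None:
        design = default_design()
    packed = pack_trials(dataset, design)
    theta = _theta_matrix(packed, subject_params, model_id)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    tables = []
    curves = []
    for rep_seed in ss.spawn(repeats):
        rng = np.random.default_rng(rep_seed)
        per_subject = []
        for s, sid in enumerate(packed.subject_ids):
            schedule = build_schedule(design, rng)
            sim = simulate_choices(theta[s], schedule, design, model_id, rng)
            sim.insert(0, "subject_id", sid)
            sim.insert(1, "group", int(packed.groups[s]))
            per_subject.append(sim)
        table = pd.concat(per_subject, ignore_index=True)
        tables.append(table)
        table = table.sort_values(["subject_id", "trial"])
        table["pair_trial"] = table.groupby(["subject_id", "pair"]).cumcount() + 1
        curves.append(table.groupby("pair_trial")["optimal"].mean())
    curve = pd.concat(curves, axis=1).mean(axis=1).rename("optimal_rate").reset_index()
    return PredictiveResult(tables=tables, curve=curve, repeats=repeats)


def pointwise_loglik(draws, dataset, model_id, design=None, thin: int = 1) -> np.ndarray:
    """(n_draws, n_trials) log choice probabilities across retained draws.

    Rows follow chain-major draw order; columns follow subject-major trial
    order.  Row sums equal the per-draw total sequence log likelihood.
    """
    if draws.subject_x is None:
        raise ValueError("draws were collected without subject-level values")
    if design is None:
        design = default_design()
    packed = pack_trials(dataset, design)
    fam = get_family(model_id)
    order = {sid: i for i, sid in enumerate(draws.subject_ids)}
    try:
        sel = np.array([order[sid] for sid in packed.subject_ids])
    except KeyError as err:
        raise ValueError(f"draws do not cover subject {err.args[0]!r}") from None
    flat = draws.subject_x.reshape(-1, len(draws.subject_ids), fam.n_params)[::thin]
    out = np.empty((flat.shape[0], packed.n_trials))
    mask = packed.valid
    for d in range(flat.shape[0]):
        lp = trialwise_logprob(packed, fam.constrain(flat[d][sel]), model_id)
        out[d] = lp[mask]
    return out


@dataclass
class LOOResult:
    elpd_loo: float
    se: float
    looic: float
    pareto_k: np.ndarray = field(repr=False)
    n_high_k: int = 0

    def __post_init__(self):
        if self.n_high_k:
            warnings.warn(
                f"{self.n_high_k} observation(s) with Pareto k > 0.7; "
                "the PSIS-LOO estimate may be unreliable",
                RuntimeWarning,
            )


def psis_loo(loglik_matrix, n_chains: int = 1) -> LOOResult:
    """Pareto-smoothed importance-sampling leave-one-out estimate.

    ``loglik_matrix`` is (n_draws, n_observations); looic = -2 * elpd_loo by
    construction.  With a single draw the importance weights are degenerate
    and the pointwise elpd reduces to the entries themselves.
    """
    import arviz as az

    mat = np.asarray(loglik_matrix, dtype=float)
    if mat.ndim != 2 or mat.size == 0:
        raise ValueError("loglik_matrix must be a nonempty 2-d array")
    if not np.all(np.isfinite(mat)):
        raise ValueError("loglik_matrix contains non-finite entries")
    n_draws, n_obs = mat.shape
    if n_draws < 2:
        pointwise = mat[0]
        elpd = float(pointwise.sum())
        se = float(np.sqrt(n_obs * pointwise.var(ddof=0))) if n_obs > 1 else 0.0
        return LOOResult(elpd, se, -2.0 * elpd, np.zeros(n_obs), 0)
    if n_draws % n_chains:
        n_chains = 1
    arr = mat.reshape(n_chains, n_draws // n_chains, n_obs)
    # a (trivial) posterior group is required by az.loo's bookkeeping
    idata = az.from_dict(
        posterior={"_draw_index": np.zeros(arr.shape[:2])},
        log_likelihood={"obs": arr},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = az.loo(idata, pointwise=True)
    k = np.asarray(res.pareto_k)
    return LOOResult(
        elpd_loo=float(res.elpd_loo),
        se=float(res.se),
        looic=float(-2.0 * res.elpd_loo),
        pareto_k=k,
        n_high_k=int(np.sum(k > 0.7)),
    )


@dataclass
class RecoveryResult:
    """Rank correlations between fitted and generative parameters."""

    per_parameter: dict  # name -> Spearman rho (NaN if truth is constant)
    mean_correlation: float
    fitted: pd.DataFrame = field(repr=False, default=None)


def parameter_recovery(
    model_id: str,
    truth,
    design: TaskDesign | None = None,
    fit_method: str = "mle",
    seed=None,
    sampler_config=None,
) -> RecoveryResult:
    """Simulate agents from known parameters, refit, and rank-correlate.

    ``truth`` is a cohort (list of SubjectTruth).  ``fit_method`` "mle" refits
    each agent independently; "hierarchical" fits the full hierarchy and uses
    subject posterior means.
    """
    from .cohort import simulate_cohort, truth_table

    if design is None:
        design = default_design()
    fam = get_family(model_id)
    truths = truth_table(truth, model_id)
    if len(truths) < 2:
        raise ValueError("recovery needs at least two agents")
    ss = np.random.SeedSequence(seed)
    sim_seed, fit_seed = ss.spawn(2)
    table = simulate_cohort(truth, design, seed=sim_seed, model_id=model_id)

    if fit_method == "mle":
        from .mle import fit_mle

        rows = []
        for sid, sub in table.groupby("subject_id", sort=False):
            res = fit_mle(sub, model_id, design=design, seed=int(fit_seed.generate_state(1)[0] % (2**31)))
            row = {"subject_id": sid}
            row.update({name: getattr(res.params, name) for name in fam.param_names})
            rows.append(row)
        fitted = pd.DataFrame(rows)
    elif fit_method == "hierarchical":
        from .hierarchical import HierarchicalRLModel
        from .priors import SamplerConfig

        cfg = sampler_config or SamplerConfig.test(
            seed=int(fit_seed.generate_state(1)[0] % (2**31))
        )
        res = HierarchicalRLModel(table, model_id=model_id).fit(config=cfg)
        fitted = res.subject_means()[["subject_id"] + list(fam.param_names)]
    else:
        raise ValueError(f"unknown fit_method {fit_method!r}")

    merged = truths.merge(fitted, on="subject_id", suffixes=("_true", "_fit"))
    per_param = {}
    for name in fam.param_names:
        t = merged[f"{name}_true"].to_numpy()
        f = merged[f"{name}_fit"].to_numpy()
        if np.ptp(t) == 0.0:
            per_param[name] = float("nan")
            continue
        rho = spearmanr(t, f).statistic
        per_param[name] = float(rho)
    finite = [v for v in per_param.values() if np.isfinite(v)]
    return RecoveryResult(
        per_parameter=per_param,
        mean_correlation=float(np.mean(finite)) if finite else float("nan"),
        fitted=fitted,
    )
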