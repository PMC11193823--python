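"""Hierarchical Bayesian estimation of the group-structured Q-learning models.

The statistical model: each subject s in efficacy group j has unconstrained
parameters x_s ~ Normal(mu + delta_j, sigma) componentwise (delta_0 = 0 for
the baseline group), and the subject's choices enter through the model
family's sequence likelihood at the constrained parameters.

Posterior sampling uses Metropolis-within-Gibbs: group-level means mu and
offsets delta have conjugate normal full conditionals given the subject
values, group spreads sigma are updated by univariate slice sampling on the
log scale, and the subject-level block is refreshed several times per sweep
with an adaptive vectorized random-walk Metropolis step (scales adapted
during warmup only, so the retained chain is a valid Markov chain).

The module is organized statsmodels-style: build a :class:`HierarchicalRLModel`
from a trial table, call ``fit()`` and work with the returned
:class:`HierarchicalRLResults`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agents import PackedTrials, pack_trials, trialwise_logprob
from .cohort import GROUP_LABELS
from .families import ModelFamily, get_family
from .priors import PriorConfig, SamplerConfig
from .task import TaskDesign, default_design

OFFSET_LABELS = (25, 50, 75, 100)


# ---------------------------------------------------------------------------
# group-level state and joint density
# ---------------------------------------------------------------------------

@dataclass
class GroupLevelState:
    """Hyperparameters per model parameter: baseline mean, offsets, spread."""

    mu: np.ndarray  # (k,)
    delta: np.ndarray  # (k, 4) for groups 25/50/75/100; baseline offset is 0
    sigma: np.ndarray  # (k,)

    def group_mean(self, p: int, group: int) -> float:
        if group == 0:
            return float(self.mu[p])
        return float(self.mu[p] + self.delta[p, OFFSET_LABELS.index(group)])


def _group_offsets(delta: np.ndarray, gidx: np.ndarray) -> np.ndarray:
    """Per-subject offset vectors; gidx indexes GROUP_LABELS (0 = baseline)."""
    idx = np.clip(gidx - 1, 0, 3)
    off = delta.T[idx]  # (n, k)
    off[gidx == 0] = 0.0
    return off


def log_joint(
    dataset: pd.DataFrame,
    group_state: GroupLevelState,
    subject_x,
    priors: PriorConfig,
    model_id: str,
    design: TaskDesign | None = None,
) -> float:
    """Joint log density of hyperparameters, subject parameters and choices.

    ``subject_x`` maps subject_id -> unconstrained vector (or is an (n, k)
    array aligned with the dataset's subject order).  An empty dataset leaves
    only the hyperprior terms.
    """
    fam = get_family(model_id)
    k = fam.n_params
    if group_state.mu.shape != (k,) or group_state.sigma.shape != (k,):
        raise ValueError("group state dimensions do not match the model family")
    if np.any(group_state.sigma <= 0):
        return -np.inf

    total = 0.0
    for p in range(k):
        total += priors.mu_logpdf(group_state.mu[p])
        total += priors.sigma_logpdf(group_state.sigma[p])
        for j in range(group_state.delta.shape[1]):
            total += priors.delta_logpdf(group_state.delta[p, j])

    if dataset is None or len(dataset) == 0:
        return float(total)

    if design is None:
        design = default_design()
    packed = pack_trials(dataset, design)
    n = packed.n_subjects
    if isinstance(subject_x, dict):
        x = np.stack([np.asarray(subject_x[s], dtype=float) for s in packed.subject_ids])
    else:
        x = np.asarray(subject_x, dtype=float)
    if x.shape != (n, k):
        raise ValueError(f"subject_x shape {x.shape} does not match ({n}, {k})")

    gidx = np.array([GROUP_LABELS.index(g) for g in packed.groups])
    m = group_state.mu[None, :] + _group_offsets(group_state.delta, gidx)
    sd = group_state.sigma[None, :]
    total += float(
        np.sum(-0.5 * ((x - m) / sd) ** 2 - np.log(sd) - 0.5 * np.log(2 * np.pi))
    )
    total += float(trialwise_logprob(packed, fam.constrain(x), model_id).sum())
    return float(total)


# ---------------------------------------------------------------------------
# posterior draws container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Retained MCMC draws indexed (chain, iteration) plus metadata."""

    model_id: str
    param_names: tuple
    mu: np.ndarray  # (chains, draws, k)
    delta: np.ndarray  # (chains, draws, k, 4)
    sigma: np.ndarray  # (chains, draws, k)
    subject_x: np.ndarray | None  # (chains, draws, n, k) or None
    subject_ids: np.ndarray
    subject_groups: np.ndarray
    prior_variant: str
    seed: int | None
    sampler: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.mu.shape[0]

    @property
    def n_draws_per_chain(self) -> int:
        return self.mu.shape[1]

    @property
    def n_retained(self) -> int:
        return self.n_chains * self.n_draws_per_chain

    def group_level_dict(self) -> dict:
        """Flat name -> (chains, draws) mapping of all group-level draws."""
        out = {}
        for p, name in enumerate(self.param_names):
            out[f"mu[{name}]"] = self.mu[:, :, p]
            for j, lab in enumerate(OFFSET_LABELS):
                out[f"delta[{name},{lab}]"] = self.delta[:, :, p, j]
            out[f"sigma[{name}]"] = self.sigma[:, :, p]
        return out

    def group_mean_draws(self, param: str) -> np.ndarray:
        """(n_retained, 5) draws of mu + delta_j for groups 0..100.

        The baseline column equals the mu draws exactly.
        """
        if param not in self.param_names:
            raise ValueError(f"unknown parameter {param!r}; have {self.param_names}")
        p = self.param_names.index(param)
        mu = self.mu[:, :, p].reshape(-1)
        cols = [mu]
        for j in range(4):
            cols.append(mu + self.delta[:, :, p, j].reshape(-1))
        return np.column_stack(cols)

    def to_arviz(self):
        import arviz as az

        return az.from_dict(posterior=self.group_level_dict())

    def to_long_dataframe(self, include_subjects: bool = True) -> pd.DataFrame:
        rows = []
        for name, arr in self.group_level_dict().items():
            c, d = np.meshgrid(
                np.arange(arr.shape[0]), np.arange(arr.shape[1]), indexing="ij"
            )
            rows.append(
                pd.DataFrame(
                    {
                        "chain": c.ravel(),
                        "iteration": d.ravel(),
                        "parameter": name,
                        "value": arr.ravel(),
                    }
                )
            )
        if include_subjects and self.subject_x is not None:
            C, D, n, k = self.subject_x.shape
            for s in range(n):
                sid = self.subject_ids[s]
                for p, pname in enumerate(self.param_names):
                    arr = self.subject_x[:, :, s, p]
                    c, d = np.meshgrid(np.arange(C), np.arange(D), indexing="ij")
                    rows.append(
                        pd.DataFrame(
                            {
                                "chain": c.ravel(),
                                "iteration": d.ravel(),
                                "parameter": f"x[{pname},{sid}]",
                                "value": arr.ravel(),
                            }
                        )
                    )
        return pd.concat(rows, ignore_index=True)

    def save(self, prefix: str, include_subjects: bool = True) -> None:
        """Persist as long CSV (chain, iteration, parameter, value) + JSON sidecar."""
        self.to_long_dataframe(include_subjects).to_csv(f"{prefix}.csv", index=False)
        meta = {
            "model_id": self.model_id,
            "param_names": list(self.param_names),
            "prior_variant": self.prior_variant,
            "seed": self.seed,
            "sampler": self.sampler,
            "diagnostics": self.diagnostics,
            "subject_ids": [str(s) for s in self.subject_ids],
            "subject_groups": [int(g) for g in self.subject_groups],
            "n_chains": self.n_chains,
            "n_draws_per_chain": self.n_draws_per_chain,
        }
        with open(f"{prefix}.json", "w") as fh:
            json.dump(meta, fh, indent=2)


# ---------------------------------------------------------------------------
# sampler internals
# ---------------------------------------------------------------------------

def _slice_sample_log_sigma(u0, logpost, rng, w=1.0, max_steps=40):
    """Univariate slice sampling (stepping-out) on u = log(sigma)."""
    y = logpost(u0) - rng.exponential()
    left = u0 - w * rng.random()
    right = left + w
    for _ in range(max_steps):
        if logpost(left) <= y:
            break
        left -= w
    for _ in range(max_steps):
        if logpost(right) <= y:
            break
        right += w
    for _ in range(200):
        u = rng.uniform(left, right)
        if logpost(u) > y:
            return u
        if u < u0:
            left = u
        else:
            right = u
    return u0  # numerically stuck; keep the current value


def _run_chain(
    packed: PackedTrials | None,
    fam: ModelFamily,
    model_id: str,
    priors: PriorConfig,
    cfg: SamplerConfig,
    rng: np.random.Generator,
    keep_subject_draws: bool,
):
    k = fam.n_params
    n = packed.n_subjects if packed is not None else 0
    n_total = cfg.n_warmup + cfg.n_sampling

    mu = rng.normal(0.0, 0.1, size=k)
    delta = np.zeros((k, 4))
    sigma = np.ones(k)
    if n:
        gidx = np.array([GROUP_LABELS.index(g) for g in packed.groups])
        x = 0.1 * rng.standard_normal((n, k))
        theta = fam.constrain(x)
        ll = trialwise_logprob(packed, theta, model_id).sum(axis=1)
        scale = np.full(n, 0.3)
    else:
        gidx = np.zeros(0, dtype=int)
        x = np.zeros((0, k))
        ll = np.zeros(0)
        scale = np.zeros(0)

    mu_out = np.empty((cfg.n_sampling, k))
    delta_out = np.empty((cfg.n_sampling, k, 4))
    sigma_out = np.empty((cfg.n_sampling, k))
    x_out = np.empty((cfg.n_sampling, n, k)) if keep_subject_draws else None

    t_adapt = 0
    log2pi = np.log(2 * np.pi)
    group_masks = [gidx == j + 1 for j in range(4)]
    group_sizes = [int(m.sum()) for m in group_masks]
    for it in range(n_total):
        warm = it < cfg.n_warmup

        # One sweep interleaves several full Gibbs cycles: hyper updates are
        # cheap relative to the likelihood pass of the subject block, and
        # interleaving them decorrelates the retained group-level draws.
        for _ in range(max(cfg.n_subject_refresh, 1)):
            # --- subject-level adaptive random-walk Metropolis refresh
            if n:
                off = _group_offsets(delta, gidx)
                prop = x + scale[:, None] * rng.standard_normal((n, k))
                llp = trialwise_logprob(packed, fam.constrain(prop), model_id).sum(axis=1)
                m = mu[None, :] + off
                lp_cur = (-0.5 * ((x - m) / sigma[None, :]) ** 2).sum(axis=1)
                lp_prop = (-0.5 * ((prop - m) / sigma[None, :]) ** 2).sum(axis=1)
                accept = np.log(rng.random(n)) < (llp - ll) + (lp_prop - lp_cur)
                x[accept] = prop[accept]
                ll[accept] = llp[accept]
                if warm:
                    t_adapt += 1
                    eta = min(0.25, 3.0 / np.sqrt(t_adapt))
                    scale *= np.exp(eta * (accept.astype(float) - cfg.mh_target_accept))

            # --- conjugate updates of mu and delta, slice update of sigma
            for p in range(k):
                var_p = sigma[p] ** 2
                if n:
                    off_p = _group_offsets(delta, gidx)[:, p]
                    prec = 1.0 / priors.mu_sd**2 + n / var_p
                    mean = ((x[:, p] - off_p).sum() / var_p) / prec
                else:
                    prec = 1.0 / priors.mu_sd**2
                    mean = 0.0
                mu[p] = rng.normal(mean, 1.0 / np.sqrt(prec))

                for j in range(4):
                    nj = group_sizes[j]
                    prec = 1.0 / priors.delta_sd**2 + nj / var_p
                    mean = (
                        ((x[group_masks[j], p] - mu[p]).sum() / var_p) / prec
                        if nj
                        else 0.0
                    )
                    delta[p, j] = rng.normal(mean, 1.0 / np.sqrt(prec))

                if n:
                    dev = x[:, p] - (mu[p] + _group_offsets(delta, gidx)[:, p])
                    ssq = float(np.dot(dev, dev))
                else:
                    ssq = 0.0

                def logpost(u, ssq=ssq, n=n):
                    s = np.exp(u)
                    lp = priors.sigma_logpdf(s)
                    if not np.isfinite(lp):
                        return -np.inf
                    if n:
                        lp += -n * (u + 0.5 * log2pi) - 0.5 * ssq / s**2
                    return lp + u  # log-scale Jacobian

                sigma[p] = np.exp(
                    _slice_sample_log_sigma(float(np.log(sigma[p])), logpost, rng)
                )

        if not warm:
            d = it - cfg.n_warmup
            mu_out[d] = mu
            delta_out[d] = delta
            sigma_out[d] = sigma
            if keep_subject_draws:
                x_out[d] = x
    return mu_out, delta_out, sigma_out, x_out


def sample_posterior(
    dataset: pd.DataFrame,
    model_id: str,
    priors: PriorConfig | None = None,
    config: SamplerConfig | None = None,
    design: TaskDesign | None = None,
    keep_subject_draws: bool = True,
) -> PosteriorDraws:
    """Draw from the hierarchical posterior (or the prior if dataset is empty)."""
    fam = get_family(model_id)
    if priors is None:
        priors = PriorConfig.from_variant(fam.default_prior_variant)
    if config is None:
        config = SamplerConfig.test()
    if design is None:
        design = default_design()

    if dataset is not None and len(dataset):
        packed = pack_trials(dataset, design)
        subject_ids = packed.subject_ids
        subject_groups = packed.groups
    else:
        packed = None
        subject_ids = np.array([], dtype=object)
        subject_groups = np.array([], dtype=int)

    ss = np.random.SeedSequence(config.seed)
    chains = []
    for child in ss.spawn(config.n_chains):
        rng = np.random.default_rng(child)
        chains.append(
            _run_chain(packed, fam, model_id, priors, config, rng, keep_subject_draws)
        )
    mu = np.stack([c[0] for c in chains])
    delta = np.stack([c[1] for c in chains])
    sigma = np.stack([c[2] for c in chains])
    subject_x = np.stack([c[3] for c in chains]) if keep_subject_draws else None

    draws = PosteriorDraws(
        model_id=model_id,
        param_names=fam.param_names,
        mu=mu,
        delta=delta,
        sigma=sigma,
        subject_x=subject_x,
        subject_ids=subject_ids,
        subject_groups=subject_groups,
        prior_variant=priors.variant,
        seed=config.seed,
        sampler={
            "n_chains": config.n_chains,
            "n_warmup": config.n_warmup,
            "n_sampling": config.n_sampling,
            "scale": config.scale,
            "n_subject_refresh": config.n_subject_refresh,
        },
    )
    draws.diagnostics = convergence_diagnostics(draws)
    bad = draws.diagnostics.get("non_converged", [])
    if bad:
        warnings.warn(
            f"split R-hat exceeds 1.1 for {bad}; treat the posterior with caution",
            RuntimeWarning,
        )
    return draws


def convergence_diagnostics(draws: PosteriorDraws) -> dict:
    """Split R-hat and effective sample size for all group-level parameters."""
    import arviz as az

    result: dict = {"per_parameter": {}, "non_converged": []}
    if draws.n_chains < 2:
        warnings.warn("R-hat requires at least two chains; reporting ESS only")
    for name, arr in draws.group_level_dict().items():
        entry = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if draws.n_chains >= 2:
                entry["rhat"] = float(az.rhat(np.asarray(arr)))
            else:
                entry["rhat"] = None
            entry["ess_bulk"] = float(az.ess(np.asarray(arr)))
        result["per_parameter"][name] = entry
        if entry["rhat"] is not None and entry["rhat"] > 1.1:
            result["non_converged"].append(name)
    return result


def subject_posterior_means(
    draws: PosteriorDraws, model_id: str | None = None
) -> pd.DataFrame:
    """Per-subject posterior means on the unconstrained and constrained scales.

    For each parameter three columns are reported: ``x_<name>`` (mean of the
    unconstrained draws), ``<name>_mean_of_transform`` (mean of transformed
    draws) and ``<name>`` (transform of the unconstrained mean; the canonical
    constrained point estimate).
    """
    if draws.subject_x is None:
        raise ValueError("draws were collected without subject-level values")
    if draws.subject_x.size == 0:
        raise ValueError("no subject-level draws present")
    fam = get_family(model_id or draws.model_id)
    flat = draws.subject_x.reshape(-1, *draws.subject_x.shape[2:])  # (D, n, k)
    x_mean = flat.mean(axis=0)  # (n, k)
    transform_mean = fam.constrain(flat).mean(axis=0)
    rows = []
    for s, sid in enumerate(draws.subject_ids):
        row = {"subject_id": sid, "group": int(draws.subject_groups[s])}
        for p, name in enumerate(fam.param_names):
            row[f"x_{name}"] = x_mean[s, p]
            row[f"{name}_mean_of_transform"] = transform_mean[s, p]
            row[name] = float(fam.transforms[p].constrain(x_mean[s, p]))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model / results front door
# ---------------------------------------------------------------------------

class HierarchicalRLModel:
    """Hierarchical Q-learning model bound to a long-format trial table.

    Parameters
    ----------
    trials : DataFrame with columns subject_id, group, trial, pair, choice,
        reward (rt_ms optional).
    model_id : one of "SWo", "SSo", "SSh", "SWh", "ES", "RLfCK".
    priors : PriorConfig, defaults to the family's canonical variant
        (wide for SWo/SWh, narrow for SSo/SSh/ES/RLfCK).
    design : TaskDesign, defaults to the three-pair 80/70/60 design.
    """

    def __init__(self, trials, model_id="SWo", priors=None, design=None):
        self.model_id = model_id
        self.family = get_family(model_id)
        self.design = design or default_design()
        self.priors = priors or PriorConfig.from_variant(
            self.family.default_prior_variant
        )
        self.trials = trials
        if trials is not None and len(trials):
            pack_trials(trials, self.design)  # validate eagerly

    @classmethod
    def from_csv(cls, path, **kwargs) -> "HierarchicalRLModel":
        from .io import read_trial_table

        return cls(read_trial_table(path), **kwargs)

    def loglike(self, group_state: GroupLevelState, subject_x) -> float:
        return log_joint(
            self.trials, group_state, subject_x, self.priors, self.model_id, self.design
        )

    def fit(
        self,
        config: SamplerConfig | None = None,
        scale: str = "test",
        seed: int | None = None,
        keep_subject_draws: bool = True,
    ) -> "HierarchicalRLResults":
        if config is None:
            config = SamplerConfig.preset(scale, seed=seed)
        elif seed is not None:
            from dataclasses import replace

            config = replace(config, seed=seed)
        draws = sample_posterior(
            self.trials,
            self.model_id,
            priors=self.priors,
            config=config,
            design=self.design,
            keep_subject_draws=keep_subject_draws,
        )
        return HierarchicalRLResults(self, draws)


class HierarchicalRLResults:
    """Posterior draws plus the derived summaries of a hierarchical fit."""

    def __init__(self, model: HierarchicalRLModel, draws: PosteriorDraws):
        self.model = model
        self.draws = draws

    @property
    def diagnostics(self) -> dict:
        return self.draws.diagnostics

    def summary(self) -> pd.DataFrame:
        """Posterior mean, sd, equal-tailed 95% interval, R-hat and ESS."""
        rows = []
        diag = self.draws.diagnostics.get("per_parameter", {})
        for name, arr in self.draws.group_level_dict().items():
            flat = arr.reshape(-1)
            entry = diag.get(name, {})
            rows.append(
                {
                    "parameter": name,
                    "mean": flat.mean(),
                    "sd": flat.std(ddof=1),
                    "ci_2.5%": np.percentile(flat, 2.5),
                    "ci_97.5%": np.percentile(flat, 97.5),
                    "rhat": entry.get("rhat"),
                    "ess_bulk": entry.get("ess_bulk"),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def group_mean_draws(self, param: str) -> np.ndarray:
        return self.draws.group_mean_draws(param)

    def pattern_fraction(self, param: str, pattern) -> float:
        from .hypotheses import pattern_fraction, resolve_pattern

        return pattern_fraction(self.group_mean_draws(param), resolve_pattern(pattern))

    def contrasts(self, param: str, rope=(-0.1, 0.1)) -> pd.DataFrame:
        from .hypotheses import pairwise_contrasts

        return pairwise_contrasts(self.group_mean_draws(param), rope=rope)

    def subject_means(self) -> pd.DataFrame:
        return subject_posterior_means(self.draws)

    def model_accuracy(self) -> float:
        from .evaluation import model_accuracy

        return model_accuracy(
            self.model.trials,
            self.subject_means(),
            self.model.model_id,
            design=self.model.design,
        )

    def loo(self, thin: int = 1):
        from .evaluation import pointwise_loglik, psis_loo

        mat = pointwise_loglik(
            self.draws, self.model.trials, self.model.model_id, self.model.design, thin=thin
        )
        return psis_loo(mat, n_chains=self.draws.n_chains)

    def posterior_predictive(self, repeats: int = 20, seed=None):
        from .evaluation import posterior_predictive

        return posterior_predictive(
            self.model.trials,
            self.subject_means(),
            self.model.model_id,
            repeats=repeats,
            seed=seed,
            design=self.model.design,
        )

    def save(self, prefix: str) -> None:
        self.draws.save(prefix)
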