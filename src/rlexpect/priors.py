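"""Hierarchical prior variants and sampler configuration.

The hierarchy places five separate group-level distributions on each model
parameter's unconstrained scale:

    x_subject ~ Normal(mu_theta0 + delta_thetaj, sigma_theta),   delta_theta0 = 0

with hyperpriors mu ~ Normal(0, 100), sigma ~ Uniform(0, 100), delta ~
Normal(0, 3) under the *wide* variant, and mu ~ Normal(0, 1), sigma ~
half-Normal(0, 0.2) under the *narrow* variant (the delta prior is unchanged).
Normal distributions are parameterized by standard deviation throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def _normal_logpdf(x, sd):
    return -0.5 * (x / sd) ** 2 - math.log(sd) - _LOG_SQRT_2PI


@dataclass(frozen=True)
class PriorConfig:
    variant: str
    mu_sd: float
    sigma_prior: tuple  # ("uniform", hi) or ("halfnormal", sd)
    delta_sd: float = 3.0

    @classmethod
    def wide(cls) -> "PriorConfig":
        return cls(variant="wide", mu_sd=100.0, sigma_prior=("uniform", 100.0))

    @classmethod
    def narrow(cls) -> "PriorConfig":
        return cls(variant="narrow", mu_sd=1.0, sigma_prior=("halfnormal", 0.2))

    @classmethod
    def from_variant(cls, variant: str) -> "PriorConfig":
        if variant == "wide":
            return cls.wide()
        if variant == "narrow":
            return cls.narrow()
        raise ValueError(f"unknown prior variant {variant!r}")

    def mu_logpdf(self, x: float) -> float:
        return _normal_logpdf(x, self.mu_sd)

    def delta_logpdf(self, x: float) -> float:
        return _normal_logpdf(x, self.delta_sd)

    def sigma_logpdf(self, s: float) -> float:
        if s <= 0:
            return -math.inf
        kind, scale = self.sigma_prior
        if kind == "uniform":
            return -math.log(scale) if s < scale else -math.inf
        if kind == "halfnormal":
            # half-Normal(0, scale) on the positive reals
            return (
                math.log(2.0) - 0.5 * (s / scale) ** 2 - math.log(scale) - _LOG_SQRT_2PI
            )
        raise ValueError(f"unknown sigma prior family {kind!r}")


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC bookkeeping.

    ``target_accept`` and ``max_tree_depth`` mirror the settings used with
    tree-based gradient samplers and are carried as configuration metadata;
    the package's Metropolis-within-Gibbs sampler adapts its random-walk
    scales toward ``mh_target_accept`` instead.  ``n_subject_refresh`` is the
    number of Metropolis refreshes of the subject-level block per sweep.
    """

    n_chains: int = 8
    n_warmup: int = 10_000
    n_sampling: int = 10_000
    target_accept: float = 0.99
    max_tree_depth: int = 15
    seed: int | None = None
    scale: str = "full"
    n_subject_refresh: int = 10
    mh_target_accept: float = 0.35

    @classmethod
    def full(cls, seed=None) -> "SamplerConfig":
        """Full-scale preset: 8 chains, 10,000 warmup + 10,000 sampling."""
        return cls(seed=seed, scale="full")

    @classmethod
    def test(cls, seed=None) -> "SamplerConfig":
        """Small preset for continuous-integration-scale runs."""
        return cls(n_chains=4, n_warmup=500, n_sampling=500, seed=seed, scale="test")

    @classmethod
    def preset(cls, scale: str, seed=None) -> "SamplerConfig":
        if scale == "full":
            return cls.full(seed)
        if scale == "test":
            return cls.test(seed)
        raise ValueError(f"unknown sampler scale {scale!r}")

    @property
    def n_retained(self) -> int:
        """Retained draws across chains (chains x sampling iterations)."""
        return self.n_chains * self.n_sampling
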