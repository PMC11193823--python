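"""Registry of the model variants fitted to choice data.

Four structural families are supported:

* ``SWo`` / ``SSo`` — dual-rate Q-learning with an *inverse gain* response
  rule (Q-values are divided by beta before the softmax); they differ only in
  their default hierarchical prior variant (wide vs. narrow).
* ``SSh`` / ``SWh`` — the same dual-rate structure under the *inverse
  temperature* convention (Q-values multiplied by beta, beta in [0, 20]).
* ``ES`` — extended dual-rate model with forgetting (phi), irreducible
  decision noise (xi) and an initial bias (q0) for the first choice of a pair.
* ``RLfCK`` — single update rate with forgetting plus a choice-kernel
  component (alpha_ck, tau) capturing choice autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .transforms import LOG, LOGIT, Transform, scaled_logit

#: response-rule conventions
INVERSE_GAIN = "inverse_gain"
SOFTMAX = "softmax"  # inverse-temperature convention
NOISY_SOFTMAX = "noisy_softmax"  # ES rule with irreducible noise
KERNEL_SOFTMAX = "kernel_softmax"  # RLf-CK rule with choice kernel


@dataclass(frozen=True)
class ModelFamily:
    model_id: str
    param_names: tuple
    transforms: tuple
    response: str
    gain_index: int
    loss_index: int
    default_prior_variant: str
    has_forgetting: bool = False
    has_kernel: bool = False
    has_initial_bias: bool = False

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def index(self, name: str) -> int:
        return self.param_names.index(name)

    def transform(self, name: str) -> Transform:
        return self.transforms[self.index(name)]

    def constrain(self, x):
        """Map an (..., k) array of unconstrained values to constrained scale."""
        import numpy as np

        x = np.asarray(x, dtype=float)
        out = np.empty_like(x)
        for i, tr in enumerate(self.transforms):
            out[..., i] = tr.constrain(x[..., i])
        return out

    def unconstrain(self, v):
        import numpy as np

        v = np.asarray(v, dtype=float)
        out = np.empty_like(v)
        for i, tr in enumerate(self.transforms):
            out[..., i] = tr.unconstrain(v[..., i])
        return out


_BETA_TEMP = scaled_logit(0.0, 20.0)

FAMILIES = {
    "SWo": ModelFamily(
        "SWo",
        ("alpha_gain", "alpha_loss", "beta"),
        (LOGIT, LOGIT, LOG),
        INVERSE_GAIN,
        gain_index=0,
        loss_index=1,
        default_prior_variant="wide",
    ),
    "SSo": ModelFamily(
        "SSo",
        ("alpha_gain", "alpha_loss", "beta"),
        (LOGIT, LOGIT, LOG),
        INVERSE_GAIN,
        gain_index=0,
        loss_index=1,
        default_prior_variant="narrow",
    ),
    "SSh": ModelFamily(
        "SSh",
        ("alpha_gain", "alpha_loss", "beta"),
        (LOGIT, LOGIT, _BETA_TEMP),
        SOFTMAX,
        gain_index=0,
        loss_index=1,
        default_prior_variant="narrow",
    ),
    "SWh": ModelFamily(
        "SWh",
        ("alpha_gain", "alpha_loss", "beta"),
        (LOGIT, LOGIT, _BETA_TEMP),
        SOFTMAX,
        gain_index=0,
        loss_index=1,
        default_prior_variant="wide",
    ),
    "ES": ModelFamily(
        "ES",
        ("alpha_gain", "alpha_loss", "beta", "phi", "xi", "q0"),
        (LOGIT, LOGIT, _BETA_TEMP, LOGIT, LOGIT, LOGIT),
        NOISY_SOFTMAX,
        gain_index=0,
        loss_index=1,
        default_prior_variant="narrow",
        has_forgetting=True,
        has_initial_bias=True,
    ),
    "RLfCK": ModelFamily(
        "RLfCK",
        ("alpha", "phi", "beta", "alpha_ck", "tau"),
        (LOGIT, LOGIT, _BETA_TEMP, LOGIT, scaled_logit(-5.0, 5.0)),
        KERNEL_SOFTMAX,
        gain_index=0,
        loss_index=0,  # single update rate for both signs of prediction error
        default_prior_variant="narrow",
        has_forgetting=True,
        has_kernel=True,
    ),
}


def get_family(model_id: str) -> ModelFamily:
    try:
        return FAMILIES[model_id]
    except KeyError:
        raise ValueError(
            f"unknown model_id {model_id!r}; expected one of {sorted(FAMILIES)}"
        ) from None
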