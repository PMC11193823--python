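"""Constrained-scale parameter containers for the model variants."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .families import INVERSE_GAIN, SOFTMAX, get_family


def _check(name, value, lo, hi):
    if not (lo <= value <= hi):
        raise ValueError(f"{name}={value} outside [{lo}, {hi}]")


@dataclass(frozen=True)
class DualRateParams:
    """Dual-rate Q-learning parameters (SWo/SSo inverse-gain or SSh/SWh softmax)."""

    alpha_gain: float
    alpha_loss: float
    beta: float
    response_convention: str = INVERSE_GAIN

    def __post_init__(self):
        _check("alpha_gain", self.alpha_gain, 0.0, 1.0)
        _check("alpha_loss", self.alpha_loss, 0.0, 1.0)
        if self.response_convention == INVERSE_GAIN:
            if self.beta < 0:
                raise ValueError("beta must be nonnegative under the inverse-gain rule")
        elif self.response_convention == SOFTMAX:
            _check("beta", self.beta, 0.0, 20.0)
        else:
            raise ValueError(f"unknown response convention {self.response_convention}")


@dataclass(frozen=True)
class ESParams:
    """Dual-rate model extended by forgetting, irreducible noise and initial bias."""

    alpha_gain: float
    alpha_loss: float
    beta: float
    phi: float
    xi: float
    q0: float

    def __post_init__(self):
        _check("alpha_gain", self.alpha_gain, 0.0, 1.0)
        _check("alpha_loss", self.alpha_loss, 0.0, 1.0)
        _check("beta", self.beta, 0.0, 20.0)
        _check("phi", self.phi, 0.0, 1.0)
        _check("xi", self.xi, 0.0, 1.0)
        _check("q0", self.q0, 0.0, 1.0)


@dataclass(frozen=True)
class RLfCKParams:
    """Single-rate forgetting model with a choice-kernel component."""

    alpha: float
    phi: float
    beta: float
    alpha_ck: float
    tau: float

    def __post_init__(self):
        _check("alpha", self.alpha, 0.0, 1.0)
        _check("phi", self.phi, 0.0, 1.0)
        _check("beta", self.beta, 0.0, 20.0)
        _check("alpha_ck", self.alpha_ck, 0.0, 1.0)
        _check("tau", self.tau, -5.0, 5.0)


_PARAM_CLASS = {
    "SWo": DualRateParams,
    "SSo": DualRateParams,
    "SSh": DualRateParams,
    "SWh": DualRateParams,
    "ES": ESParams,
    "RLfCK": RLfCKParams,
}


def params_class(model_id: str):
    fam = get_family(model_id)  # validates the id
    return _PARAM_CLASS[fam.model_id]


def params_from_array(model_id: str, values) -> object:
    """Build the model's parameter container from constrained values in family order."""
    fam = get_family(model_id)
    values = np.asarray(values, dtype=float)
    if values.shape != (fam.n_params,):
        raise ValueError(
            f"expected {fam.n_params} values for {model_id}, got shape {values.shape}"
        )
    kwargs = dict(zip(fam.param_names, values.tolist()))
    if _PARAM_CLASS[model_id] is DualRateParams:
        kwargs["response_convention"] = fam.response
    return _PARAM_CLASS[model_id](**kwargs)


def params_to_array(model_id: str, params) -> np.ndarray:
    fam = get_family(model_id)
    return np.array([getattr(params, name) for name in fam.param_names], dtype=float)


def params_to_json(model_id: str, params) -> str:
    doc = {"model_id": model_id}
    doc.update({k: v for k, v in asdict(params).items() if k != "response_convention"})
    return json.dumps(doc, indent=2)


def params_from_json(text: str):
    doc = json.loads(text)
    model_id = doc.pop("model_id", None)
    if model_id is None:
        raise ValueError("parameter JSON requires a model_id field")
    fam = get_family(model_id)
    values = [float(doc[name]) for name in fam.param_names]
    return model_id, params_from_array(model_id, values)
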