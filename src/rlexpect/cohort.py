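"""Synthetic cohorts with the hierarchical five-group structure.

Subjects are assigned i.i.d. uniformly to the five purported-efficacy groups
(0/25/50/75/100%), and each subject's unconstrained parameters are drawn
around group-level means mu_theta0 + delta_thetaj with spread sigma_theta.
Presets encode the two competing group-effect hypotheses on the gain learning
rate: a strictly monotonic increase with purported efficacy, and an
inverted-U peaking at the maximum-uncertainty (50%) group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agents import simulate_choices
from .families import get_family
from .params import params_from_array
from .task import TaskDesign, build_schedule, default_design

GROUP_LABELS = (0, 25, 50, 75, 100)

# Baseline group-level means on the unconstrained scale, chosen to put the
# constrained values in the range typically estimated for this task family
# (gain rate ~0.3, loss rate ~0.1, inverse gain ~0.15, inverse temperature ~4,
# mild forgetting/noise).  Within-group spread is 0.5 for every parameter.
_DEFAULT_SIGMA = 0.5
_BASELINES = {
    "SWo": {"alpha_gain": -0.847, "alpha_loss": -2.197, "beta": -1.897},
    "SSh": {"alpha_gain": -0.847, "alpha_loss": -2.197, "beta": -1.386},
    "ES": {
        "alpha_gain": -0.847,
        "alpha_loss": -2.197,
        "beta": -1.386,
        "phi": -2.197,
        "xi": -2.944,
        "q0": -0.847,
    },
    "RLfCK": {
        "alpha": -1.099,
        "phi": -2.197,
        "beta": -1.386,
        "alpha_ck": -0.847,
        "tau": 0.405,
    },
}
_BASELINES["SSo"] = _BASELINES["SWo"]
_BASELINES["SWh"] = _BASELINES["SSh"]

#: default group offsets (unconstrained scale) on the preset's target parameter
PRESET_DELTAS = {
    "null": {0: 0.0, 25: 0.0, 50: 0.0, 75: 0.0, 100: 0.0},
    "monotonic": {0: 0.0, 25: 0.2, 50: 0.4, 75: 0.6, 100: 0.8},
    "inverted_u": {0: 0.0, 25: 0.4, 50: 0.8, 75: 0.4, 100: 0.0},
}


@dataclass(frozen=True)
class ParamEffect:
    """Group structure of one parameter on the unconstrained scale."""

    mu0: float
    delta: dict  # group label -> offset; baseline offset must be 0
    sigma: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.delta.get(0, 0.0) != 0.0:
            raise ValueError("the baseline group (0%) carries no offset")
        unknown = set(self.delta) - set(GROUP_LABELS)
        if unknown:
            raise ValueError(f"unknown group labels {sorted(unknown)}")

    def group_mean(self, group: int) -> float:
        return self.mu0 + self.delta.get(group, 0.0)


@dataclass(frozen=True)
class ScenarioConfig:
    model_id: str
    n_subjects: int
    effects: dict  # parameter name -> ParamEffect
    preset: str = "custom"

    def __post_init__(self):
        fam = get_family(self.model_id)
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")
        if set(self.effects) != set(fam.param_names):
            raise ValueError(
                f"effects must cover exactly the parameters of {self.model_id}: "
                f"{fam.param_names}"
            )


def preset_target_parameter(model_id: str) -> str:
    """The parameter carrying the group effect in the named presets."""
    return "alpha" if model_id == "RLfCK" else "alpha_gain"


def make_scenario(
    preset: str,
    model_id: str,
    n_subjects: int,
    peak_delta: float | None = None,
    sigma: float = _DEFAULT_SIGMA,
) -> ScenarioConfig:
    """Build a ScenarioConfig from a named preset.

    ``peak_delta`` rescales the preset's offsets so that the largest offset
    equals it (default: keep the preset magnitudes, peak 0.8).
    """
    if preset not in PRESET_DELTAS:
        raise ValueError(
            f"unknown preset {preset!r}; expected one of {sorted(PRESET_DELTAS)}"
        )
    fam = get_family(model_id)
    deltas = dict(PRESET_DELTAS[preset])
    if peak_delta is not None and preset != "null":
        top = max(abs(v) for v in deltas.values())
        deltas = {j: v * peak_delta / top for j, v in deltas.items()}
    target = preset_target_parameter(model_id)
    effects = {}
    for name in fam.param_names:
        mu0 = _BASELINES[model_id][name]
        d = deltas if name == target else {j: 0.0 for j in GROUP_LABELS}
        effects[name] = ParamEffect(mu0=mu0, delta=d, sigma=sigma)
    return ScenarioConfig(
        model_id=model_id, n_subjects=n_subjects, effects=effects, preset=preset
    )


@dataclass(frozen=True)
class SubjectTruth:
    subject_id: int
    group: int
    x: np.ndarray = field(repr=False)  # unconstrained, family order
    params: object = None  # constrained container


def draw_cohort(scenario: ScenarioConfig, seed) -> list:
    """Draw group labels and subject parameters for a scenario."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fam = get_family(scenario.model_id)
    n = scenario.n_subjects
    groups = rng.integers(0, len(GROUP_LABELS), size=n)
    cohort = []
    for s in range(n):
        g = GROUP_LABELS[groups[s]]
        x = np.array(
            [
                rng.normal(
                    scenario.effects[name].group_mean(g),
                    scenario.effects[name].sigma,
                )
                for name in fam.param_names
            ]
        )
        constrained = fam.constrain(x)
        cohort.append(
            SubjectTruth(
                subject_id=s + 1,
                group=g,
                x=x,
                params=params_from_array(scenario.model_id, constrained),
            )
        )
    return cohort


def simulate_cohort(
    cohort: list,
    design: TaskDesign | None = None,
    seed=None,
    model_id: str | None = None,
    with_rt: bool = True,
) -> pd.DataFrame:
    """Simulate the full trial table of a cohort (fresh schedule per subject).

    Optional reaction times are log-normal (median 600 ms, log-sd 0.25) and
    carry no model content; they exist so RT-handling code paths run.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    if design is None:
        design = default_design()
    if model_id is None:
        model_id = _infer_model_id(cohort[0].params)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    tables = []
    for subject, child in zip(cohort, ss.spawn(len(cohort))):
        rng = np.random.default_rng(child)
        schedule = build_schedule(design, rng)
        sim = simulate_choices(subject.params, schedule, design, model_id, rng)
        sim.insert(0, "subject_id", subject.subject_id)
        sim.insert(1, "group", subject.group)
        if with_rt:
            sim["rt_ms"] = np.round(
                np.exp(rng.normal(np.log(600.0), 0.25, size=len(sim)))
            )
        tables.append(sim)
    return pd.concat(tables, ignore_index=True)


def truth_table(cohort: list, model_id: str | None = None) -> pd.DataFrame:
    """Generative parameters as a flat table (for recovery studies)."""
    if model_id is None:
        model_id = _infer_model_id(cohort[0].params)
    fam = get_family(model_id)
    rows = []
    for s in cohort:
        row = {"subject_id": s.subject_id, "group": s.group}
        for i, name in enumerate(fam.param_names):
            row[f"x_{name}"] = s.x[i]
            row[name] = getattr(s.params, name)
        rows.append(row)
    return pd.DataFrame(rows)


def _infer_model_id(params) -> str:
    from .params import DualRateParams, ESParams, RLfCKParams
    from .families import INVERSE_GAIN

    if isinstance(params, ESParams):
        return "ES"
    if isinstance(params, RLfCKParams):
        return "RLfCK"
    if isinstance(params, DualRateParams):
        return "SWo" if params.response_convention == INVERSE_GAIN else "SSh"
    raise TypeError(f"unrecognized parameter container {type(params)!r}")
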