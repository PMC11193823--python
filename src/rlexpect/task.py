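"""Probabilistic selection task: three fixed stimulus pairs with complementary
reward probabilities (80:20, 70:30, 60:40), 40 trials per pair, position-balanced.

The task presents two stimuli of a pair per trial; the chosen stimulus is
rewarded with its fixed Bernoulli probability, so even the worse stimulus of a
pair pays off occasionally.  Stimulus identity is an opaque integer label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class PairSpec:
    """One stimulus pair; the worse stimulus is rewarded with 1 - p_reward_better."""

    pair_id: int
    stim_better: int
    stim_worse: int
    p_reward_better: float

    def __post_init__(self):
        if not (0.5 < self.p_reward_better <= 1.0):
            raise ValueError(
                f"p_reward_better must be in (0.5, 1], got {self.p_reward_better}"
            )
        if self.stim_better == self.stim_worse:
            raise ValueError("stim_better and stim_worse must differ")

    @property
    def p_reward_worse(self) -> float:
        return 1.0 - self.p_reward_better

    @property
    def stimuli(self):
        return (self.stim_better, self.stim_worse)

    def reward_probability(self, stimulus: int) -> float:
        if stimulus == self.stim_better:
            return self.p_reward_better
        if stimulus == self.stim_worse:
            return self.p_reward_worse
        raise ValueError(f"stimulus {stimulus} not in pair {self.pair_id}")


@dataclass(frozen=True)
class TaskDesign:
    pairs: tuple
    trials_per_pair: int = 40
    response_window_ms: int = 1700  # metadata only; no timing is simulated
    feedback_ms: int = 1000

    def __post_init__(self):
        if self.trials_per_pair < 1:
            raise ValueError("trials_per_pair must be positive")
        stimuli = [s for p in self.pairs for s in p.stimuli]
        if len(set(stimuli)) != len(stimuli):
            raise ValueError("stimulus ids must be distinct across pairs")

    @property
    def n_trials(self) -> int:
        return len(self.pairs) * self.trials_per_pair

    @property
    def stimuli(self):
        return tuple(s for p in self.pairs for s in p.stimuli)

    def pair(self, pair_id: int) -> PairSpec:
        for p in self.pairs:
            if p.pair_id == pair_id:
                return p
        raise ValueError(f"unknown pair_id {pair_id}")

    def pair_of_stimulus(self, stimulus: int) -> PairSpec:
        for p in self.pairs:
            if stimulus in p.stimuli:
                return p
        raise ValueError(f"stimulus {stimulus} belongs to no pair")

    def to_json(self) -> str:
        doc = {
            "pairs": [
                {
                    "pair_id": p.pair_id,
                    "stim_better": p.stim_better,
                    "stim_worse": p.stim_worse,
                    "p_reward_better": p.p_reward_better,
                }
                for p in self.pairs
            ],
            "trials_per_pair": self.trials_per_pair,
            "response_window_ms": self.response_window_ms,
            "feedback_ms": self.feedback_ms,
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TaskDesign":
        doc = json.loads(text)
        pairs = tuple(
            PairSpec(
                pair_id=int(p["pair_id"]),
                stim_better=int(p.get("stim_better", 2 * i + 1)),
                stim_worse=int(p.get("stim_worse", 2 * i + 2)),
                p_reward_better=float(p["p_reward_better"]),
            )
            for i, p in enumerate(doc["pairs"])
        )
        return cls(
            pairs=pairs,
            trials_per_pair=int(doc.get("trials_per_pair", 40)),
            response_window_ms=int(doc.get("response_window_ms", 1700)),
            feedback_ms=int(doc.get("feedback_ms", 1000)),
        )


def default_design() -> TaskDesign:
    """Three pairs with better-stimulus reward probabilities 0.8, 0.7 and 0.6."""
    return TaskDesign(
        pairs=(
            PairSpec(1, 1, 2, 0.8),
            PairSpec(2, 3, 4, 0.7),
            PairSpec(3, 5, 6, 0.6),
        )
    )


def build_schedule(design: TaskDesign, seed) -> pd.DataFrame:
    """Randomized interleaving of all (pair, position) slots.

    Each pair appears ``trials_per_pair`` times and each stimulus of a pair is
    shown on the left in exactly half of that pair's trials.  Trial order is a
    uniform random permutation of the slots, deterministic given the seed.

    Returns a DataFrame with columns trial (1-based), pair, left, right.
    """
    if design.trials_per_pair % 2 != 0:
        raise ValueError(
            "trials_per_pair must be even for an exact left/right position balance"
        )
    rng = _rng(seed)
    half = design.trials_per_pair // 2
    rows = []
    for p in design.pairs:
        rows += [(p.pair_id, p.stim_better, p.stim_worse)] * half
        rows += [(p.pair_id, p.stim_worse, p.stim_better)] * half
    order = rng.permutation(len(rows))
    rows = [rows[i] for i in order]
    return pd.DataFrame(
        {
            "trial": np.arange(1, len(rows) + 1),
            "pair": [r[0] for r in rows],
            "left": [r[1] for r in rows],
            "right": [r[2] for r in rows],
        }
    )


def sample_feedback(pair: PairSpec, chosen_stimulus: int, seed, size=None):
    """Bernoulli feedback for choosing ``chosen_stimulus`` from ``pair``.

    With ``size=None`` returns a single int in {0, 1}; otherwise an int array.
    """
    p = pair.reward_probability(chosen_stimulus)
    rng = _rng(seed)
    draw = rng.random(size)
    if size is None:
        return int(draw < p)
    return (draw < p).astype(int)


def bernoulli_entropy(p: float) -> float:
    """Shannon entropy (nats) of a Bernoulli(p) outcome; 0 at the endpoints."""
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if p in (0.0, 1.0):
        return 0.0
    return -(p * np.log(p) + (1.0 - p) * np.log(1.0 - p))


def max_entropy_reward_probability() -> float:
    """Reward probability maximizing outcome uncertainty (Bernoulli entropy).

    Maximum reward uncertainty is the condition under which tonic dopaminergic
    activity peaks in the conditioning literature; this is the numerical
    counterpart used when reasoning about the 50% efficacy group.
    """
    res = minimize_scalar(
        lambda p: -bernoulli_entropy(p), bounds=(1e-9, 1 - 1e-9), method="bounded"
    )
    return float(res.x)
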