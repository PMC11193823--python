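"""Conventional behavioral summaries and the response-count exclusion rule.

Four aggregate measures are computed per subject: reaction time (when
present), rate of optimal choices, rate of collected reward, and the stay
probability — the probability that a third consecutive choice within a
stimulus pair repeats two equal preceding choices.  Windows for the stay
probability are overlapping, strictly within pair, over consecutive
presentations of that pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, pearsonr


@dataclass(frozen=True)
class SubjectBehavior:
    subject_id: object
    group: int
    optimal_rate: float
    reward_rate: float
    mean_rt_ms: float  # NaN when reaction times are absent
    stay_prob: float  # NaN when no eligible window exists
    response_count: int


def stay_probability(choices_by_pair) -> float:
    """Stay probability over within-pair windows of three consecutive choices.

    ``choices_by_pair`` is an iterable of chronological choice sequences, one
    per pair.  Returns NaN when no window has two equal preceding choices.
    """
    eligible = 0
    stays = 0
    for seq in choices_by_pair:
        seq = list(seq)
        for i in range(len(seq) - 2):
            if seq[i] == seq[i + 1]:
                eligible += 1
                if seq[i + 2] == seq[i]:
                    stays += 1
    if eligible == 0:
        return math.nan
    return stays / eligible


def aggregate_behavior(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject SubjectBehavior fields as a DataFrame."""
    if len(table) == 0:
        raise ValueError("empty trial table")
    rows = []
    for sid, sub in table.groupby("subject_id", sort=False):
        sub = sub.sort_values("trial")
        if len(sub) == 0:
            raise ValueError(f"subject {sid!r} has no trials")
        per_pair = [g["choice"].tolist() for _, g in sub.groupby("pair", sort=False)]
        if "rt_ms" in sub.columns and sub["rt_ms"].notna().any():
            mean_rt = float(sub["rt_ms"].dropna().mean())
        else:
            mean_rt = math.nan
        rows.append(
            {
                "subject_id": sid,
                "group": int(sub["group"].iloc[0]) if "group" in sub.columns else -1,
                "optimal_rate": float(sub["optimal"].mean()),
                "reward_rate": float(sub["reward"].mean()),
                "mean_rt_ms": mean_rt,
                "stay_prob": stay_probability(per_pair),
                "response_count": int(len(sub)),
            }
        )
    return pd.DataFrame(rows)


def cumulative_curves(table: pd.DataFrame, measure: str) -> dict:
    """Individual running means of a measure by within-pair trial index.

    Returns ``{"individual": DataFrame, "group": DataFrame}`` where the
    individual frame holds one running-mean value per (subject, pair,
    pair_trial) and the group frame the cross-subject mean and standard error
    per (pair, pair_trial).
    """
    if measure not in table.columns:
        raise ValueError(f"unknown measure {measure!r}")
    df = table.sort_values(["subject_id", "trial"]).copy()
    df["pair_trial"] = df.groupby(["subject_id", "pair"]).cumcount() + 1
    grp = df.groupby(["subject_id", "pair"])[measure]
    df["running_mean"] = grp.cumsum() / df["pair_trial"]
    individual = df[["subject_id", "pair", "pair_trial", "running_mean"]]
    group = (
        individual.groupby(["pair", "pair_trial"])["running_mean"]
        .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)))
        .reset_index()
    )
    return {"individual": individual, "group": group}


def sliding_window_correlation(
    table: pd.DataFrame,
    subject_statistic,
    measure: str,
    window: int = 20,
    step: int = 1,
) -> pd.DataFrame:
    """Correlation trace between a per-subject statistic and windowed behavior.

    For each window position (the first window, labeled by its last trial
    ``window``, covers trials 1..window) the product-moment correlation across
    subjects between ``subject_statistic`` and the subject's windowed mean of
    ``measure`` is computed, with an uncorrected Fisher-z 95% interval.
    Windows with zero variance in either variable yield NaN.

    ``subject_statistic`` maps subject_id -> value (dict or Series).
    """
    if measure not in table.columns:
        raise ValueError(f"unknown measure {measure!r}")
    stat = dict(subject_statistic)
    wide = (
        table.sort_values(["subject_id", "trial"])
        .groupby("subject_id", sort=False)[measure]
        .apply(lambda v: v.to_numpy())
    )
    subjects = list(wide.index)
    missing = [s for s in subjects if s not in stat]
    if missing:
        raise ValueError(f"subject_statistic undefined for {missing}")
    lengths = {len(v) for v in wide}
    if len(lengths) != 1:
        raise ValueError("all subjects must have the same number of trials")
    (t_total,) = lengths
    if t_total < window:
        raise ValueError("fewer trials than the window length")
    s_vals = np.array([stat[s] for s in subjects], dtype=float)
    series = np.stack(list(wide))  # (n_subjects, T)

    zcrit = norm.ppf(0.975)
    rows = []
    for end in range(window, t_total + 1, step):
        w_mean = series[:, end - window : end].mean(axis=1)
        if np.ptp(s_vals) == 0.0 or np.ptp(w_mean) == 0.0:
            r, lo, hi = math.nan, math.nan, math.nan
        else:
            r = float(pearsonr(s_vals, w_mean).statistic)
            if abs(r) >= 1.0 or len(subjects) < 4:
                lo, hi = math.nan, math.nan
            else:
                z = math.atanh(r)
                half = zcrit / math.sqrt(len(subjects) - 3)
                lo, hi = math.tanh(z - half), math.tanh(z + half)
        rows.append({"window_end": end, "r": r, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


def exclusion_filter(table: pd.DataFrame) -> list:
    """Retain subjects responding at least mean - 3 * sd response counts.

    The threshold uses the sample (n-1) standard deviation of per-subject
    response counts; subjects strictly below it are excluded.
    """
    if len(table) == 0:
        raise ValueError("empty trial table")
    counts = table.groupby("subject_id", sort=False).size()
    if len(counts) < 2:
        raise ValueError("the exclusion rule needs at least two subjects")
    threshold = counts.mean() - 3.0 * counts.std(ddof=1)
    return [sid for sid, c in counts.items() if c >= threshold]
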