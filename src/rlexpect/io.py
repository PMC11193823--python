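"""Stable file formats: trial-table CSV, posterior-draw CSV + JSON sidecar.

CSV is the single tabular interchange format (header row, UTF-8, "." decimal);
JSON carries configurations, reports and metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

TRIAL_COLUMNS = ["subject_id", "group", "trial", "pair", "choice", "optimal", "reward", "rt_ms"]
_REQUIRED = ["subject_id", "group", "trial", "pair", "choice", "optimal", "reward"]


def read_trial_table(path) -> pd.DataFrame:
    """Read and validate a long-format trial table.

    Raises ValueError naming the offending row for illegal reward values or
    duplicate (subject, trial) keys; an empty file with a header is a valid
    empty table.
    """
    table = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if "rt_ms" not in table.columns:
        table["rt_ms"] = np.nan
    if len(table) == 0:
        return table

    bad = table.index[~table["reward"].isin([0, 1])]
    if len(bad):
        raise ValueError(
            f"{path}: illegal reward value {table.loc[bad[0], 'reward']} in row {bad[0]}"
        )
    dup = table.duplicated(subset=["subject_id", "trial"])
    if dup.any():
        row = int(np.flatnonzero(dup)[0])
        raise ValueError(
            f"{path}: duplicate (subject_id, trial) key "
            f"({table.loc[row, 'subject_id']!r}, {table.loc[row, 'trial']!r}) in row {row}"
        )
    for sid, sub in table.groupby("subject_id", sort=False):
        t = sub["trial"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"{path}: trials of subject {sid!r} are not increasing")
    return table


def write_trial_table(table: pd.DataFrame, path) -> None:
    out = table.reindex(columns=TRIAL_COLUMNS)
    out.to_csv(path, index=False)


def write_json(doc: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")


def read_draws(prefix):
    """Reconstruct a PosteriorDraws object saved with ``PosteriorDraws.save``."""
    from .hierarchical import OFFSET_LABELS, PosteriorDraws

    with open(f"{prefix}.json") as fh:
        meta = json.load(fh)
    df = pd.read_csv(f"{prefix}.csv")
    C = int(meta["n_chains"])
    D = int(meta["n_draws_per_chain"])
    names = tuple(meta["param_names"])
    k = len(names)

    def grab(param_name):
        sub = df[df["parameter"] == param_name].sort_values(["chain", "iteration"])
        if len(sub) != C * D:
            raise ValueError(f"{prefix}.csv: parameter {param_name!r} has wrong draw count")
        return sub["value"].to_numpy().reshape(C, D)

    mu = np.stack([grab(f"mu[{n}]") for n in names], axis=-1)
    sigma = np.stack([grab(f"sigma[{n}]") for n in names], axis=-1)
    delta = np.stack(
        [
            np.stack([grab(f"delta[{n},{lab}]") for lab in OFFSET_LABELS], axis=-1)
            for n in names
        ],
        axis=-2,
    )

    subject_ids = meta["subject_ids"]
    # subject ids are persisted as strings; restore integer ids when possible
    if all(str(s).lstrip("-").isdigit() for s in subject_ids):
        subject_ids = [int(s) for s in subject_ids]
    present = set(df["parameter"])
    subject_x = None
    if subject_ids and f"x[{names[0]},{subject_ids[0]}]" in present:
        subject_x = np.empty((C, D, len(subject_ids), k))
        for s, sid in enumerate(subject_ids):
            for p, n in enumerate(names):
                subject_x[:, :, s, p] = grab(f"x[{n},{sid}]")

    return PosteriorDraws(
        model_id=meta["model_id"],
        param_names=names,
        mu=mu,
        delta=delta,
        sigma=sigma,
        subject_x=subject_x,
        subject_ids=np.asarray(subject_ids),
        subject_groups=np.asarray(meta["subject_groups"], dtype=int),
        prior_variant=meta["prior_variant"],
        seed=meta.get("seed"),
        sampler=meta.get("sampler", {}),
        diagnostics=meta.get("diagnostics", {}),
    )
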