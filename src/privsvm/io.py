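"""Tabular input/output.

Datasets travel as CSV with columns ``id, y, x_1..x_d, px_1..px_dt``; missing
privileged entries are blank (read back as NaN, which defines the PI mask).
A sidecar JSON can carry the generating :class:`~privsvm.synthetic.SyntheticSpec`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import TrainingSet
from .synthetic import SyntheticSpec

__all__ = ["write_dataset_csv", "read_dataset_csv", "write_spec_json", "read_spec_json"]


def _dataset_frame(data: TrainingSet) -> pd.DataFrame:
    d, dt = data.X.shape[1], data.X_priv.shape[1]
    cols = {"id": np.arange(data.n), "y": data.y}
    for j in range(d):
        cols[f"x_{j + 1}"] = data.X[:, j]
    P = data.X_priv.astype(float).copy()
    P[~data.pi_mask] = np.nan
    for j in range(dt):
        cols[f"px_{j + 1}"] = P[:, j]
    return pd.DataFrame(cols)


def write_dataset_csv(data: TrainingSet, path, spec: SyntheticSpec | None = None) -> None:
    """Write a dataset as CSV (+ optional ``<path>.spec.json`` sidecar)."""
    path = Path(path)
    _dataset_frame(data).to_csv(path, index=False, float_format="%.17g")
    if spec is not None:
        write_spec_json(spec, path.with_suffix(path.suffix + ".spec.json"))


def read_dataset_csv(path) -> TrainingSet:
    """Read a dataset CSV; blank/NaN privileged rows define the PI mask.

    A privileged row counts as present only when *all* its entries are
    observed (the model's privileged block is per-row, not per-cell).
    """
    df = pd.read_csv(path)
    if "y" not in df.columns:
        raise ValueError("dataset CSV must have a 'y' label column")
    x_cols = sorted((c for c in df.columns if c.startswith("x_")),
                    key=lambda c: int(c.split("_")[1]))
    px_cols = sorted((c for c in df.columns if c.startswith("px_")),
                     key=lambda c: int(c.split("_")[1]))
    if not x_cols:
        raise ValueError("dataset CSV has no main-feature columns x_1..x_d")
    X = df[x_cols].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=int)
    if px_cols:
        P = df[px_cols].to_numpy(dtype=float)
        mask = ~np.isnan(P).any(axis=1)
    else:
        P = None
        mask = np.zeros(len(df), dtype=bool)
    return TrainingSet(X=X, X_priv=P, pi_mask=mask, y=y)


def write_spec_json(spec: SyntheticSpec, path) -> None:
    with open(path, "w") as fh:
        json.dump(spec.to_json(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_spec_json(path) -> SyntheticSpec:
    with open(path) as fh:
        return SyntheticSpec.from_json(json.load(fh))
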