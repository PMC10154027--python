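"""Named representation tables (embeddings, fingerprints) and distance matrices.

A :class:`RepresentationTable` maps molecule keys to fixed-width vectors and
carries the distance metric under which the representation is compared:
``correlation_centered`` for embeddings (center per dimension over the key
population under analysis, then 1 − Pearson), ``tanimoto`` for bit
fingerprints, ``l1`` for count fingerprints.  Because the centering
population is part of the correlation metric, distance matrices depend on
the exact key set they are computed over.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .chem import center_rows, cfp_edit_distance, correlation_distance, tanimoto_distance

METRICS = ("correlation_centered", "tanimoto", "l1")


@dataclass
class RepresentationTable:
    name: str
    metric: str
    vectors: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; expected one of {METRICS}")
        widths = {v.shape[0] for v in self.vectors.values()}
        if len(widths) > 1:
            raise ValueError(f"inconsistent vector widths in table {self.name!r}: {sorted(widths)}")

    @property
    def width(self) -> int:
        return next(iter(self.vectors.values())).shape[0] if self.vectors else 0

    def matrix(self, keys: Sequence[str]) -> np.ndarray:
        missing = [k for k in keys if k not in self.vectors]
        if missing:
            raise KeyError(f"keys absent from table {self.name!r}: {missing[:10]}")
        return np.vstack([self.vectors[k] for k in keys]).astype(float)


@dataclass
class DistanceMatrix:
    keys: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.keys)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match key count")
        if not np.allclose(self.values, self.values.T) or not np.allclose(np.diag(self.values), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")

    def pair(self, a: str, b: str) -> float:
        i, j = self.keys.index(a), self.keys.index(b)
        return float(self.values[i, j])


def load_table(path, name: str, metric: str) -> RepresentationTable:
    """Load a CSV with a key column followed by v0..v{d-1} numeric columns."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a key column plus at least one vector column")
    key_col = df.columns[0]
    dup = df[key_col][df[key_col].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate keys: {dup.tolist()[:5]}")
    vec_cols = df.columns[1:]
    try:
        values = df[vec_cols].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        bad = df[vec_cols].apply(pd.to_numeric, errors="coerce").isna().any(axis=1)
        rows = df.loc[bad, key_col].tolist()
        raise ValueError(f"{path}: non-numeric vector cells in rows {rows[:5]}") from exc
    vectors = {str(k): values[i] for i, k in enumerate(df[key_col])}
    return RepresentationTable(name=name, metric=metric, vectors=vectors)


def save_table(table: RepresentationTable, path) -> None:
    keys = list(table.vectors)
    mat = table.matrix(keys)
    df = pd.DataFrame(mat, columns=[f"v{i}" for i in range(mat.shape[1])])
    df.insert(0, "key", keys)
    df.to_csv(path, index=False, float_format="%.17g")


def distance_matrix(table: RepresentationTable, keys: Sequence[str]) -> DistanceMatrix:
    """Pairwise distances over ``keys`` under the table's metric.

    For the centered-correlation metric the centering population is exactly
    ``keys``: sub-population and full-population matrices legitimately differ.
    """
    keys = list(keys)
    if len(keys) < 2:
        raise ValueError("need at least 2 keys")
    mat = table.matrix(keys)
    n = len(keys)
    out = np.zeros((n, n))
    if table.metric == "correlation_centered":
        mat = center_rows(mat)
        dist = correlation_distance
    elif table.metric == "tanimoto":
        dist = tanimoto_distance
    else:
        dist = cfp_edit_distance
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = dist(mat[i], mat[j])
    return DistanceMatrix(keys=keys, values=out)


def save_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.values, index=dm.keys, columns=dm.keys).to_csv(path)
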