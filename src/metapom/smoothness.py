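"""Pathway smoothness in a PCA-compressed representation space.

Representations are compressed to a common dimensionality (64 by default)
with PCA so that comparisons between spaces of different native width are
not biased by dimensionality.  For a pathway A -> ... -> Z, the smoothness of
an intermediate X is the ratio of the direct Euclidean distance d(A, Z) to
the path length through X, d(A, X) + d(X, Z).  The ratio lies in (0, 1] by
the triangle inequality and equals 1 exactly when X sits on the segment from
A to Z — a perfectly interpolated intermediate.  Paired t-tests compare the
smoothness of the same intermediates across two representations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .representations import RepresentationTable


@dataclass(frozen=True)
class PCAConfig:
    n_components: int = 64
    n_view: int = 2

    def __post_init__(self) -> None:
        if self.n_view > self.n_components or self.n_components < 1:
            raise ValueError("require 1 <= n_view <= n_components")


@dataclass(frozen=True)
class SmoothnessRecord:
    pathway_id: str
    intermediate: str
    start: str
    end: str
    smoothness: float


@dataclass(frozen=True)
class PairedTestResult:
    n: int
    mean_diff: float
    t_statistic: float
    p_value: float
    sided: str = "two_sided"


def pca_project(
    table: RepresentationTable, keys: Sequence[str], cfg: PCAConfig = PCAConfig()
) -> dict[str, np.ndarray]:
    """Project the key population onto its top principal components.

    The effective number of components is min(n_components, n_keys − 1,
    native width): PCA cannot exceed the data rank.
    """
    keys = list(keys)
    if len(keys) < 3:
        raise ValueError("need at least 3 keys for a PCA projection")
    mat = table.matrix(keys)
    k = min(cfg.n_components, len(keys) - 1, mat.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    proj = pca.fit_transform(mat)
    return {key: proj[i] for i, key in enumerate(keys)}


def explained_variance_fractions(
    table: RepresentationTable, keys: Sequence[str], cfg: PCAConfig = PCAConfig()
) -> np.ndarray:
    keys = list(keys)
    mat = table.matrix(keys)
    k = min(cfg.n_components, len(keys) - 1, mat.shape[1])
    return PCA(n_components=k, svd_solver="full").fit(mat).explained_variance_ratio_


def smoothness_ratio(start: np.ndarray, intermediate: np.ndarray, end: np.ndarray) -> float:
    """d(start, end) / (d(start, intermediate) + d(intermediate, end))."""
    start = np.asarray(start, dtype=float)
    intermediate = np.asarray(intermediate, dtype=float)
    end = np.asarray(end, dtype=float)
    direct = float(np.linalg.norm(end - start))
    if direct == 0.0:
        raise ValueError("smoothness undefined: start and end coincide")
    through = float(np.linalg.norm(intermediate - start) + np.linalg.norm(end - intermediate))
    if through == 0.0:  # pragma: no cover - excluded by direct > 0
        raise ValueError("degenerate triplet")
    return direct / through


def score_pathways(
    pathways: dict[str, Sequence[str]],
    table: RepresentationTable,
    cfg: PCAConfig = PCAConfig(),
    mode: str = "endpoint",
) -> list[SmoothnessRecord]:
    """Smoothness of every pathway intermediate in the PCA-projected space.

    PCA is fitted once on the union of all pathway members.  ``endpoint``
    mode scores each intermediate X of pathway A..Z as d(A,Z)/(d(A,X)+d(X,Z));
    ``consecutive`` mode scores triplets of consecutive members instead.
    """
    if mode not in ("endpoint", "consecutive"):
        raise ValueError(f"unknown mode {mode!r}")
    members: list[str] = []
    for pid, path in pathways.items():
        if len(path) < 3:
            raise ValueError(f"pathway {pid!r} has fewer than 3 members")
        missing = [k for k in path if k not in table.vectors]
        if missing:
            raise KeyError(f"pathway {pid!r} members missing from table: {missing}")
        members.extend(path)
    keys = sorted(set(members))
    coords = pca_project(table, keys, cfg)
    records = []
    for pid, path in pathways.items():
        if mode == "endpoint":
            a, z = path[0], path[-1]
            triplets = [(a, x, z) for x in path[1:-1]]
        else:
            triplets = [(path[i], path[i + 1], path[i + 2]) for i in range(len(path) - 2)]
        for a, x, z in triplets:
            records.append(
                SmoothnessRecord(
                    pathway_id=pid,
                    intermediate=x,
                    start=a,
                    end=z,
                    smoothness=smoothness_ratio(coords[a], coords[x], coords[z]),
                )
            )
    return records


def paired_t_test(a: Sequence[float], b: Sequence[float], sided: str = "two_sided") -> PairedTestResult:
    """Paired Student t-test on matched observations a_i vs b_i.

    ``sided='greater'`` tests mean(a − b) > 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal-length vectors with n >= 2")
    diffs = a - b
    if diffs.std(ddof=1) == 0:
        raise ValueError("paired t-test undefined: zero variance of differences")
    alternative = {"two_sided": "two-sided", "greater": "greater"}.get(sided)
    if alternative is None:
        raise ValueError(f"unknown sidedness {sided!r}")
    res = stats.ttest_rel(a, b, alternative=alternative)
    return PairedTestResult(
        n=a.size,
        mean_diff=float(diffs.mean()),
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        sided=sided,
    )


def view_coordinates(
    projection: dict[str, np.ndarray], keys: Sequence[str]
) -> list[tuple[str, float, float]]:
    """First two principal-component coordinates per key, for trajectory plots."""
    out = []
    for k in keys:
        vec = projection[k]
        if vec.shape[0] < 2:
            raise ValueError("projection has fewer than 2 components")
        out.append((k, float(vec[0]), float(vec[1])))
    return out


def plot_pathway(
    projection: dict[str, np.ndarray], path: Sequence[str], out_path, title: str = ""
) -> None:
    """Write a 2-D trajectory plot of one pathway (convenience output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = view_coordinates(projection, path)
    xs = [c[1] for c in coords]
    ys = [c[2] for c in coords]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(xs, ys, "-o", color="tab:red")
    for k, x, y in coords:
        ax.annotate(k, (x, y), fontsize=7)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
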