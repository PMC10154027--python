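"""Co-occurrence rank-shift analysis over essential-oil compositions.

Two molecules co-occur when they appear together in at least one natural
substance (essential oil).  For a representation's pairwise distance matrix
over all N molecules, the P = N(N−1)/2 unordered pair distances are ranked
ascending (average ranks on ties), and each label group's rank shift is its
mean rank minus (P+1)/2, the expected rank of a uniformly random pair.
Negative shift means the group sits nearer than chance.  The group-weighted
shifts of the co-occurring and non-co-occurring groups cancel exactly — a
rank-sum conservation identity used as a built-in sanity check.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .representations import DistanceMatrix
from .smoothness import PairedTestResult, paired_t_test

Pair = tuple[str, str]


@dataclass
class OilDataset:
    oils: dict[str, set[str]]

    def __post_init__(self) -> None:
        empty = [name for name, members in self.oils.items() if not members]
        if empty:
            raise ValueError(f"empty oils: {empty[:5]}")

    @property
    def molecules(self) -> list[str]:
        return sorted(set().union(*self.oils.values())) if self.oils else []


@dataclass
class RankShiftResult:
    representation: str
    n_pairs: int
    n_cooccurring: int
    shift_cooccurring: float
    shift_non: float
    ci95_cooccurring: tuple[float, float]
    ci95_non: tuple[float, float]


def _pair_key(a: str, b: str) -> Pair:
    return (a, b) if a <= b else (b, a)


def cooccurrence_labels(oils: OilDataset) -> dict[Pair, bool]:
    """Label every unordered molecule pair: together in >= 1 oil?"""
    molecules = oils.molecules
    if len(molecules) < 2:
        raise ValueError("need at least 2 molecules")
    labels = {_pair_key(a, b): False for a, b in itertools.combinations(molecules, 2)}
    for members in oils.oils.values():
        for a, b in itertools.combinations(sorted(members), 2):
            labels[_pair_key(a, b)] = True
    return labels


def ranked_distances(dm: DistanceMatrix) -> dict[Pair, float]:
    """Ascending 1..P ranks of all unordered pair distances, average ranks on ties."""
    index = {k: i for i, k in enumerate(dm.keys)}
    pairs = [_pair_key(a, b) for a, b in itertools.combinations(dm.keys, 2)]
    dists = np.array([dm.values[index[a], index[b]] for a, b in pairs])
    ranks = stats.rankdata(dists, method="average")
    return dict(zip(pairs, ranks.astype(float)))


def rank_shift(ranks: Mapping[Pair, float], labels: Mapping[Pair, bool], representation: str = "") -> RankShiftResult:
    """Mean rank shift of each label group relative to a random pair.

    shift = mean(group ranks) − (P+1)/2; 95% CI by the normal approximation
    over the group's ranks.
    """
    if set(ranks) != set(labels):
        raise ValueError("ranks and labels cover different pair universes")
    p_total = len(ranks)
    expected = (p_total + 1) / 2
    co = np.array([r for pair, r in ranks.items() if labels[pair]])
    non = np.array([r for pair, r in ranks.items() if not labels[pair]])
    if co.size == 0 or non.size == 0:
        raise ValueError("both label classes must be non-empty")

    def _ci(group: np.ndarray) -> tuple[float, float]:
        shift = group.mean() - expected
        se = group.std(ddof=1) / np.sqrt(group.size) if group.size > 1 else 0.0
        return (float(shift - 1.96 * se), float(shift + 1.96 * se))

    return RankShiftResult(
        representation=representation,
        n_pairs=p_total,
        n_cooccurring=int(co.size),
        shift_cooccurring=float(co.mean() - expected),
        shift_non=float(non.mean() - expected),
        ci95_cooccurring=_ci(co),
        ci95_non=_ci(non),
    )


def compare_rank_shifts(
    table_pairs: Sequence[tuple[str, Mapping[Pair, float]]],
    labels: Mapping[Pair, bool],
) -> dict[tuple[str, str], dict[str, PairedTestResult]]:
    """Paired t-tests of per-pair rank differences between representations.

    For each representation pair, ranks are differenced per molecule pair and
    tested separately over co-occurring and non-co-occurring pairs.
    """
    universe = set(labels)
    for name, ranks in table_pairs:
        if set(ranks) != universe:
            raise ValueError(f"representation {name!r} covers a different pair universe")
    co_pairs = sorted(p for p in universe if labels[p])
    non_pairs = sorted(p for p in universe if not labels[p])
    out: dict[tuple[str, str], dict[str, PairedTestResult]] = {}
    for (name_a, ranks_a), (name_b, ranks_b) in itertools.combinations(table_pairs, 2):
        out[(name_a, name_b)] = {
            "cooccurring": paired_t_test(
                [ranks_a[p] for p in co_pairs], [ranks_b[p] for p in co_pairs]
            ),
            "non_cooccurring": paired_t_test(
                [ranks_a[p] for p in non_pairs], [ranks_b[p] for p in non_pairs]
            ),
        }
    return out


# -- I/O -----------------------------------------------------------------

def read_oils(path) -> OilDataset:
    """Read oils from JSON {oil: [keys]} or two-column CSV (oil, key)."""
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            raw = json.load(fh)
        return OilDataset(oils={name: set(members) for name, members in raw.items()})
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("oil CSV needs columns (oil, key)")
    oil_col, key_col = df.columns[:2]
    oils: dict[str, set[str]] = {}
    for oil, key in zip(df[oil_col], df[key_col]):
        oils.setdefault(str(oil), set()).add(str(key))
    return OilDataset(oils=oils)


def write_oils(oils: OilDataset, path) -> None:
    with open(path, "w") as fh:
        json.dump({name: sorted(members) for name, members in oils.oils.items()}, fh, indent=1)
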