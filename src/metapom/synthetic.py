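"""Seeded generators for desk-scale synthetic study inputs.

Real inputs to this pipeline — a curated reaction database, a trained
molecular embedding, essential-oil composition tables, trial-resolved
calcium traces — are large, licensed or model-dependent.  These generators
produce small substitutes with the statistical structure every stage
assumes, so the full pipeline is testable end to end:

* a directed metabolite graph grown from a root, whose node "structures"
  (count fingerprints) drift by a fixed number of coordinate edits per
  reaction step, so structural distance grows with metabolic distance;
* an embedding table whose pair-level correlation between metabolic
  distance and embedding correlation-distance is tunable by ``rho`` —
  the generator calibrates its structure/noise mixing weight against an
  internal stratified pair sample until the target is met;
* oils as metabolic neighborhoods (balls in the undirected skeleton);
* trial-resolved traces with planted responders;
* feature/label datasets of controllable informativeness.

Every generator is a pure function of its configuration: the same seed
reproduces bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np

from .chem import CountFingerprint, center_rows
from .cooccurrence import OilDataset
from .neural import TrialTraces
from .network import MetabolicNetwork, ReactionRecord, SamplingConfig, build_network, sample_pairs
from .perfindex import EvalDataset
from .representations import RepresentationTable


@dataclass(frozen=True)
class GeneratorConfig:
    n_metabolites: int = 600
    branching: float = 0.25
    edit_rate: int = 4
    rho: float = 0.9
    embed_dim: int = 256
    noise_sd: float = 1.0
    fp_dim: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if self.n_metabolites < 10:
            raise ValueError("need at least 10 metabolites")
        if not 0.0 <= self.branching <= 1.0:
            raise ValueError("branching must lie in [0, 1]")


@dataclass
class SyntheticMetabolome:
    network: MetabolicNetwork
    molecule_fps: dict[str, CountFingerprint]
    pathways: list[list[str]]
    reactions: list[ReactionRecord] = field(default_factory=list)

    @property
    def keys(self) -> list[str]:
        return sorted(self.network.nodes)


def make_metabolome(cfg: GeneratorConfig) -> SyntheticMetabolome:
    """Grow a directed metabolite tree with fingerprint drift along edges.

    Each new metabolite extends the most recently added node with
    probability 1 − branching (long reaction chains), otherwise branches
    from a uniformly chosen existing node.  A product's count fingerprint is
    its parent's with exactly ``edit_rate`` distinct coordinates shifted by
    one (upward when the coordinate is zero), so graph neighbors sit at L1
    distance ``edit_rate``.  Pathways are all maximal root-to-leaf paths.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_metabolites
    keys = [f"M{i:04d}" for i in range(n)]
    root_fp = rng.poisson(2.0, size=cfg.fp_dim).astype(np.int64)
    fps: dict[str, np.ndarray] = {keys[0]: root_fp}
    parent: dict[str, str] = {}
    reactions: list[ReactionRecord] = []
    last = keys[0]
    for i in range(1, n):
        if rng.random() < cfg.branching:
            src = keys[int(rng.integers(i))]
        else:
            src = last
        child = keys[i]
        parent[child] = src
        reactions.append(
            ReactionRecord(reaction_id=f"R{i:04d}", reactants=(src,), products=(child,), species="synthetic")
        )
        fp = fps[src].copy()
        coords = rng.choice(cfg.fp_dim, size=cfg.edit_rate, replace=False)
        for c in coords:
            if fp[c] == 0 or rng.random() < 0.5:
                fp[c] += 1
            else:
                fp[c] -= 1
        fps[child] = fp
        last = child
    net = build_network(reactions, species="synthetic")
    children: dict[str, list[str]] = {}
    for c, p in parent.items():
        children.setdefault(p, []).append(c)
    pathways = []
    for leaf in keys:
        if leaf not in children and leaf in parent:
            path = [leaf]
            while path[-1] in parent:
                path.append(parent[path[-1]])
            pathways.append(path[::-1])
    molecule_fps = {
        k: CountFingerprint(counts=v, dim=cfg.fp_dim, radius=0) for k, v in fps.items()
    }
    return SyntheticMetabolome(network=net, molecule_fps=molecule_fps, pathways=pathways, reactions=reactions)


def fingerprint_table(met: SyntheticMetabolome, name: str = "cfp", metric: str = "l1") -> RepresentationTable:
    """The metabolome's count fingerprints (or their bit supports) as a table."""
    if metric == "l1":
        vectors = {k: fp.counts.astype(float) for k, fp in met.molecule_fps.items()}
    elif metric == "tanimoto":
        vectors = {k: (fp.counts > 0).astype(float) for k, fp in met.molecule_fps.items()}
    else:
        raise ValueError("fingerprint tables support metrics 'l1' and 'tanimoto'")
    return RepresentationTable(name=name, metric=metric, vectors=vectors)


def _pairwise_correlation_distance(mat: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
    """Vectorized correlation distances for index pairs over a centered table."""
    mat = center_rows(mat)
    rows = mat - mat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(rows, axis=1)
    num = np.einsum("ij,ij->i", rows[idx_a], rows[idx_b])
    return 1.0 - num / (norms[idx_a] * norms[idx_b])


#: Step angle of the spherical walk (radians).  At this angle the clean
#: (noise-free) pair-level correlation between metabolic distance and
#: embedding correlation-distance plateaus around 0.96 for the default
#: metabolome; larger angles saturate the correlation decay too quickly.
WALK_STEP_ANGLE = 0.52


def _spherical_walk_base(met: SyntheticMetabolome, dim: int, alpha: float, rng) -> np.ndarray:
    """Unit vectors drifting along the metabolite tree by a fixed angle per step.

    Each reaction step rotates the parent's vector by ``alpha`` toward a
    fresh direction orthogonal to the entire ancestor path, so the inner
    product between an ancestor and a descendant separated by d reactions is
    exactly cos(alpha)**d: correlation decays smoothly and almost linearly
    with metabolic distance, with no crosstalk noise between steps.
    """
    keys = met.keys
    parent = {v: u for u, v in met.network.graph.edges()}
    roots = [k for k in keys if k not in parent]
    index = {k: i for i, k in enumerate(keys)}
    out = np.empty((len(keys), dim))

    def unit(v: np.ndarray) -> np.ndarray:
        return v / np.linalg.norm(v)

    basis: dict[str, list[np.ndarray]] = {}
    for root in roots:
        vec = unit(rng.normal(size=dim))
        out[index[root]] = vec
        basis[root] = [vec]
    # children were appended after their parents, so insertion order works
    for k in keys:
        if k in basis:
            continue
        p = parent[k]
        w = rng.normal(size=dim)
        for b in basis[p]:
            w -= (w @ b) * b
        w = unit(w)
        vec = np.cos(alpha) * out[index[p]] + np.sin(alpha) * w
        out[index[k]] = vec
        basis[k] = basis[p] + [w]
    return out


def make_embedding_table(
    met: SyntheticMetabolome, cfg: GeneratorConfig, name: str = "pom_synthetic"
) -> RepresentationTable:
    """Synthetic embedding whose metabolic correlation is tunable by rho.

    The structured part is a spherical walk along the metabolite tree (see
    :func:`_spherical_walk_base`), whose correlation distance grows nearly
    linearly with graph distance.  Rows are mixed with independent Gaussian
    noise; the mixing weight is found by bisection so that the Pearson
    correlation between metabolic distance and embedding correlation
    distance, measured on an internal stratified pair sample, hits rho.
    With rho = 1 or noise_sd = 0 the clean walk is returned unmixed; with
    rho = 0 the table is pure noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7_901]))
    keys = met.keys
    n = len(keys)
    dim = cfg.embed_dim

    noise = rng.normal(0.0, cfg.noise_sd if cfg.noise_sd > 0 else 1.0, size=(n, dim))
    noise = _standardize_rows(noise)

    if cfg.rho == 0.0:
        vectors = {k: noise[i] for i, k in enumerate(keys)}
        return RepresentationTable(name=name, metric="correlation_centered", vectors=vectors)

    base = _spherical_walk_base(met, dim, WALK_STEP_ANGLE, rng)
    base = _standardize_rows(base)

    if cfg.rho >= 1.0 or cfg.noise_sd == 0.0:
        mix = base
    else:
        # calibrate the noise weight against an internal stratified sample
        idx_a, idx_b, dists = _internal_pair_sample(met, keys)
        target = cfg.rho

        def measured_r(lam: float) -> float:
            m = (1.0 - lam) * base + lam * noise
            y = _pairwise_correlation_distance(m, idx_a, idx_b)
            return float(np.corrcoef(dists, y)[0, 1])

        lo, hi = 0.0, 1.0
        for _ in range(20):
            mid = 0.5 * (lo + hi)
            if measured_r(mid) > target:
                lo = mid
            else:
                hi = mid
        lam = 0.5 * (lo + hi)
        mix = (1.0 - lam) * base + lam * noise

    vectors = {k: mix[i].copy() for i, k in enumerate(keys)}
    return RepresentationTable(name=name, metric="correlation_centered", vectors=vectors)


def _standardize_rows(mat: np.ndarray) -> np.ndarray:
    rows = mat - mat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(rows, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return rows / norms


def _internal_pair_sample(
    met: SyntheticMetabolome, keys: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    cfg = SamplingConfig(pairs_per_distance=50, d_min=1, d_max=12, seed=104_729, strict=False)
    pairs = sample_pairs(met.network, keys, cfg)
    index = {k: i for i, k in enumerate(keys)}
    idx_a = np.array([index[p.key_a] for p in pairs])
    idx_b = np.array([index[p.key_b] for p in pairs])
    dists = np.array([p.metabolic_distance for p in pairs], dtype=float)
    return idx_a, idx_b, dists


def make_oils(
    met: SyntheticMetabolome,
    n_oils: int = 30,
    radius: int = 2,
    seed: int = 0,
    max_retries: int = 200,
) -> OilDataset:
    """Oils as metabolic neighborhoods: balls of the undirected skeleton.

    Each oil collects every metabolite within ``radius`` undirected steps of
    a randomly drawn anchor; oils with fewer than two members are redrawn.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    rng = np.random.default_rng(seed)
    und = met.network.graph.to_undirected(as_view=True)
    keys = met.keys
    oils: dict[str, set[str]] = {}
    attempts = 0
    while len(oils) < n_oils:
        if attempts > max_retries + n_oils:
            raise RuntimeError("could not draw enough oils with >= 2 members")
        attempts += 1
        anchor = keys[int(rng.integers(len(keys)))]
        members = set(nx.single_source_shortest_path_length(und, anchor, cutoff=radius))
        if len(members) < 2:
            continue
        oils[f"oil_{len(oils):03d}"] = members
    return OilDataset(oils=oils)


def make_neural(
    odorants: Sequence[str],
    neurons: Sequence[str],
    responders: Iterable[tuple[str, str]],
    n_trials: int = 10,
    frames: int = 100,
    onset: int = 40,
    amplitude: float = 5.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> dict[tuple[str, str], TrialTraces]:
    """Trial-resolved traces with planted responders.

    Non-responders are pure Gaussian baseline noise; responders additionally
    receive a post-onset ramp (5 frames) to a plateau of the given amplitude.
    SNR is amplitude / noise_sd.
    """
    rng = np.random.default_rng(seed)
    responders = set(responders)
    out: dict[tuple[str, str], TrialTraces] = {}
    ramp = np.clip((np.arange(frames) - onset + 1) / 5.0, 0.0, 1.0)
    ramp[: onset] = 0.0
    for od in odorants:
        for nr in neurons:
            traces = rng.normal(0.0, noise_sd, size=(n_trials, frames))
            if (od, nr) in responders:
                traces += amplitude * ramp
            out[(od, nr)] = TrialTraces(frames=traces, onset=onset)
    return out


def make_eval_dataset(
    n: int,
    informative: bool,
    task: str,
    table: RepresentationTable,
    seed: int = 0,
    name: Optional[str] = None,
    noise_sd: float = 0.0,
) -> EvalDataset:
    """Feature/label dataset of controllable informativeness.

    Informative targets are a (thresholded, for classification) function of
    the single highest-variance representation coordinate plus optional
    noise; uninformative targets are independent of the features.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    all_keys = sorted(table.vectors)
    if n > len(all_keys):
        raise ValueError(f"table has only {len(all_keys)} keys, requested {n}")
    keys = [all_keys[i] for i in sorted(rng.choice(len(all_keys), size=n, replace=False))]
    mat = np.vstack([table.vectors[k] for k in keys])
    informative_col = int(np.argmax(mat.var(axis=0)))
    score = mat[:, informative_col]
    score = (score - score.mean()) / (score.std() or 1.0)
    if informative:
        y = score + rng.normal(0.0, noise_sd, size=n)
    else:
        y = rng.normal(0.0, 1.0, size=n)
    if task == "classification":
        y = (y > np.median(y)).astype(int)
        # guarantee both classes even under ties
        if y.sum() in (0, n):
            y[: n // 2] = 1 - y[: n // 2]
    targets = pd.DataFrame({"target": y})
    return EvalDataset(
        name=name or ("informative" if informative else "uninformative"),
        keys=keys,
        targets=targets,
        task=task,
    )


def smooth_table_along_pathways(
    table: RepresentationTable, pathways: Sequence[Sequence[str]], weight: float = 0.8
) -> RepresentationTable:
    """A smoothed copy of a table: pathway intermediates pulled toward the
    chord between their pathway's endpoints.

    Used to exercise the smoothness discrimination property: the smoothed
    table must score higher pathway smoothness than the original.
    """
    vectors = {k: v.astype(float).copy() for k, v in table.vectors.items()}
    for path in pathways:
        if len(path) < 3:
            continue
        a = table.vectors[path[0]].astype(float)
        z = table.vectors[path[-1]].astype(float)
        m = len(path) - 1
        for i, key in enumerate(path[1:-1], start=1):
            on_chord = a + (z - a) * (i / m)
            vectors[key] = (1.0 - weight) * vectors[key] + weight * on_chord
    return RepresentationTable(name=f"{table.name}_smoothed", metric=table.metric, vectors=vectors)
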