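"""Directed metabolite graphs, shortest-path metabolic distance and pair sampling.

A metabolic network has one node per metabolite and a directed edge from
every reactant to every product of every documented reaction.  The metabolic
distance between two metabolites is the length of the shortest directed path
— the minimum number of reactions converting one into the other.  Because
short distances vastly outnumber long ones in sparse reaction graphs, the
correlation stage consumes a stratified sample: a fixed number of ordered
odorant pairs drawn uniformly at each distance d = d_min..d_max.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReactionRecord:
    reaction_id: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    species: str = ""

    def __post_init__(self) -> None:
        if not self.reactants or not self.products:
            raise ValueError(f"reaction {self.reaction_id!r}: reactants and products must be non-empty")


@dataclass(frozen=True)
class SamplingConfig:
    pairs_per_distance: int = 50
    d_min: int = 1
    d_max: int = 12
    seed: int = 0
    strict: bool = False

    def __post_init__(self) -> None:
        if self.d_min > self.d_max or self.d_min < 1 or self.pairs_per_distance < 1:
            raise ValueError("require 1 <= d_min <= d_max and pairs_per_distance >= 1")


@dataclass
class PairSample:
    key_a: str
    key_b: str
    metabolic_distance: int
    rep_distances: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.key_a == self.key_b or self.metabolic_distance < 1:
            raise ValueError("pair must join two distinct metabolites at distance >= 1")


class MetabolicNetwork:
    """Directed metabolite graph with reaction-labeled edges.

    Parallel edges from distinct reactions are recorded but count once for
    distance purposes (the underlying simple digraph is what is traversed).
    """

    def __init__(self, species: str = "") -> None:
        self.species = species
        self.graph = nx.DiGraph()

    # -- construction ----------------------------------------------------
    def add_reaction(self, reaction: ReactionRecord) -> None:
        for r in reaction.reactants:
            for p in reaction.products:
                if self.graph.has_edge(r, p):
                    self.graph[r][p]["reactions"].add(reaction.reaction_id)
                else:
                    self.graph.add_edge(r, p, reactions={reaction.reaction_id})

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str, str]]:
        return {
            (u, v, rid)
            for u, v, data in self.graph.edges(data=True)
            for rid in data["reactions"]
        }

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    # -- distances -------------------------------------------------------
    def metabolic_distance(self, a: str, b: str) -> Optional[int]:
        """Shortest directed path length a -> b, or None if unreachable."""
        for k in (a, b):
            if k not in self.graph:
                raise KeyError(f"unknown metabolite key {k!r}")
        try:
            return int(nx.shortest_path_length(self.graph, a, b))
        except nx.NetworkXNoPath:
            return None

    def distances_from(self, source: str, cutoff: Optional[int] = None) -> dict[str, int]:
        """BFS distances from ``source`` to all reachable nodes (optionally capped)."""
        if source not in self.graph:
            raise KeyError(f"unknown metabolite key {source!r}")
        return {k: int(v) for k, v in nx.single_source_shortest_path_length(self.graph, source, cutoff=cutoff).items()}


def build_network(reactions: Iterable[ReactionRecord], species: str = "") -> MetabolicNetwork:
    """Assemble the directed metabolite graph of one species' reactions."""
    net = MetabolicNetwork(species=species)
    for reaction in reactions:
        net.add_reaction(reaction)
    return net


def select_networks(nets: Sequence[MetabolicNetwork], min_size: int = 100) -> list[MetabolicNetwork]:
    """Networks with at least ``min_size`` metabolites, largest first."""
    kept = [n for n in nets if len(n) >= min_size]
    return sorted(kept, key=len, reverse=True)


def pairs_by_distance(
    net: MetabolicNetwork, odorous: Iterable[str], d_min: int, d_max: int
) -> dict[int, list[tuple[str, str]]]:
    """All ordered odorous pairs at each exact directed distance in [d_min, d_max]."""
    odorous = sorted(set(odorous))
    unknown = [k for k in odorous if k not in net.graph]
    if unknown:
        raise KeyError(f"odorous keys not in network: {unknown[:5]}")
    odor_set = set(odorous)
    strata: dict[int, list[tuple[str, str]]] = {d: [] for d in range(d_min, d_max + 1)}
    for a in odorous:
        for b, d in net.distances_from(a, cutoff=d_max).items():
            if d_min <= d and b != a and b in odor_set:
                strata[d].append((a, b))
    return strata


def sample_pairs(
    net: MetabolicNetwork, odorous: Iterable[str], cfg: SamplingConfig
) -> list[PairSample]:
    """Stratified uniform sample of ordered odorant pairs, one stratum per distance.

    Each stratum d in [d_min, d_max] receives min(pairs_per_distance,
    available) pairs drawn without replacement with the seeded generator.
    With ``strict`` set, an empty stratum raises; otherwise it is logged and
    skipped so small networks remain usable.
    """
    strata = pairs_by_distance(net, odorous, cfg.d_min, cfg.d_max)
    rng = np.random.default_rng(cfg.seed)
    out: list[PairSample] = []
    for d in range(cfg.d_min, cfg.d_max + 1):
        avail = strata[d]
        if not avail:
            if cfg.strict:
                raise ValueError(f"no odorant pairs available at metabolic distance {d}")
            logger.warning("no odorant pairs available at metabolic distance %d; stratum empty", d)
            continue
        n_take = min(cfg.pairs_per_distance, len(avail))
        if n_take < cfg.pairs_per_distance:
            logger.warning(
                "stratum d=%d underfilled: %d of %d requested pairs", d, n_take, cfg.pairs_per_distance
            )
        idx = rng.choice(len(avail), size=n_take, replace=False)
        out.extend(PairSample(key_a=avail[i][0], key_b=avail[i][1], metabolic_distance=d) for i in sorted(idx))
    return out


# -- I/O -----------------------------------------------------------------

def read_reaction_table(path) -> list[ReactionRecord]:
    """Read a TSV with columns reaction_id, species, reactants, products.

    Reactants/products are semicolon-separated molecule keys or SMILES.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"reaction_id", "species", "reactants", "products"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"reaction table missing columns: {sorted(missing)}")
    return [
        ReactionRecord(
            reaction_id=row.reaction_id,
            species=row.species,
            reactants=tuple(s for s in row.reactants.split(";") if s),
            products=tuple(s for s in row.products.split(";") if s),
        )
        for row in df.itertuples()
    ]


def read_pathway_table(path) -> dict[str, list[str]]:
    """Read a TSV with columns pathway_id, species, members (semicolon-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"pathway_id", "members"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pathway table missing columns: {sorted(missing)}")
    return {row.pathway_id: [m for m in row.members.split(";") if m] for row in df.itertuples()}


def write_reaction_table(reactions: Sequence[ReactionRecord], path) -> None:
    pd.DataFrame(
        {
            "reaction_id": [r.reaction_id for r in reactions],
            "species": [r.species for r in reactions],
            "reactants": [";".join(r.reactants) for r in reactions],
            "products": [";".join(r.products) for r in reactions],
        }
    ).to_csv(path, sep="\t", index=False)
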