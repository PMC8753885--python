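"""Dense-module mining: MCODE vertex weighting and complex prediction.

Re-implementation of the published MCODE algorithm (vertex weighting by
core-clustering coefficient, greedy seeded expansion, haircut and k-core
post-filters). Tie-breaking is lexicographic on gene id everywhere so runs
are deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd


@dataclass
class MCODEParams:
    degree_cutoff: int = 2
    k_core: int = 3
    node_score_cutoff: float = 0.2
    haircut: bool = True
    fluff: bool = False
    min_module_size: int = 4

    def __post_init__(self) -> None:
        if not (0.0 <= self.node_score_cutoff <= 1.0):
            raise ValueError("node_score_cutoff must lie in [0, 1]")
        if self.k_core < 2:
            raise ValueError("k_core must be >= 2")
        if self.fluff:
            raise NotImplementedError("fluff post-processing is not implemented")


@dataclass
class Module:
    """A mined gene set with its induced subgraph."""

    module_id: str
    genes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    seed_gene: str
    score: float
    contrast_tags: frozenset[str] = frozenset()

    @property
    def size(self) -> int:
        return len(self.genes)

    def sorted_genes(self) -> list[str]:
        return sorted(self.genes)


def _density(n_nodes: int, n_edges: int) -> float:
    if n_nodes < 2:
        return 0.0
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def vertex_weights(net: nx.Graph, degree_cutoff: int = 2) -> dict[str, float]:
    """MCODE vertex weight: highest-core number of the closed neighbourhood
    times the density of that highest k-core. Nodes below the degree cutoff
    get weight 0."""
    weights: dict[str, float] = {}
    for v in net.nodes:
        if net.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        nbhd = net.subgraph(set(net[v]) | {v})
        core_num = nx.core_number(nbhd)
        k_max = max(core_num.values())
        core_nodes = [u for u, c in core_num.items() if c >= k_max]
        core = nbhd.subgraph(core_nodes)
        weights[v] = k_max * _density(core.number_of_nodes(), core.number_of_edges())
    return weights


def predict_complexes(
    net: nx.Graph,
    weights: dict[str, float] | None = None,
    params: MCODEParams | None = None,
) -> list[Module]:
    """Greedy complex prediction.

    Seeds are taken in descending weight order (ties broken by gene id)
    among unassigned nodes; expansion adds unassigned neighbours whose
    weight is at least ``(1 - node_score_cutoff) * seed_weight``. A node is
    assigned to at most one complex. Complexes lacking a 2-core are
    discarded; the haircut removes singly-connected nodes; surviving
    complexes must contain a k-core of order ``k_core`` and at least
    ``min_module_size`` nodes. Output is sorted by score (density * size),
    descending.
    """
    params = params or MCODEParams()
    if weights is None:
        weights = vertex_weights(net, params.degree_cutoff)
    if net.number_of_nodes() == 0:
        return []

    assigned: set[str] = set()
    raw_complexes: list[tuple[str, set[str]]] = []
    for seed in sorted(net.nodes, key=lambda v: (-weights[v], v)):
        if seed in assigned or weights[seed] <= 0.0:
            continue
        threshold = (1.0 - params.node_score_cutoff) * weights[seed]
        members = {seed}
        frontier = [seed]
        while frontier:
            nxt: list[str] = []
            for u in sorted(frontier):
                for w in sorted(net[u]):
                    if w in members or w in assigned:
                        continue
                    if weights[w] >= threshold:
                        members.add(w)
                        nxt.append(w)
            frontier = nxt
        assigned |= members
        raw_complexes.append((seed, members))

    modules: list[Module] = []
    for seed, members in raw_complexes:
        sub = net.subgraph(members)
        if nx.k_core(sub, 2).number_of_nodes() == 0:
            continue
        if params.haircut:
            keep = [v for v in sub.nodes if sub.degree(v) > 1]
            sub = net.subgraph(keep)
        if nx.k_core(sub, params.k_core).number_of_nodes() == 0:
            continue
        if sub.number_of_nodes() < params.min_module_size:
            continue
        score = _density(sub.number_of_nodes(), sub.number_of_edges()) * sub.number_of_nodes()
        modules.append(
            Module(
                module_id="",
                genes=frozenset(sub.nodes),
                edges=frozenset(tuple(sorted(e)) for e in sub.edges),
                seed_gene=seed,
                score=score,
            )
        )
    modules.sort(key=lambda m: (-m.score, m.sorted_genes()))
    return [
        Module(f"M{i + 1}", m.genes, m.edges, m.seed_gene, m.score, m.contrast_tags)
        for i, m in enumerate(modules)
    ]


def classify_initial(
    modules: list[Module], degs: dict[str, set[str]]
) -> list[Module]:
    """Tag each module with every contrast for which it holds at least one
    DEG; modules with no tag are dropped from the initial sets."""
    tagged = []
    for m in modules:
        tags = frozenset(c for c, genes in degs.items() if m.genes & genes)
        if tags:
            tagged.append(Module(m.module_id, m.genes, m.edges, m.seed_gene,
                                 m.score, tags))
    return tagged


# -------------------------------------------------------------------- I/O


def modules_to_json(modules: list[Module], path) -> None:
    data = [
        {
            "module_id": m.module_id,
            "genes": m.sorted_genes(),
            "edges": sorted(map(list, m.edges)),
            "seed": m.seed_gene,
            "score": m.score,
            "tags": sorted(m.contrast_tags),
        }
        for m in modules
    ]
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)


def modules_from_json(path) -> list[Module]:
    with open(path) as fh:
        data = json.load(fh)
    return [
        Module(
            module_id=rec["module_id"],
            genes=frozenset(rec["genes"]),
            edges=frozenset(tuple(e) for e in rec["edges"]),
            seed_gene=rec["seed"],
            score=rec["score"],
            contrast_tags=frozenset(rec["tags"]),
        )
        for rec in data
    ]


def modules_summary(modules: list[Module]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "module_id": [m.module_id for m in modules],
            "n_genes": [m.size for m in modules],
            "n_edges": [len(m.edges) for m in modules],
            "seed": [m.seed_gene for m in modules],
            "score": [m.score for m in modules],
            "tags": [",".join(sorted(m.contrast_tags)) for m in modules],
        }
    )
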