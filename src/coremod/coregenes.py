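"""Shortest-path core-gene prioritization.

Each risk-module gene x is scored by B(x), the number of known-disease-gene
pairs (s, t) for which x lies on at least one shortest s-t path; the top
upper quartile of candidates (genes with B > 0) are the core genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class KnownGeneSet:
    all_known: set[str]
    in_network: set[str]

    @classmethod
    def from_network(cls, known, net: nx.Graph) -> "KnownGeneSet":
        all_known = set(known)
        in_net = all_known & set(net.nodes)
        dropped = all_known - in_net
        if dropped:
            logger.warning("%d known gene(s) absent from the network: %s",
                           len(dropped), sorted(dropped)[:10])
        return cls(all_known=all_known, in_network=in_net)

    @classmethod
    def from_txt(cls, path, net: nx.Graph) -> "KnownGeneSet":
        with open(path) as fh:
            genes = {line.strip() for line in fh if line.strip()}
        return cls.from_network(genes, net)


@dataclass
class CoreGeneScore:
    gene_id: str
    B: int
    rank: int = 0
    is_candidate: bool = False
    is_core: bool = False


def pair_linkage_scores(
    net: nx.Graph, module_genes, known: KnownGeneSet
) -> list[CoreGeneScore]:
    """B(x) for every module gene.

    x lies on a shortest s-t geodesic iff dist(s,x) + dist(x,t) = dist(s,t)
    (unweighted hop distances). Disconnected known pairs contribute 0;
    genes with B > 0 are candidates. Output sorted by B descending, then
    gene id.
    """
    if len(known.in_network) < 2:
        raise ValueError("need at least 2 known genes in the network")
    module_genes = sorted(set(module_genes))
    dist = {s: nx.single_source_shortest_path_length(net, s)
            for s in known.in_network}
    counts = {x: 0 for x in module_genes}
    known_sorted = sorted(known.in_network)
    for i, s in enumerate(known_sorted):
        ds = dist[s]
        for t in known_sorted[i + 1:]:
            if t not in ds:
                continue  # disconnected pair
            dst = ds[t]
            dt = dist[t]
            for x in module_genes:
                if x == s or x == t:
                    continue
                if x in ds and x in dt and ds[x] + dt[x] == dst:
                    counts[x] += 1
    scores = [CoreGeneScore(gene_id=x, B=counts[x], is_candidate=counts[x] > 0)
              for x in module_genes]
    scores.sort(key=lambda sc: (-sc.B, sc.gene_id))
    for rank, sc in enumerate(scores, start=1):
        sc.rank = rank
    return scores


def select_core(scores: list[CoreGeneScore], quartile: float = 0.25) -> set[str]:
    """Top upper quartile of candidates by B, boundary ties included.

    Candidates are genes with B > 0; with fewer than 4 candidates all of
    them are returned (with a warning). The cut keeps candidates of rank
    <= floor(quartile * n) plus any candidate tied with the boundary B.
    """
    candidates = sorted((sc for sc in scores if sc.is_candidate),
                        key=lambda sc: (-sc.B, sc.gene_id))
    n = len(candidates)
    if n == 0:
        logger.warning("no candidate genes lie on known-gene geodesics")
        return set()
    if n < 4:
        logger.warning("only %d candidate gene(s); returning all of them", n)
        for sc in candidates:
            sc.is_core = True
        return {sc.gene_id for sc in candidates}
    cut = max(int(math.floor(quartile * n)), 1)
    boundary_b = candidates[cut - 1].B
    core = {sc.gene_id for pos, sc in enumerate(candidates, start=1)
            if pos <= cut or sc.B == boundary_b}
    for sc in scores:
        sc.is_core = sc.gene_id in core
    return core


def scores_to_frame(scores: list[CoreGeneScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in scores],
            "B": [s.B for s in scores],
            "rank": [s.rank for s in scores],
            "is_candidate": [s.is_candidate for s in scores],
            "is_core": [s.is_core for s in scores],
        }
    )
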