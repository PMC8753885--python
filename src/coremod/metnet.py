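"""Gene-network reconstruction from a reaction table.

Two genes are linked when the product of the reaction catalysed by one is
the substrate of the reaction catalysed by the other, excluding currency
metabolites (H2O, CO2, ADP, ...) whose ubiquity would create spurious hubs.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: Open-ended default; the substrate-product chaining rule skips these.
DEFAULT_CURRENCY = frozenset(
    {"h2o", "co2", "adp", "atp", "pi", "h", "nad", "nadh",
     "nadp", "nadph", "coa", "ppi"}
)

_COMPARTMENT_RE = re.compile(r"\[[a-z0-9]+\]$", re.IGNORECASE)


def normalize_metabolite(met: str, strip_compartments: bool = True) -> str:
    """Lower-case a metabolite id, optionally stripping a trailing
    compartment suffix such as ``[c]`` or ``[m]``."""
    met = met.strip()
    if strip_compartments:
        met = _COMPARTMENT_RE.sub("", met)
    return met.lower()


@dataclass
class Reaction:
    reaction_id: str
    substrates: list[str]
    products: list[str]
    genes: list[str]
    reversible: bool = False


@dataclass
class ReactionTable:
    reactions: list[Reaction]

    def __post_init__(self) -> None:
        for r in self.reactions:
            if not r.reaction_id:
                raise ValueError("reaction with empty id")

    def __len__(self) -> int:
        return len(self.reactions)

    def gene_universe(self) -> set[str]:
        return {g for r in self.reactions for g in r.genes}

    # ------------------------------------------------------------------ I/O

    def to_tsv(self, path) -> None:
        rows = [
            {
                "reaction_id": r.reaction_id,
                "substrates": ";".join(r.substrates),
                "products": ";".join(r.products),
                "genes": ";".join(r.genes),
                "reversible": int(r.reversible),
            }
            for r in self.reactions
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ReactionTable":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        reactions = []
        for _, row in df.iterrows():
            reactions.append(
                Reaction(
                    reaction_id=row["reaction_id"],
                    substrates=[m for m in row["substrates"].split(";") if m],
                    products=[m for m in row["products"].split(";") if m],
                    genes=[g for g in row["genes"].split(";") if g],
                    reversible=bool(int(row["reversible"])) if "reversible" in row and row["reversible"] != "" else False,
                )
            )
        return cls(reactions)

    @classmethod
    def from_json(cls, path) -> "ReactionTable":
        with open(path) as fh:
            data = json.load(fh)
        return cls([Reaction(**rec) for rec in data])


def build_network(
    rt: ReactionTable,
    currency: frozenset[str] | set[str] = DEFAULT_CURRENCY,
    strip_compartments: bool = True,
    intra_reaction_cliques: bool = False,
) -> nx.Graph:
    """Reconstruct the undirected gene-gene network.

    For every ordered reaction pair (R1, R2) whose products(R1) and
    substrates(R2) share a non-currency metabolite, every gene of R1 is
    linked to every gene of R2 (self-pairs skipped). Reversible reactions
    contribute both orientations. All genes appear as nodes even when
    isolated. Genes within one reaction are *not* linked unless
    *intra_reaction_cliques* is set.
    """
    if not rt.reactions:
        raise ValueError("empty reaction table")
    currency_norm = {normalize_metabolite(m, strip_compartments) for m in currency}

    def usable(mets: list[str]) -> set[str]:
        return {
            n for m in mets
            if (n := normalize_metabolite(m, strip_compartments)) not in currency_norm
        }

    net = nx.Graph()
    prod_sets, subs_sets = [], []
    for r in rt.reactions:
        if not r.genes:
            logger.info("reaction %s has no genes; contributes nothing", r.reaction_id)
        net.add_nodes_from(r.genes)
        subs, prods = usable(r.substrates), usable(r.products)
        if r.reversible:
            subs, prods = subs | prods, subs | prods
        subs_sets.append(subs)
        prod_sets.append(prods)
    if net.number_of_nodes() == 0:
        raise ValueError("reaction table has an empty gene universe")

    # index: metabolite -> reactions consuming it (as substrate)
    consumers: dict[str, list[int]] = {}
    for j, subs in enumerate(subs_sets):
        for m in subs:
            consumers.setdefault(m, []).append(j)
    for i, prods in enumerate(prod_sets):
        hit: set[int] = set()
        for m in prods:
            hit.update(consumers.get(m, ()))
        hit.discard(i)
        for j in hit:
            for g1 in rt.reactions[i].genes:
                for g2 in rt.reactions[j].genes:
                    if g1 != g2:
                        net.add_edge(g1, g2)
    if intra_reaction_cliques:
        for r in rt.reactions:
            for a in r.genes:
                for b in r.genes:
                    if a < b:
                        net.add_edge(a, b)
    return net


def annotate_degs(
    net: nx.Graph, degs: dict[str, set[str]]
) -> dict[str, set[str]]:
    """Per contrast, the DEGs that are present among the network's nodes."""
    nodes = set(net.nodes)
    return {contrast: set(genes) & nodes for contrast, genes in degs.items()}


def write_edge_list(net: nx.Graph, path) -> None:
    rows = [{"gene1": a, "gene2": b} for a, b in sorted(map(sorted, net.edges()))]
    df = pd.DataFrame(rows, columns=["gene1", "gene2"])
    df.to_csv(path, sep="\t", index=False)
    iso = [n for n in net.nodes if net.degree(n) == 0]
    if iso:
        logger.info("edge list omits %d isolated nodes", len(iso))


def read_edge_list(path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t", dtype=str)
    g = nx.Graph()
    g.add_edges_from(df.itertuples(index=False, name=None))
    return g
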