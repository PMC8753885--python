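"""MRF-based module score with mutual-information weighting.

The score rewards the expression-difference mass of a module's DEGs
(scaled by sqrt of the module size) and penalises degree-normalised
expression-difference discrepancy between adjacent non-DEGs, weighted by
their mutual information. The Gibbs-distribution constants T and K only
normalise the implied joint probability and never enter the score; they
are carried for documentation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from coremod.prep import ExpressionDataset

logger = logging.getLogger(__name__)

E_CLIP_HIGH = 8.2
P_FLOOR = 1e-16


@dataclass
class MRFScore:
    module_id: str
    mrfms: float
    contrast: tuple[str, str]
    term1: float
    term2: float


def expression_difference(
    gene: str,
    ds: ExpressionDataset,
    contrast: tuple[str, str],
    transform: str = "normal_quantile",
) -> float:
    """Per-gene expression difference E between the two contrast states.

    Default transform: Welch two-sample t-test p-value p, then
    E = Phi^{-1}(1 - p) clipped to [0, 8.2] (p clipped away from 0/1).
    The alternative ``"abs_t"`` transform returns |t| directly.
    """
    s1, s2 = contrast
    x = ds.submatrix([gene], s1)[0]
    y = ds.submatrix([gene], s2)[0]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both states need >= 2 samples")
    if x.var() == 0.0 and y.var() == 0.0:
        if x.mean() == y.mean():
            return 0.0
        t_val, p = np.inf, P_FLOOR
    else:
        t_val, p = stats.ttest_ind(y, x, equal_var=False)
    if transform == "abs_t":
        return float(min(abs(t_val), E_CLIP_HIGH))
    if transform != "normal_quantile":
        raise ValueError(f"unknown transform {transform!r}")
    p = float(np.clip(p, P_FLOOR, 1.0 - P_FLOOR))
    e = stats.norm.ppf(1.0 - p)
    return float(np.clip(e, 0.0, E_CLIP_HIGH))


def mutual_information(x, y, n_bins: int | None = None) -> float:
    """Plug-in mutual information (bits) on an equal-frequency
    discretization with *n_bins* bins per variable.

    Default n_bins is ceil(log2 n) + 1. Constant vectors give 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0
    if n_bins is None:
        n_bins = int(math.ceil(math.log2(n))) + 1
    n_bins = min(n_bins, n)

    def discretize(v: np.ndarray) -> np.ndarray:
        ranks = np.argsort(np.argsort(v, kind="stable"), kind="stable")
        return (ranks * n_bins) // n

    bx, by = discretize(x), discretize(y)
    joint = np.zeros((n_bins, n_bins))
    np.add.at(joint, (bx, by), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (px @ py)[nz])))


@dataclass
class MRFModel:
    """Everything mrfms needs, precomputed for one contrast.

    Caches E values and pairwise MI so permutation draws reuse them.
    Degrees come from the full network, never the module subgraph.
    """

    net: nx.Graph
    ds: ExpressionDataset
    contrast: tuple[str, str]
    deg_genes: set[str]
    e_transform: str = "normal_quantile"
    mi_bins: int | None = None
    mi_samples: str = "pooled"  # or "first"/"second" state only
    g2_pairs: str = "edges"  # or "all" non-DEG pairs
    _e_cache: dict[str, float] = field(default_factory=dict, repr=False)
    _mi_cache: dict[tuple[str, str], float] = field(default_factory=dict, repr=False)

    def E(self, gene: str) -> float:
        if gene not in self._e_cache:
            if not self.ds.has_gene(gene):
                raise KeyError(f"no expression for gene {gene!r}")
            self._e_cache[gene] = expression_difference(
                gene, self.ds, self.contrast, self.e_transform)
        return self._e_cache[gene]

    def degree(self, gene: str) -> int:
        if gene not in self.net:
            raise KeyError(f"gene {gene!r} not in network")
        return self.net.degree(gene)

    def _mi_columns(self) -> list[int]:
        s1, s2 = self.contrast
        if self.mi_samples == "pooled":
            return self.ds.samples_in_state(s1) + self.ds.samples_in_state(s2)
        if self.mi_samples == "first":
            return self.ds.samples_in_state(s1)
        if self.mi_samples == "second":
            return self.ds.samples_in_state(s2)
        raise ValueError(f"unknown mi_samples {self.mi_samples!r}")

    def MI(self, u: str, v: str) -> float:
        key = (u, v) if u <= v else (v, u)
        if key not in self._mi_cache:
            cols = self._mi_columns()
            x = self.ds.gene_rows([key[0]])[0][cols]
            y = self.ds.gene_rows([key[1]])[0][cols]
            self._mi_cache[key] = mutual_information(x, y, self.mi_bins)
        return self._mi_cache[key]


def mrfms(module_genes, model: MRFModel, module_id: str = "") -> MRFScore:
    """MRF module score.

    term1 = g^(-1/2) * sum of E over the module's DEGs; term2 = (1/b) * sum
    over induced module edges joining two non-DEGs of
    (E_v/sqrt(d_v) - E_z/sqrt(d_z))^2 * MI(v, z), with b the count of all
    induced module edges. mrfms = term1 - term2 (equivalently -F(E)).
    """
    genes = set(module_genes)
    g = len(genes)
    if g < 1:
        raise ValueError("empty module")
    for gene in sorted(genes):
        if gene not in model.net:
            raise KeyError(f"gene {gene!r} has no degree in the network")
    g1 = genes & model.deg_genes
    g2 = genes - g1
    term1 = sum(model.E(u) for u in sorted(g1)) / math.sqrt(g)

    sub = model.net.subgraph(genes)
    b = sub.number_of_edges()
    if model.g2_pairs == "edges":
        pairs = [tuple(sorted(e)) for e in sub.edges
                 if e[0] in g2 and e[1] in g2]
    elif model.g2_pairs == "all":
        g2_sorted = sorted(g2)
        pairs = [(u, v) for i, u in enumerate(g2_sorted) for v in g2_sorted[i + 1:]]
    else:
        raise ValueError(f"unknown g2_pairs {model.g2_pairs!r}")
    term2 = 0.0
    if pairs:
        if b == 0:
            raise ValueError("module has non-DEG pairs but no induced edges")
        acc = 0.0
        for v, z in sorted(pairs):
            ev = model.E(v) / math.sqrt(model.degree(v))
            ez = model.E(z) / math.sqrt(model.degree(z))
            acc += (ev - ez) ** 2 * model.MI(v, z)
        term2 = acc / b
    return MRFScore(module_id=module_id, mrfms=term1 - term2,
                    contrast=model.contrast, term1=term1, term2=term2)


def gibbs_energy(module_genes, model: MRFModel) -> float:
    """F(E), the Gibbs energy of the module's expression-difference field;
    by construction mrfms = -F(E)."""
    genes = set(module_genes)
    g = len(genes)
    g1 = genes & model.deg_genes
    g2 = genes - g1
    t1 = -sum(model.E(u) for u in sorted(g1)) / math.sqrt(g)
    sub = model.net.subgraph(genes)
    b = sub.number_of_edges()
    if model.g2_pairs == "edges":
        pairs = [tuple(sorted(e)) for e in sub.edges if e[0] in g2 and e[1] in g2]
    else:
        g2_sorted = sorted(g2)
        pairs = [(u, v) for i, u in enumerate(g2_sorted) for v in g2_sorted[i + 1:]]
    t2 = 0.0
    if pairs:
        acc = 0.0
        for v, z in sorted(pairs):
            acc += (model.E(v) / math.sqrt(model.degree(v))
                    - model.E(z) / math.sqrt(model.degree(z))) ** 2 * model.MI(v, z)
        t2 = acc / b
    return t1 + t2


def select_risk_modules(
    candidates,
    model: MRFModel,
    n_rand: int,
    rng: np.random.Generator,
    alpha: float = 0.05,
):
    """Run the two permutation nulls with the MRF statistic on each
    candidate module; keep those with both p < alpha.

    Returns ``(risk_module_ids, results)``. Random-set genes have their DEG
    status re-evaluated against the contrast's DEG list via the model.
    """
    from coremod.diffcorr import permutation_pvalues

    results = []
    for m in candidates:
        res = permutation_pvalues(
            m.genes,
            lambda gs: mrfms(gs, model).mrfms,
            model.net,
            n_rand=n_rand,
            rng=rng,
            module_id=m.module_id,
            statistic_name="MRFms",
        )
        results.append(res)
    risk = [r.module_id for r in results
            if r.p_degree < alpha and r.p_size < alpha]
    return risk, results
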