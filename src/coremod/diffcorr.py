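"""Differential-correlation module score W = |H - H'| and permutation nulls.

H is the mean absolute pairwise Pearson correlation of a module's genes in
one sample state, H' the same quantity in the other; modules whose W is
extreme under both a degree-conserved and a size-conserved random-module
null (p = 1 - t/n_rand, t = #{random < observed}) become candidates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from coremod.prep import ExpressionDataset

logger = logging.getLogger(__name__)


@dataclass
class DiffCorrScore:
    module_id: str
    H: float
    H_prime: float
    W: float
    contrast: tuple[str, str]
    n: int
    m: int
    n_pairs: int


@dataclass
class PermutationResult:
    module_id: str
    statistic_name: str
    observed: float
    p_degree: float
    p_size: float
    n_rand: int
    t_degree: int
    t_size: int


def mean_abs_pearson(genes, ds: ExpressionDataset, state: str) -> float:
    """Mean |Pearson r| over all unordered gene pairs, computed on the
    samples of one state. Pairs involving a zero-variance gene count as 0."""
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    sub = ds.submatrix(genes, state)
    if sub.shape[1] < 3:
        raise ValueError(f"state {state!r} has fewer than 3 samples")
    sd = sub.std(axis=1)
    degenerate = sd == 0.0
    if degenerate.any():
        logger.warning("%d zero-variance gene(s) in state %s; their pairs "
                       "count as r=0", int(degenerate.sum()), state)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(sub)
    r = np.nan_to_num(r, nan=0.0)
    iu = np.triu_indices(len(genes), k=1)
    return float(np.abs(r[iu]).mean())


def w_score(
    module_genes, ds: ExpressionDataset, contrast: tuple[str, str],
    module_id: str = "",
) -> DiffCorrScore:
    """W(M) = |H - H'| between the two states of the contrast."""
    s1, s2 = contrast
    h = mean_abs_pearson(module_genes, ds, s1)
    hp = mean_abs_pearson(module_genes, ds, s2)
    g = len(list(module_genes))
    return DiffCorrScore(
        module_id=module_id,
        H=h,
        H_prime=hp,
        W=abs(h - hp),
        contrast=contrast,
        n=len(ds.samples_in_state(s1)),
        m=len(ds.samples_in_state(s2)),
        n_pairs=g * (g - 1) // 2,
    )


# ------------------------------------------------------------ random modules


def sample_size_conserved(net: nx.Graph, size: int, rng: np.random.Generator) -> set[str]:
    """Uniform sample of `size` distinct network nodes."""
    nodes = sorted(net.nodes)
    if size > len(nodes):
        raise ValueError(f"cannot sample {size} nodes from a {len(nodes)}-node network")
    idx = rng.choice(len(nodes), size=size, replace=False)
    return {nodes[i] for i in idx}


def sample_degree_conserved(
    net: nx.Graph, module_genes, rng: np.random.Generator
) -> set[str]:
    """Random node set matching the module's degree multiset.

    For each module node a distinct node of equal degree is drawn without
    replacement; when an exact-degree pool is exhausted the match relaxes
    to the node with the nearest log2 degree (logged).
    """
    module_genes = set(module_genes)
    if not module_genes <= set(net.nodes):
        raise ValueError("module is not a subset of the network's nodes")
    if len(module_genes) > net.number_of_nodes():
        raise ValueError("network too small")
    by_degree: dict[int, list[str]] = {}
    for v in sorted(net.nodes):
        by_degree.setdefault(net.degree(v), []).append(v)
    for pool in by_degree.values():
        rng.shuffle(pool)
    pools = {d: list(p) for d, p in by_degree.items()}
    chosen: set[str] = set()
    # high-degree nodes first: their pools are the scarcest
    for v in sorted(module_genes, key=lambda u: (-net.degree(u), u)):
        d = net.degree(v)
        pool = [u for u in pools.get(d, []) if u not in chosen]
        if pool:
            pick = pool[0]
        else:
            # widen to nearest log-binned degree
            candidates = [u for u in net.nodes if u not in chosen]
            if not candidates:
                raise ValueError("network exhausted during degree-conserved sampling")
            target = math.log2(d + 1)
            pick = min(candidates,
                       key=lambda u: (abs(math.log2(net.degree(u) + 1) - target), u))
            logger.info("degree-conserved sampling relaxed: wanted degree %d, "
                        "took %s (degree %d)", d, pick, net.degree(pick))
        chosen.add(pick)
    return chosen


def permutation_pvalues(
    module_genes,
    statistic_fn,
    net: nx.Graph,
    n_rand: int,
    rng: np.random.Generator,
    module_id: str = "",
    statistic_name: str = "W",
    max_redraws: int = 100,
) -> PermutationResult:
    """Two permutation p-values for an observed module statistic.

    ``statistic_fn(gene_set) -> float`` is evaluated on the module, on
    *n_rand* degree-conserved random sets and on *n_rand* size-conserved
    random sets; for each null, t counts random sets whose statistic is
    strictly below the observed one and p = 1 - t/n_rand. A failing draw is
    redrawn (never silently dropped).
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    module_genes = set(module_genes)
    observed = float(statistic_fn(module_genes))

    def null_stats(sampler) -> list[float]:
        out = []
        for _ in range(n_rand):
            for attempt in range(max_redraws):
                genes = sampler()
                try:
                    out.append(float(statistic_fn(genes)))
                    break
                except Exception as exc:  # redraw on statistic failure
                    logger.warning("statistic failed on random set (%s); redrawing", exc)
            else:
                raise RuntimeError("statistic failed on every redraw")
        return out

    deg_stats = null_stats(lambda: sample_degree_conserved(net, module_genes, rng))
    size_stats = null_stats(lambda: sample_size_conserved(net, len(module_genes), rng))
    t_degree = sum(1 for s in deg_stats if s < observed)
    t_size = sum(1 for s in size_stats if s < observed)
    return PermutationResult(
        module_id=module_id,
        statistic_name=statistic_name,
        observed=observed,
        p_degree=1.0 - t_degree / n_rand,
        p_size=1.0 - t_size / n_rand,
        n_rand=n_rand,
        t_degree=t_degree,
        t_size=t_size,
    )


def select_candidates(results: list[PermutationResult], alpha: float = 0.05) -> list[str]:
    """Module ids significant under both nulls (both p < alpha)."""
    return [r.module_id for r in results if r.p_degree < alpha and r.p_size < alpha]
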