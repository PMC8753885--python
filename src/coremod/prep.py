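"""Expression preprocessing and SAM-style differential expression.

Implements the preprocessing chain (missing-value row filtering, kNN
imputation, probe collapsing) and a moderated-d differential-expression
caller with permutation-based FDR q-values.

All expression values are assumed to be on log2 scale, so fold changes are
plain differences of group means.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class EmptyOutputError(ValueError):
    """Raised when a filtering step would remove every row."""


@dataclass
class ExpressionDataset:
    """A log2-scale gene x sample matrix with per-sample state labels."""

    matrix: np.ndarray  # shape (n_genes, n_samples)
    gene_ids: list[str]
    sample_ids: list[str]
    state_of: dict[str, str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        missing = [s for s in self.sample_ids if s not in self.state_of]
        if missing:
            raise ValueError(f"samples without a state label: {missing[:5]}")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def states(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.state_of[s], None)
        return list(seen)

    def samples_in_state(self, state: str) -> list[int]:
        """Column indices of the samples labelled *state*."""
        return [i for i, s in enumerate(self.sample_ids) if self.state_of[s] == state]

    def gene_rows(self, genes) -> np.ndarray:
        try:
            idx = [self._gene_index[g] for g in genes]
        except KeyError as e:
            raise KeyError(f"gene {e.args[0]!r} not in dataset") from None
        return self.matrix[idx, :]

    def submatrix(self, genes, state: str) -> np.ndarray:
        """Rows for *genes* restricted to the columns of one state."""
        return self.gene_rows(genes)[:, self.samples_in_state(state)]

    def has_gene(self, gene: str) -> bool:
        return gene in self._gene_index

    # ------------------------------------------------------------------ I/O

    def to_tsv(self, expr_path, states_path) -> None:
        df = pd.DataFrame(self.matrix, index=self.gene_ids, columns=self.sample_ids)
        df.index.name = "gene_id"
        df.to_csv(expr_path, sep="\t")
        pd.DataFrame(
            {"sample_id": self.sample_ids,
             "state": [self.state_of[s] for s in self.sample_ids]}
        ).to_csv(states_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, expr_path, states_path) -> "ExpressionDataset":
        df = pd.read_csv(expr_path, sep="\t", index_col=0)
        st = pd.read_csv(states_path, sep="\t", dtype=str)
        state_of = dict(zip(st["sample_id"], st["state"]))
        return cls(
            matrix=df.to_numpy(dtype=float),
            gene_ids=[str(g) for g in df.index],
            sample_ids=[str(c) for c in df.columns],
            state_of=state_of,
        )


@dataclass
class DEGRecord:
    gene_id: str
    contrast: tuple[str, str]
    d: float
    log2fc: float
    q: float
    is_deg: bool


# ---------------------------------------------------------------- filtering


def filter_missing(matrix: np.ndarray, max_missing_fraction: float = 0.5):
    """Drop rows whose missing (NaN) fraction strictly exceeds the threshold.

    Returns ``(filtered_matrix, kept_row_indices)`` with row order preserved.
    """
    matrix = np.asarray(matrix, dtype=float)
    frac = np.isnan(matrix).mean(axis=1)
    keep = np.flatnonzero(frac <= max_missing_fraction)
    if keep.size == 0:
        raise EmptyOutputError("missing-value filter removed every row")
    return matrix[keep, :], keep


def knn_impute(matrix: np.ndarray, k: int = 10) -> np.ndarray:
    """Fill missing cells with the inverse-distance-weighted average of the
    k nearest rows (Euclidean distance over co-observed columns).

    Observed cells are never modified. Rows at zero distance dominate (their
    plain average is used). If fewer than k usable neighbours exist for a
    cell, all available ones are used and a warning is logged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = np.array(matrix, dtype=float)
    obs = ~np.isnan(X)
    if not (obs.sum(axis=1) >= 1).all():
        raise ValueError("every row must have at least one observed value")
    if obs.all():
        return X
    out = X.copy()
    n = X.shape[0]
    for r in np.flatnonzero(~obs.all(axis=1)):
        # distances from row r to every other row over co-observed columns
        dists = np.full(n, np.inf)
        for o in range(n):
            if o == r:
                continue
            shared = obs[r] & obs[o]
            if not shared.any():
                continue
            dists[o] = math.sqrt(float(np.sum((X[r, shared] - X[o, shared]) ** 2)))
        for c in np.flatnonzero(~obs[r]):
            cand = np.flatnonzero(obs[:, c] & np.isfinite(dists))
            if cand.size == 0:
                # no row both observes this column and shares a column with
                # row r: fall back to the column mean
                logger.warning("knn_impute: no usable neighbour for cell "
                               "(%d, %d); using column mean", r, c)
                out[r, c] = float(X[obs[:, c], c].mean())
                continue
            if cand.size < k:
                logger.warning(
                    "knn_impute: only %d usable neighbours for cell (%d, %d), "
                    "k=%d requested", cand.size, r, c, k)
            order = cand[np.argsort(dists[cand], kind="stable")]
            nearest = order[:min(k, order.size)]
            d = dists[nearest]
            if np.any(d == 0.0):
                out[r, c] = float(X[nearest[d == 0.0], c].mean())
            else:
                w = 1.0 / d
                out[r, c] = float(np.sum(w * X[nearest, c]) / np.sum(w))
    return out


def collapse_probes(
    matrix: np.ndarray,
    probe_ids: list[str],
    probe_map: dict[str, list[str]],
    sample_ids: list[str],
    state_of: dict[str, str],
) -> ExpressionDataset:
    """Collapse probe rows to gene rows.

    Probes mapping to more than one gene are deleted; a gene covered by
    several probes gets the arithmetic mean of their rows.
    """
    if not probe_map:
        raise ValueError("empty probe map")
    matrix = np.asarray(matrix, dtype=float)
    per_gene: dict[str, list[int]] = {}
    for i, p in enumerate(probe_ids):
        genes = probe_map.get(p, [])
        if len(genes) != 1:
            continue  # unmapped or multi-gene probes are dropped
        per_gene.setdefault(genes[0], []).append(i)
    if not per_gene:
        raise EmptyOutputError("probe collapsing removed every row")
    gene_ids = sorted(per_gene)
    rows = np.vstack([matrix[per_gene[g], :].mean(axis=0) for g in gene_ids])
    return ExpressionDataset(rows, gene_ids, list(sample_ids), dict(state_of))


# ----------------------------------------------------------------- SAM DEGs

#: Enumerate all label assignments when the permutation space is this small.
EXHAUSTIVE_LIMIT = 10_000


def _d_statistic(m: np.ndarray, idx1, idx2, s0: float) -> np.ndarray:
    x, y = m[:, idx1], m[:, idx2]
    n1, n2 = x.shape[1], y.shape[1]
    diff = y.mean(axis=1) - x.mean(axis=1)
    ss = ((x - x.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + \
         ((y - y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    denom = s + s0
    # a gene constant across all samples gives diff = 0 and denom = 0 when
    # s0 itself is 0; define d = 0 there rather than dividing by zero
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(denom > 0.0, diff / np.where(denom > 0.0, denom, 1.0),
                     np.sign(diff) * np.inf)
    return np.where(diff == 0.0, 0.0, d)


def _pooled_se(m: np.ndarray, idx1, idx2) -> np.ndarray:
    x, y = m[:, idx1], m[:, idx2]
    n1, n2 = x.shape[1], y.shape[1]
    ss = ((x - x.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + \
         ((y - y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    return np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))


def sam_degs(
    ds: ExpressionDataset,
    contrast: tuple[str, str],
    n_perm: int = 1000,
    s0_quantile: float = 0.05,
    fc_threshold: float = 1.0,
    q_threshold: float = 0.05,
    rng: np.random.Generator | None = None,
) -> list[DEGRecord]:
    """SAM-style two-class differential expression.

    For each gene, d = (mean_B - mean_A) / (s_i + s0) where s_i is the
    pooled standard error and s0 the *s0_quantile* quantile of {s_i}.
    q-values come from a label-permutation estimate of the FDR at each |d|
    cut, monotonized so q is non-increasing in |d|. The permutation space
    is enumerated exhaustively when it has at most ``EXHAUSTIVE_LIMIT``
    distinct assignments.
    """
    state_a, state_b = contrast
    idx_a = ds.samples_in_state(state_a)
    idx_b = ds.samples_in_state(state_b)
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError(f"contrast {contrast} needs >=2 samples per state")
    rng = np.random.default_rng() if rng is None else rng

    m = ds.matrix
    cols = np.array(idx_a + idx_b)
    n1 = len(idx_a)
    s = _pooled_se(m, idx_a, idx_b)
    s0 = float(np.quantile(s, s0_quantile))
    d = _d_statistic(m, idx_a, idx_b, s0)
    log2fc = m[:, idx_b].mean(axis=1) - m[:, idx_a].mean(axis=1)

    n_total = len(cols)
    n_assign = math.comb(n_total, n1)
    perm_abs: list[np.ndarray] = []
    if n_assign <= EXHAUSTIVE_LIMIT:
        for combo in itertools.combinations(range(n_total), n1):
            mask = np.zeros(n_total, dtype=bool)
            mask[list(combo)] = True
            perm_abs.append(np.abs(_d_statistic(m, cols[mask], cols[~mask], s0)))
    else:
        for _ in range(n_perm):
            perm = rng.permutation(n_total)
            perm_abs.append(np.abs(
                _d_statistic(m, cols[perm[:n1]], cols[perm[n1:]], s0)))
    perm_flat = np.sort(np.concatenate(perm_abs))
    n_used = len(perm_abs)

    abs_d = np.abs(d)
    n_genes = abs_d.size
    sorted_abs = np.sort(abs_d)
    # at cut c = |d_i|: observed = #{|d| >= c}, expected FP = mean perm count >= c
    obs = n_genes - np.searchsorted(sorted_abs, abs_d, side="left")
    efp = (perm_flat.size - np.searchsorted(perm_flat, abs_d, side="left")) / n_used
    fdr = np.minimum(efp / np.maximum(obs, 1), 1.0)
    # q_i = min FDR over all cuts <= |d_i|  (monotone non-increasing in |d|)
    order = np.argsort(abs_d, kind="stable")
    q = np.empty(n_genes)
    q[order] = np.minimum.accumulate(fdr[order])

    records = []
    for i, g in enumerate(ds.gene_ids):
        is_deg = bool(abs(log2fc[i]) > fc_threshold and q[i] < q_threshold)
        records.append(DEGRecord(g, contrast, float(d[i]), float(log2fc[i]),
                                 float(q[i]), is_deg))
    return records


def deg_gene_set(records: list[DEGRecord]) -> set[str]:
    """Gene ids flagged as differentially expressed."""
    return {r.gene_id for r in records if r.is_deg}


def degs_to_frame(records: list[DEGRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "contrast": [f"{r.contrast[0]}_vs_{r.contrast[1]}" for r in records],
            "d": [r.d for r in records],
            "log2fc": [r.log2fc for r in records],
            "q": [r.q for r in records],
            "is_deg": [r.is_deg for r in records],
        }
    )
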