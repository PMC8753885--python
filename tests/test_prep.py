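import itertools
import math

import numpy as np
import pytest

from coremod import prep, synth
from coremod.prep import (
    EmptyOutputError,
    ExpressionDataset,
    collapse_probes,
    filter_missing,
    knn_impute,
    sam_degs,
)


def make_ds(matrix, states):
    matrix = np.asarray(matrix, dtype=float)
    genes = [f"g{i}" for i in range(matrix.shape[0])]
    samples = [f"s{i}" for i in range(matrix.shape[1])]
    return ExpressionDataset(matrix, genes, samples,
                             dict(zip(samples, states)))


class TestFilterMissing:
    def test_row_above_threshold_removed(self):
        m = np.array([[1.0, np.nan, np.nan, np.nan], [1, 2, 3, 4]])
        out, kept = filter_missing(m, 0.5)
        assert list(kept) == [1]

    def test_exactly_half_missing_retained(self):
        m = np.array([[1.0, 2.0, np.nan, np.nan], [1, 2, 3, 4]])
        out, kept = filter_missing(m, 0.5)
        assert list(kept) == [0, 1]

    def test_complete_matrix_unchanged(self):
        m = np.arange(12.0).reshape(3, 4)
        out, kept = filter_missing(m, 0.5)
        np.testing.assert_array_equal(out, m)
        assert list(kept) == [0, 1, 2]

    def test_all_removed_raises(self):
        m = np.full((2, 4), np.nan)
        with pytest.raises(EmptyOutputError):
            filter_missing(m, 0.5)

    def test_order_preserved(self):
        m = np.array([[1, 2.0], [np.nan, np.nan], [3, 4.0], [5, 6.0]])
        _, kept = filter_missing(m, 0.4)
        assert list(kept) == [0, 2, 3]


class TestKnnImpute:
    def test_no_missing_is_identity(self):
        m = np.arange(12.0).reshape(3, 4)
        np.testing.assert_array_equal(knn_impute(m, 2), m)

    def test_observed_cells_untouched(self, rng):
        m = rng.normal(size=(8, 6))
        mask = rng.random((8, 6)) < 0.15
        mm = m.copy()
        mm[mask] = np.nan
        out = knn_impute(mm, 3)
        np.testing.assert_array_equal(out[~mask], m[~mask])
        assert np.isfinite(out).all()

    def test_hand_computed_weighted_mean_k2(self):
        # rows 1 and 2 are the two nearest of row 0 over the co-observed
        # columns (1, 2); brute-force check over all row pairs
        m = np.array([
            [np.nan, 1.0, 2.0],
            [10.0, 1.5, 2.0],
            [20.0, 0.0, 3.0],
            [30.0, 9.0, 9.0],
        ])
        d1 = math.sqrt(0.5**2 + 0.0**2)
        d2 = math.sqrt(1.0**2 + 1.0**2)
        d3 = math.sqrt(8.0**2 + 7.0**2)
        assert d1 < d2 < d3  # rows 1, 2 are the k=2 nearest
        expected = (10.0 / d1 + 20.0 / d2) / (1.0 / d1 + 1.0 / d2)
        out = knn_impute(m, 2)
        assert out[0, 0] == pytest.approx(expected)

    def test_zero_distance_neighbour_restores_exactly(self):
        m = np.array([[1.0, 2.0, 3.0], [1.0, np.nan, 3.0], [5.0, 9.0, 1.0]])
        out = knn_impute(m, 1)
        assert out[1, 1] == 2.0

    def test_k_larger_than_neighbours_falls_back(self, caplog):
        m = np.array([[1.0, 2.0], [1.1, np.nan]])
        out = knn_impute(m, 10)
        assert out[1, 1] == 2.0

    def test_bad_k(self):
        with pytest.raises(ValueError):
            knn_impute(np.ones((2, 2)), 0)


class TestCollapseProbes:
    samples = ["s0", "s1"]
    states = {"s0": "A", "s1": "B"}

    def test_mean_of_probes(self):
        m = np.array([[1.0, 3.0], [3.0, 5.0]])
        ds = collapse_probes(m, ["p1", "p2"], {"p1": ["g"], "p2": ["g"]},
                             self.samples, self.states)
        assert ds.gene_ids == ["g"]
        np.testing.assert_array_equal(ds.matrix, [[2.0, 4.0]])

    def test_multi_gene_probe_deleted(self):
        m = np.array([[1.0, 3.0], [3.0, 5.0]])
        ds = collapse_probes(m, ["p1", "p2"],
                             {"p1": ["g1", "g2"], "p2": ["g3"]},
                             self.samples, self.states)
        assert ds.gene_ids == ["g3"]

    def test_one_to_one_identity(self):
        m = np.array([[1.0, 3.0], [3.0, 5.0]])
        ds = collapse_probes(m, ["p1", "p2"], {"p1": ["gA"], "p2": ["gB"]},
                             self.samples, self.states)
        assert ds.gene_ids == ["gA", "gB"]
        np.testing.assert_array_equal(ds.matrix, m)

    def test_empty_map_raises(self):
        with pytest.raises(ValueError):
            collapse_probes(np.ones((1, 2)), ["p1"], {}, self.samples, self.states)


def brute_force_sam(matrix, n1, s0_quantile=0.05):
    """Independent oracle: d, s0 and exhaustive-permutation q-values
    computed with plain loops."""
    matrix = np.asarray(matrix, dtype=float)
    n_genes, n_total = matrix.shape
    n2 = n_total - n1

    def d_stat(cols1, cols2, s0):
        ds = []
        for row in matrix:
            x, y = row[list(cols1)], row[list(cols2)]
            ss = sum((v - x.mean()) ** 2 for v in x) + sum((v - y.mean()) ** 2 for v in y)
            s = math.sqrt((1 / len(x) + 1 / len(y)) * ss / (len(x) + len(y) - 2))
            ds.append((y.mean() - x.mean()) / (s + s0))
        return np.array(ds)

    base1, base2 = tuple(range(n1)), tuple(range(n1, n_total))
    s_list = []
    for row in matrix:
        x, y = row[list(base1)], row[list(base2)]
        ss = sum((v - x.mean()) ** 2 for v in x) + sum((v - y.mean()) ** 2 for v in y)
        s_list.append(math.sqrt((1 / n1 + 1 / n2) * ss / (n1 + n2 - 2)))
    s0 = float(np.quantile(s_list, s0_quantile))
    d = d_stat(base1, base2, s0)

    all_perm_abs = []
    for combo in itertools.combinations(range(n_total), n1):
        rest = tuple(i for i in range(n_total) if i not in combo)
        all_perm_abs.append(np.abs(d_stat(combo, rest, s0)))
    n_perm = len(all_perm_abs)

    q = np.zeros(n_genes)
    abs_d = np.abs(d)
    for i in range(n_genes):
        best = np.inf
        for c in sorted(abs_d[abs_d <= abs_d[i]]):
            obs = int((abs_d >= c).sum())
            efp = sum(int((p >= c).sum()) for p in all_perm_abs) / n_perm
            best = min(best, min(efp / obs, 1.0))
        q[i] = best
    return d, q


class TestSamDegs:
    def test_identical_groups_all_zero(self):
        m = np.tile(np.arange(5.0)[:, None], (1, 8))
        ds = make_ds(m, ["A"] * 4 + ["B"] * 4)
        recs = sam_degs(ds, ("A", "B"), rng=np.random.default_rng(0))
        assert all(r.d == 0.0 for r in recs)
        assert not any(r.is_deg for r in recs)

    def test_exhaustive_oracle_4v4(self, rng):
        m = rng.normal(size=(12, 8))
        m[:3, 4:] += 2.5
        ds = make_ds(m, ["A"] * 4 + ["B"] * 4)
        recs = sam_degs(ds, ("A", "B"), rng=np.random.default_rng(0))
        d_oracle, q_oracle = brute_force_sam(m, 4)
        np.testing.assert_allclose([r.d for r in recs], d_oracle, rtol=1e-12)
        np.testing.assert_allclose([r.q for r in recs], q_oracle, rtol=1e-12)

    def test_d_antisymmetric_log2fc_invariant(self, rng):
        m = rng.normal(size=(10, 12))
        ds = make_ds(m, ["A"] * 6 + ["B"] * 6)
        ab = sam_degs(ds, ("A", "B"), rng=np.random.default_rng(0))
        ba = sam_degs(ds, ("B", "A"), rng=np.random.default_rng(0))
        np.testing.assert_allclose([r.d for r in ab], [-r.d for r in ba])
        np.testing.assert_allclose([abs(r.log2fc) for r in ab],
                                   [abs(r.log2fc) for r in ba])

    def test_q_monotone_in_abs_d(self, rng):
        m = rng.normal(size=(30, 10))
        m[:5, 5:] += 3
        ds = make_ds(m, ["A"] * 5 + ["B"] * 5)
        recs = sam_degs(ds, ("A", "B"), rng=np.random.default_rng(1))
        order = sorted(recs, key=lambda r: abs(r.d))
        qs = [r.q for r in order]
        assert all(qs[i] >= qs[i + 1] for i in range(len(qs) - 1))

    def test_planted_deg_recall(self, small_bundle, small_cfg):
        contrast = small_cfg.diff_contrast
        truth_degs = small_bundle.truth.planted_deg_sets[contrast]
        recs = sam_degs(small_bundle.dataset, contrast,
                        rng=np.random.default_rng(2))
        called = prep.deg_gene_set(recs)
        recall = len(called & truth_degs) / len(truth_degs)
        assert recall >= 0.95

    def test_constant_gene_no_division_by_zero(self):
        m = np.vstack([np.ones(8), np.random.default_rng(0).normal(size=8)])
        ds = make_ds(m, ["A"] * 4 + ["B"] * 4)
        recs = sam_degs(ds, ("A", "B"), rng=np.random.default_rng(0))
        assert all(np.isfinite(r.d) for r in recs)

    def test_global_null_fdr_control(self):
        # fraction of q < 0.05 calls under a pure null stays near/below 0.05
        rng = np.random.default_rng(99)
        fracs = []
        for _ in range(5):
            m = rng.normal(size=(200, 16))
            ds = make_ds(m, ["A"] * 8 + ["B"] * 8)
            recs = sam_degs(ds, ("A", "B"), n_perm=300, rng=rng)
            fracs.append(np.mean([r.q < 0.05 for r in recs]))
        se = math.sqrt(0.05 * 0.95 / (5 * 200))
        assert np.mean(fracs) <= 0.05 + 2 * se

    def test_too_few_samples_raises(self):
        m = np.ones((3, 3))
        ds = make_ds(m, ["A", "A", "B"])
        with pytest.raises(ValueError):
            sam_degs(ds, ("A", "B"))
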