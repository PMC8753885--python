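import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from coremod import mrf
from coremod.mcode import Module
from coremod.mrf import (
    MRFModel,
    expression_difference,
    gibbs_energy,
    mrfms,
    mutual_information,
    select_risk_modules,
)
from tests.test_prep import make_ds


class TestExpressionDifference:
    def test_identical_groups_zero(self):
        ds = make_ds([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], ["A"] * 3 + ["B"] * 3)
        assert expression_difference("g0", ds, ("A", "B")) == 0.0

    def test_p_half_gives_zero(self):
        # symmetric overlapping groups: p close to 1 -> E clipped at 0
        ds = make_ds([[0.0, 1.0, -1.0, 1.0, 0.0, -1.0]], ["A"] * 3 + ["B"] * 3)
        assert expression_difference("g0", ds, ("A", "B")) == 0.0

    def test_matches_hand_computed_welch(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([4.0, 6.0, 8.0])
        ds = make_ds([np.concatenate([x, y])], ["A"] * 3 + ["B"] * 3)
        # Welch t and df by the textbook formulas
        vx, vy = x.var(ddof=1) / 3, y.var(ddof=1) / 3
        t = (y.mean() - x.mean()) / math.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / 2 + vy**2 / 2)
        p = 2 * stats.t.sf(abs(t), df)
        expected = stats.norm.ppf(1 - p)
        assert expression_difference("g0", ds, ("A", "B")) == \
            pytest.approx(expected, rel=1e-9)

    def test_huge_difference_clipped(self):
        ds = make_ds([[0.0, 0.0, 0.0, 9.0, 9.0, 9.0]], ["A"] * 3 + ["B"] * 3)
        e = expression_difference("g0", ds, ("A", "B"))
        assert 0.0 < e <= mrf.E_CLIP_HIGH

    def test_abs_t_transform(self):
        ds = make_ds([[1.0, 2.0, 3.0, 4.0, 6.0, 8.0]], ["A"] * 3 + ["B"] * 3)
        t, _ = stats.ttest_ind([4.0, 6.0, 8.0], [1.0, 2.0, 3.0], equal_var=False)
        assert expression_difference("g0", ds, ("A", "B"), transform="abs_t") == \
            pytest.approx(abs(t))


class TestMutualInformation:
    def test_identical_two_bins_one_bit(self):
        x = np.arange(16.0)
        assert mutual_information(x, x, n_bins=2) == pytest.approx(1.0)

    def test_constant_zero(self):
        assert mutual_information(np.ones(10), np.arange(10.0)) == 0.0

    def test_permutation_baseline(self, rng):
        x = rng.normal(size=200)
        self_mi = mutual_information(x, x, n_bins=4)
        shuffled = [mutual_information(x, rng.permutation(x), n_bins=4)
                    for _ in range(100)]
        assert np.mean(shuffled) < self_mi / 10

    def test_nonnegative(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=(2, 50))
            assert mutual_information(x, y) >= 0.0

    def test_length_validation(self):
        with pytest.raises(ValueError):
            mutual_information([1.0, 2.0], [1.0, 2.0])


def model_with(net, e_values, deg_genes, mi_values=None, ds=None):
    """MRFModel with hand-set E and MI caches for arithmetic tests."""
    if ds is None:
        genes = sorted(e_values)
        mat = np.zeros((len(genes), 8))
        ds = make_ds(mat, ["A"] * 4 + ["B"] * 4)
        ds.gene_ids = genes
        ds._gene_index = {g: i for i, g in enumerate(genes)}
    m = MRFModel(net=net, ds=ds, contrast=("A", "B"), deg_genes=set(deg_genes))
    m._e_cache.update(e_values)
    if mi_values:
        for (a, b), v in mi_values.items():
            m._mi_cache[(a, b) if a <= b else (b, a)] = v
    return m


class TestMrfms:
    def test_all_degs_unit_e(self):
        net = nx.complete_graph(["a", "b", "c", "d"])
        model = model_with(net, {g: 1.0 for g in "abcd"}, deg_genes=set("abcd"))
        sc = mrfms(set("abcd"), model)
        assert sc.term2 == 0.0
        assert sc.mrfms == pytest.approx(2.0)  # 4 / sqrt(4)

    def test_all_zero_e(self):
        net = nx.complete_graph(["a", "b", "c", "d"])
        model = model_with(net, {g: 0.0 for g in "abcd"}, deg_genes={"a"},
                           mi_values={(x, y): 0.5 for x in "abcd" for y in "abcd"})
        assert mrfms(set("abcd"), model).mrfms == 0.0

    def test_five_gene_toy_spreadsheet_oracle(self):
        # module a-b-c-d-e on a path plus edge b-d; DEGs {a, b}
        net = nx.Graph([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("b", "d")])
        e = {"a": 2.0, "b": 1.5, "c": 1.0, "d": 0.5, "e": 0.25}
        mi = {("c", "d"): 0.3, ("d", "e"): 0.7}
        model = model_with(net, e, deg_genes={"a", "b"}, mi_values=mi)
        sc = mrfms(set("abcde"), model)
        g, b = 5, 5  # all induced edges
        term1 = (2.0 + 1.5) / math.sqrt(g)
        d = dict(net.degree())
        t_cd = (1.0 / math.sqrt(d["c"]) - 0.5 / math.sqrt(d["d"])) ** 2 * 0.3
        t_de = (0.5 / math.sqrt(d["d"]) - 0.25 / math.sqrt(d["e"])) ** 2 * 0.7
        term2 = (t_cd + t_de) / b
        assert sc.term1 == pytest.approx(term1)
        assert sc.term2 == pytest.approx(term2)
        assert sc.mrfms == pytest.approx(term1 - term2)

    def test_equals_negative_gibbs_energy(self, rng):
        for _ in range(25):
            net = nx.gnp_random_graph(10, 0.4, seed=int(rng.integers(1 << 30)))
            net = nx.relabel_nodes(net, {i: f"g{i}" for i in net.nodes})
            genes = sorted(net.nodes)[:6]
            e = {g: float(rng.uniform(0, 3)) for g in net.nodes}
            mi = {}
            for a in net.nodes:
                for b in net.nodes:
                    if a < b:
                        mi[(a, b)] = float(rng.uniform(0, 1))
            degs = set(rng.choice(genes, size=2, replace=False))
            model = model_with(net, e, deg_genes=degs, mi_values=mi)
            sub = net.subgraph(genes)
            if sub.number_of_edges() == 0:
                continue
            sc = mrfms(set(genes), model)
            f = gibbs_energy(set(genes), model)
            assert sc.mrfms == pytest.approx(-f, rel=1e-12, abs=1e-15)
            assert sc.term2 >= 0.0
            assert sc.mrfms <= sc.term1

    def test_monotone_in_deg_e(self):
        net = nx.complete_graph(["a", "b", "c", "d"])
        base = {g: 1.0 for g in "abcd"}
        mi = {(x, y): 0.4 for x in "abcd" for y in "abcd"}
        lo = mrfms(set("abcd"), model_with(net, base, {"a"}, mi)).mrfms
        bumped = dict(base, a=2.0)
        hi = mrfms(set("abcd"), model_with(net, bumped, {"a"}, mi)).mrfms
        assert hi > lo

    def test_nondeg_discrepancy_never_helps(self):
        net = nx.Graph([("a", "b"), ("b", "c"), ("c", "a")])
        mi = {("a", "b"): 0.5, ("b", "c"): 0.5, ("a", "c"): 0.5}
        even = mrfms(set("abc"), model_with(net, {"a": 1.0, "b": 1.0, "c": 1.0},
                                            set(), mi)).mrfms
        skewed = mrfms(set("abc"), model_with(net, {"a": 2.5, "b": 1.0, "c": 1.0},
                                              set(), mi)).mrfms
        assert skewed <= even

    def test_term1_scales_sqrt_g(self):
        e_val = 1.3
        n1 = nx.complete_graph([f"x{i}" for i in range(4)])
        n2 = nx.complete_graph([f"x{i}" for i in range(8)])
        m1 = model_with(n1, {g: e_val for g in n1.nodes}, set(n1.nodes))
        m2 = model_with(n2, {g: e_val for g in n2.nodes}, set(n2.nodes))
        t1 = mrfms(set(n1.nodes), m1).term1
        t2 = mrfms(set(n2.nodes), m2).term1
        assert t2 == pytest.approx(math.sqrt(2) * t1)

    def test_missing_gene_named_in_error(self):
        net = nx.complete_graph(["a", "b", "c", "d"])
        model = model_with(net, {g: 1.0 for g in "abcd"}, {"a"})
        with pytest.raises(KeyError, match="zz"):
            mrfms({"a", "zz"}, model)


class TestSelectRiskModules:
    def test_planted_module_selected(self, small_bundle, small_cfg, small_net):
        ds = small_bundle.dataset
        contrast = small_cfg.diff_contrast
        truth = small_bundle.truth
        model = MRFModel(net=small_net, ds=ds, contrast=contrast,
                         deg_genes=truth.planted_deg_sets[contrast])
        mod = Module("M1", frozenset(truth.planted_module_genes),
                     frozenset(), "x", 1.0)
        risk, results = select_risk_modules(
            [mod], model, n_rand=150, rng=np.random.default_rng(5))
        assert risk == ["M1"]
        assert results[0].statistic_name == "MRFms"

    def test_filter_semantics_one_in_at_most_one_out(self, small_bundle,
                                                     small_cfg, small_net):
        ds = small_bundle.dataset
        contrast = small_cfg.diff_contrast
        model = MRFModel(net=small_net, ds=ds, contrast=contrast,
                         deg_genes=set())
        genes = frozenset(sorted(small_net.nodes)[-6:])
        mod = Module("MX", genes, frozenset(), "x", 1.0)
        risk, results = select_risk_modules(
            [mod], model, n_rand=60, rng=np.random.default_rng(6))
        assert len(results) == 1
        assert len(risk) <= 1

    def test_no_degs_discordant_nondegs_nonpositive(self, small_bundle,
                                                    small_cfg, small_net):
        ds = small_bundle.dataset
        model = MRFModel(net=small_net, ds=ds, contrast=small_cfg.diff_contrast,
                         deg_genes=set())
        genes = set(small_bundle.truth.planted_module_genes)
        sc = mrfms(genes, model)
        assert sc.term1 == 0.0
        assert sc.mrfms <= 0.0
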