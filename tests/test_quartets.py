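import dendropy
import numpy as np
import pytest
from hypothesis import given, strategies as st

from tspscan import (
    NotEnoughAllelesError,
    Quartet,
    QuartetCount,
    ScenarioConfig,
    bayes_factor,
    bf_matrix,
    count_topologies,
    enumerate_quartets,
    max_bayes_factor,
    quartet_topology,
    simulate_posterior_sample,
)

from conftest import random_newick, sample_from_newicks, tree_from_newick

Q = Quartet("a1", "a2", "b1", "b2")


def quartet_oracle(tree: dendropy.Tree, q: Quartet) -> str:
    """Brute-force oracle: extract the induced 4-tip tree and inspect its
    bipartitions directly."""
    sub = tree.extract_tree_with_taxa_labels(list(q.tips))
    for edge in sub.preorder_edge_iter():
        if edge.head_node.parent_node is None:
            continue
        below = {t.taxon.label for t in edge.head_node.leaf_iter()}
        if len(below) == 2:
            if below in ({q.a1, q.a2}, {q.b1, q.b2}):
                return "monophyletic"
            return "nonmonophyletic"
    return "uninformative"


class TestQuartetTopology:
    @pytest.mark.parametrize(
        "nwk, expected",
        [
            ("((a1:1,a2:1):1,(b1:1,b2:1):1);", "monophyletic"),
            ("((a1:1,b1:1):1,(a2:1,b2:1):1);", "nonmonophyletic"),
            ("(a1:1,(b1:1,(a2:1,b2:1):1):1);", "nonmonophyletic"),
            ("(a1:1,a2:1,b1:1,b2:1);", "uninformative"),
        ],
    )
    def test_examples(self, nwk, expected):
        assert quartet_topology(tree_from_newick(nwk), Q) == expected

    def test_three_resolutions_give_one_mono_two_nonmono(self):
        resolutions = [
            "((a1:1,a2:1):1,(b1:1,b2:1):1);",
            "((a1:1,b1:1):1,(a2:1,b2:1):1);",
            "((a1:1,b2:1):1,(a2:1,b1:1):1);",
        ]
        calls = [quartet_topology(tree_from_newick(n), Q) for n in resolutions]
        assert calls.count("monophyletic") == 1
        assert calls.count("nonmonophyletic") == 2

    def test_missing_tip_named(self):
        tree = tree_from_newick("((a1:1,a2:1):1,(b1:1,x:1):1);")
        with pytest.raises(KeyError, match="b2"):
            quartet_topology(tree, Q)

    def test_extra_taxa_do_not_disturb_classification(self):
        tree = tree_from_newick("(((a1:1,a2:1):1,z:1):1,((b1:1,b2:1):1,w:1):1);")
        assert quartet_topology(tree, Q) == "monophyletic"


class TestCountTopologies:
    def test_pure_sample(self):
        s = sample_from_newicks(["((a1:1,a2:1):1,(b1:1,b2:1):1);"] * 10)
        c = count_topologies(s, Q)
        assert (c.n_mono, c.n_nonmono, c.n_uninformative) == (10, 0, 0)

    def test_mixed_sample(self):
        s = sample_from_newicks(
            ["((a1:1,a2:1):1,(b1:1,b2:1):1);"] * 7
            + ["((a1:1,b1:1):1,(a2:1,b2:1):1);"] * 3
        )
        c = count_topologies(s, Q)
        assert (c.n_mono, c.n_nonmono) == (7, 3)

    def test_order_permutation_invariance(self):
        newicks = ["((a1:1,a2:1):1,(b1:1,b2:1):1);"] * 4 + [
            "((a1:1,b1:1):1,(a2:1,b2:1):1);"
        ] * 6
        c1 = count_topologies(sample_from_newicks(newicks), Q)
        c2 = count_topologies(sample_from_newicks(newicks[::-1]), Q)
        assert (c1.n_mono, c1.n_nonmono) == (c2.n_mono, c2.n_nonmono)

    def test_agrees_with_bruteforce_oracle_on_random_trees(self):
        rng = np.random.default_rng(42)
        labels = ["a1", "a2", "b1", "b2", "x", "y"]
        newicks = [random_newick(labels, rng) for _ in range(200)]
        s = sample_from_newicks(newicks)
        oracle = [quartet_oracle(t, Q) for t in s.trees]
        c = count_topologies(s, Q)
        assert c.n_mono == oracle.count("monophyletic")
        assert c.n_nonmono == oracle.count("nonmonophyletic")
        assert c.n_uninformative == oracle.count("uninformative")


class TestBayesFactor:
    def test_zero_mono_among_14000_trees_gives_7000_lower_bound(self):
        r = bayes_factor(QuartetCount(n_mono=0, n_nonmono=14_000))
        assert r.K == pytest.approx(7000.0)
        assert r.is_lower_bound

    def test_equal_counts_give_half(self):
        r = bayes_factor(QuartetCount(n_mono=250, n_nonmono=250))
        assert r.K == pytest.approx(0.5)
        assert not r.is_lower_bound

    def test_zero_nonmono_among_100_trees(self):
        r = bayes_factor(QuartetCount(n_mono=100, n_nonmono=0))
        assert r.K == pytest.approx(1 / 200)
        assert r.is_lower_bound

    def test_all_uninformative_is_undefined(self):
        with pytest.raises(ValueError):
            bayes_factor(QuartetCount(n_mono=0, n_nonmono=0, n_uninformative=10))

    @given(
        st.integers(min_value=1, max_value=10_000),
        st.integers(min_value=1, max_value=10_000),
    )
    def test_reciprocal_product_is_prior_odds_squared(self, a, b):
        k1 = bayes_factor(QuartetCount(n_mono=a, n_nonmono=b)).K
        k2 = bayes_factor(QuartetCount(n_mono=b, n_nonmono=a)).K
        assert k1 * k2 == pytest.approx(0.25)

    @given(st.integers(min_value=10, max_value=1000))
    def test_strictly_increasing_in_nonmono_at_fixed_n(self, n):
        ks = [
            bayes_factor(QuartetCount(n_mono=n - m, n_nonmono=m)).K
            for m in range(1, n)
        ]
        assert all(x < y for x, y in zip(ks, ks[1:]))


class TestEnumerateQuartets:
    def test_minimal_groups_give_one_quartet(self):
        qs = enumerate_quartets(["a1", "a2"], ["b1", "b2"])
        assert qs == [Quartet("a1", "a2", "b1", "b2")]

    def test_three_by_three_gives_nine(self):
        qs = enumerate_quartets(list("abc"), list("xyz"), cap=100)
        assert len(qs) == 9

    def test_insufficient_alleles_signalled(self):
        with pytest.raises(NotEnoughAllelesError):
            enumerate_quartets(["a1", "a2"], ["b1"])

    def test_exclusions_never_appear_and_can_deplete(self):
        qs = enumerate_quartets(list("abcd"), list("wxyz"), excluded={"a", "w"})
        for q in qs:
            assert "a" not in q.tips and "w" not in q.tips
        with pytest.raises(NotEnoughAllelesError):
            enumerate_quartets(list("abc"), list("xyz"), excluded={"a", "b"})

    def test_cap_subsampling_is_deterministic(self):
        A, B = [f"a{i}" for i in range(8)], [f"b{i}" for i in range(8)]
        q1 = enumerate_quartets(A, B, cap=50, seed=3)
        q2 = enumerate_quartets(A, B, cap=50, seed=3)
        assert q1 == q2 and len(q1) == 50
        assert enumerate_quartets(A, B, cap=50, seed=4) != q1


class TestMaxBayesFactor:
    def test_single_quartet_equals_bayes_factor(self):
        s = sample_from_newicks(
            ["((a1:1,a2:1):1,(b1:1,b2:1):1);"] * 7
            + ["((a1:1,b1:1):1,(a2:1,b2:1):1);"] * 3
        )
        r = max_bayes_factor(s, ["a1", "a2"], ["b1", "b2"])
        direct = bayes_factor(count_topologies(s, Q))
        assert r.K == direct.K
        assert r.best_quartet == Q
        assert r.n_quartets_tested == 1

    def test_noise_free_calibration_is_exact(self):
        cfg = ScenarioConfig(scenario="monophyly", epsilon=0.0, n_trees=100, seed=7)
        s, _ = simulate_posterior_sample(cfg)
        A = [l.raw for l in s.tip_labels if l.species_code == "HLA"]
        B = [l.raw for l in s.tip_labels if l.species_code == "Mamu"]
        r = max_bayes_factor(s, A, B)
        n = 100
        assert r.K == pytest.approx((1 / (n + 1)) / (n / (n + 1)) * 0.5)
        assert r.is_lower_bound

    def test_tsp_sample_with_noise_is_decisive(self):
        cfg = ScenarioConfig(scenario="tsp", n_lineages=2, epsilon=0.02,
                             n_trees=500, seed=5)
        s, _ = simulate_posterior_sample(cfg)
        A = [l.raw for l in s.tip_labels if l.species_code == "HLA"]
        B = [l.raw for l in s.tip_labels if l.species_code == "Mamu"]
        assert max_bayes_factor(s, A, B).K > 100


class TestBfMatrix:
    def _regions(self):
        tsp_cfg = ScenarioConfig(scenario="tsp", epsilon=0.0, n_trees=300, seed=21)
        mono_cfg = ScenarioConfig(scenario="monophyly", epsilon=0.0, n_trees=300, seed=22)
        s_tsp, _ = simulate_posterior_sample(tsp_cfg)
        s_mono, _ = simulate_posterior_sample(mono_cfg)
        return {"exon2": s_tsp, "exon3": s_mono}

    def test_two_region_contrast(self):
        df = bf_matrix(
            self._regions(),
            comparisons=[("human-vs-macaque", ["HLA"], ["Mamu"])],
        )
        k = df.set_index("region")["K"]
        assert k["exon2"] > 100
        assert k["exon3"] < 1
        labels = df.set_index("region")["label"]
        assert labels["exon2"].startswith(">")  # zero-count lower bound

    def test_insufficient_alleles_render_blank(self):
        df = bf_matrix(
            self._regions(),
            comparisons=[("human-vs-unknown", ["HLA"], ["Popy"])],
        )
        assert df["K"].isna().all()
        assert (df["label"] == "").all()

    def test_exclusions_apply_per_region(self):
        regions = self._regions()
        tips = [l.raw for l in regions["exon2"].tip_labels if l.species_code == "Mamu"]
        df = bf_matrix(
            regions,
            comparisons=[("human-vs-macaque", ["HLA"], ["Mamu"])],
            exclusions={"exon2": tips[:-1]},  # leave one macaque allele
        )
        k = df.set_index("region")
        assert np.isnan(k.loc["exon2", "K"])
        assert np.isfinite(k.loc["exon3", "K"])
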