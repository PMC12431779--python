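import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from tspscan import (
    RAPID_PRESETS,
    SiteRatePosterior,
    association_regression,
    codon_rates,
    exon_rapid_summary,
    fold_changes,
    identify_baseline_sites,
    mean_site_rates,
    read_rate_posterior,
    simulate_rate_posterior,
    write_rate_posterior,
)


class TestMeanSiteRates:
    def test_single_state_identity(self):
        post = SiteRatePosterior(rates=[[1.0, 2.0, 3.0]], column_ids=[1, 2, 3])
        assert mean_site_rates(post).tolist() == [1.0, 2.0, 3.0]

    def test_two_state_average(self):
        post = SiteRatePosterior(rates=[[1.0], [3.0]], column_ids=[1])
        assert mean_site_rates(post)[0] == pytest.approx(2.0)

    def test_large_sample_concentrates_on_truth(self):
        truth = np.array([0.5, 1.0, 4.0])
        post, _ = simulate_rate_posterior(truth, n_states=1000, noise_sigma=0.2, seed=2)
        # lognormal noise inflates the mean by exp(sigma^2/2) uniformly
        expected = truth * np.exp(0.2 ** 2 / 2)
        assert np.all(np.abs(mean_site_rates(post) / expected - 1) < 0.02)

    def test_tsv_round_trip(self, tmp_path):
        post, _ = simulate_rate_posterior([1.0, 2.0], n_states=5, seed=0)
        p = tmp_path / "rates.tsv"
        write_rate_posterior(post, str(p))
        back = read_rate_posterior(str(p))
        np.testing.assert_allclose(back.rates, post.rates)
        assert list(back.column_ids) == list(post.column_ids)


class TestBaselineSites:
    ALN = {
        "bb1": "AC--G-",
        "bb2": "AC--GG",
        "oth": "ACGTGG",
    }

    def test_all_backbones_gapped(self):
        mask = identify_baseline_sites(self.ALN, ["bb1", "bb2"])
        assert mask.tolist() == [False, False, True, True, False, False]

    def test_all_quantifier_requires_every_backbone(self):
        mask = identify_baseline_sites(self.ALN, ["bb1", "bb2"])
        assert not mask[5]  # gapped in bb1 only

    def test_missing_backbone_named(self):
        with pytest.raises(KeyError, match="HLA-X"):
            identify_baseline_sites(self.ALN, ["bb1", "HLA-X"])

    def test_no_gappy_columns_then_fold_changes_fails(self):
        mask = identify_baseline_sites({"bb": "ACGT", "o": "ACGA"}, ["bb"])
        assert not mask.any()
        with pytest.raises(ValueError, match="no baseline"):
            fold_changes(np.ones(4), mask)


class TestFoldChanges:
    def test_fourfold_is_two_and_twice_is_one(self):
        means = np.array([4.0, 1.0, 2.0, 1.0])
        mask = np.array([False, True, False, True])
        prof = fold_changes(means, mask)
        assert prof.fold_change[0] == pytest.approx(2.0)
        assert prof.fold_change[1] == pytest.approx(0.0)
        assert prof.fold_change[2] == pytest.approx(1.0)

    def test_baseline_mean_identity_is_exact(self):
        rng = np.random.default_rng(3)
        means = rng.lognormal(0, 1, size=200)
        mask = np.zeros(200, bool)
        mask[rng.choice(200, 50, replace=False)] = True
        prof = fold_changes(means, mask)
        assert np.mean(2.0 ** prof.fold_change[mask]) == pytest.approx(1.0, abs=1e-12)

    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance(self, c):
        means = np.array([0.5, 1.0, 2.0, 4.0])
        mask = np.array([False, True, True, False])
        base = fold_changes(means, mask).fold_change
        scaled = fold_changes(c * means, mask).fold_change
        np.testing.assert_allclose(scaled, base, atol=1e-9)

    def test_planted_multiplier_recovery(self):
        truth = np.concatenate([
            np.full(50, 0.5), np.full(50, 1.0), np.full(50, 4.0), np.ones(100)
        ])
        post, _ = simulate_rate_posterior(truth, n_states=1000, noise_sigma=0.2, seed=5)
        mask = np.zeros(250, bool)
        mask[150:] = True
        prof = fold_changes(mean_site_rates(post), mask)
        target = np.concatenate([
            np.full(50, -1.0), np.full(50, 0.0), np.full(50, 2.0)
        ])
        err = np.abs(prof.fold_change[:150] - target)
        assert np.mean(err <= 0.15) >= 0.95


class TestCodonRates:
    def test_mean_of_three_positions(self):
        cds = {0: (0, 0), 1: (0, 1), 2: (0, 2)}
        assert codon_rates(np.array([1.0, 2.0, 3.0]), cds) == {0: pytest.approx(2.0)}

    def test_gap_member_emits_missing(self):
        cds = {0: (0, 0), 1: (0, 1), 2: (0, 2)}
        out = codon_rates(np.array([1.0, np.nan, 3.0]), cds)
        assert np.isnan(out[0])

    def test_partial_codon_emits_missing(self):
        cds = {0: (0, 0), 1: (0, 1)}
        assert np.isnan(codon_rates(np.array([1.0, 2.0]), cds)[0])

    def test_planted_fast_codon(self):
        vals = np.array([2.0, 2.0, 2.0, 0.0, 0.0, 0.0])
        cds = {i: (i // 3, i % 3) for i in range(6)}
        out = codon_rates(vals, cds)
        assert out == {0: pytest.approx(2.0), 1: pytest.approx(0.0)}


def _profile_from_fc(fc, baseline_extra=20):
    """RateProfile whose fold changes equal ``fc``, padded with baseline."""
    fc = np.asarray(fc, float)
    means = np.concatenate([2.0 ** fc, np.ones(baseline_extra)])
    mask = np.zeros(means.size, bool)
    mask[fc.size:] = True
    return fold_changes(means, mask)


class TestExonRapidSummary:
    def test_extreme_contrast_has_tiny_fisher_p(self):
        fc = np.concatenate([np.full(20, 3.0), np.zeros(20)])
        prof = _profile_from_fc(fc)
        df = exon_rapid_summary(
            prof, [("2", 1, 20), ("5", 21, 40)], threshold=2.0, pbr_exons=("2",)
        )
        row = df.set_index("exon").loc["2"]
        assert row["proportion"] == 1.0
        assert row["fisher_p_vs_other"] < 1e-10

    def test_threshold_above_everything(self):
        prof = _profile_from_fc(np.zeros(30))
        df = exon_rapid_summary(prof, [("2", 1, 15), ("5", 16, 30)], threshold=10.0)
        assert (df["n_rapid"] == 0).all()

    def test_planted_fast_exon_has_highest_proportion(self):
        rng = np.random.default_rng(8)
        fc = rng.normal(0, 0.2, size=90)
        fc[30:60] += 3.0  # the peptide-binding exon
        prof = _profile_from_fc(fc)
        df = exon_rapid_summary(
            prof,
            [("1", 1, 30), ("2", 31, 60), ("5", 61, 90)],
            threshold=2.0,
        )
        top = df.loc[df["proportion"].idxmax(), "exon"]
        assert top == "2"

    def test_presets_match_paper_conventions(self):
        assert RAPID_PRESETS["twice"] == (1.0, True)
        assert RAPID_PRESETS["fourfold"] == (2.0, False)
        fc = np.array([1.0, 2.0, 2.5])
        prof = _profile_from_fc(fc)
        thr, inc = RAPID_PRESETS["twice"]
        df = exon_rapid_summary(prof, [("2", 1, 3)], threshold=thr, inclusive=inc)
        assert df.loc[0, "n_rapid"] == 3  # fold change >= 1 counts all three
        thr, inc = RAPID_PRESETS["fourfold"]
        df = exon_rapid_summary(prof, [("2", 1, 3)], threshold=thr, inclusive=inc)
        assert df.loc[0, "n_rapid"] == 1  # only strictly above 2

    def test_overlapping_exons_rejected(self):
        prof = _profile_from_fc(np.zeros(30))
        with pytest.raises(ValueError, match="overlap"):
            exon_rapid_summary(prof, [("2", 1, 20), ("3", 15, 30)])


class TestAssociationRegression:
    def test_noiseless_linear_counts(self):
        rates = {i: 0.1 * i for i in range(20)}
        counts = {i: 3.0 * rates[i] + 1.0 for i in range(20)}
        res = association_regression(rates, counts)
        assert res.slope == pytest.approx(3.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.pvalue < 1e-12

    def test_two_positions_rejected(self):
        with pytest.raises(ValueError):
            association_regression({1: 0.1, 2: 0.2}, {1: 1, 2: 2})

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            association_regression({i: 1.0 for i in range(5)},
                                   {i: float(i) for i in range(5)})

    def test_null_pvalues_are_uniform(self):
        # permuted counts carry no signal: slope p-values should be uniform
        rng = np.random.default_rng(17)
        pvals = []
        for _ in range(200):
            x = rng.normal(size=100)
            y = rng.poisson(2.0, size=100).astype(float)
            pvals.append(association_regression(dict(enumerate(x)),
                                                dict(enumerate(y))).pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
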