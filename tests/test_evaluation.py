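import numpy as np
import pytest

from tecpause import evaluation as ev
from tecpause.io_formats import CoverageTrack, GeneInterval, build_concatenated_transcriptome


def mann_whitney_auc(scores, labels):
    """Brute-force pairwise P(score_pos > score_neg) with half credit for ties."""
    pos = scores[labels.astype(bool)]
    neg = scores[~labels.astype(bool)]
    wins = ties = 0
    for p in pos:
        wins += np.sum(p > neg)
        ties += np.sum(p == neg)
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        r = ev.roc_auc(np.array([1.0, 2, 3, 4]), np.array([0, 0, 1, 1]))
        assert r.auc == pytest.approx(1.0)

    def test_inverted_separation(self):
        r = ev.roc_auc(np.array([4.0, 3, 2, 1]), np.array([0, 0, 1, 1]))
        assert r.auc == pytest.approx(0.0)

    def test_constant_scores_give_half(self):
        r = ev.roc_auc(np.full(10, 2.0), np.array([1, 0] * 5))
        assert r.auc == pytest.approx(0.5)

    def test_curve_monotone_from_origin_to_one(self):
        rng = np.random.default_rng(61)
        r = ev.roc_auc(rng.normal(size=50), rng.integers(0, 2, size=50))
        assert r.fpr[0] == r.tpr[0] == 0.0
        assert r.fpr[-1] == r.tpr[-1] == 1.0
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)

    def test_equals_mann_whitney_on_random_instances(self):
        rng = np.random.default_rng(62)
        for _ in range(100):
            n = int(rng.integers(10, 500))
            scores = np.round(rng.normal(size=n), 1)  # coarse -> plenty of ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            assert ev.roc_auc(scores, labels).auc == pytest.approx(
                mann_whitney_auc(scores, labels), abs=1e-12)

    def test_complement_symmetry(self):
        rng = np.random.default_rng(63)
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, size=200)
        assert ev.roc_auc(scores, labels).auc + ev.roc_auc(-scores, labels).auc \
            == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(64)
        scores = np.round(rng.normal(size=300), 1)
        labels = rng.integers(0, 2, size=300)
        assert ev.roc_auc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="positive and .* negative"):
            ev.roc_auc(np.arange(5.0), np.ones(5))


class TestPauseFractionByScore:
    def test_all_negative_labels_give_zero_fractions(self):
        rng = np.random.default_rng(65)
        curve = ev.pause_fraction_by_score(rng.normal(size=200), np.zeros(200))
        assert np.all(curve.frac == 0.0)
        assert curve.odds.isna().all()  # f = 0 bins excluded from the odds transform

    def test_bin_tallies_match_brute_force(self):
        rng = np.random.default_rng(66)
        scores = rng.normal(0, 3, size=1000)
        labels = rng.integers(0, 2, size=1000)
        curve = ev.pause_fraction_by_score(scores, labels, bin_width=1.5)
        for _, row in curve.iterrows():
            sel = np.floor(scores / 1.5) * 1.5 + 0.75 == row.bin_center
            assert row.n == sel.sum()
            assert row.frac == pytest.approx(labels[sel].mean())

    def test_pure_bins_have_nan_odds(self):
        scores = np.array([0.1, 0.2, 5.1, 5.2])
        labels = np.array([1, 1, 1, 0])
        curve = ev.pause_fraction_by_score(scores, labels, bin_width=1.0)
        assert np.isnan(curve.odds.iloc[0])  # f = 1
        assert curve.odds.iloc[-1] == pytest.approx(1.0)


class TestFitLogOdds:
    def test_recovers_planted_slope(self):
        rng = np.random.default_rng(67)
        x = rng.normal(0, 5, size=200_000)
        p = 1 / (1 + np.exp(-(-4.0 + 0.5 * x)))
        y = rng.random(len(x)) < p
        fit = ev.fit_log_odds(x, y)
        assert fit.beta == pytest.approx(0.5, rel=0.10)
        assert fit.alpha == pytest.approx(-4.0, rel=0.10)

    def test_null_slope_covered_by_confidence_interval(self):
        rng = np.random.default_rng(68)
        x = rng.normal(0, 5, size=100_000)
        y = rng.random(len(x)) < 0.02
        fit = ev.fit_log_odds(x, y)
        lo, hi = fit.beta_ci()
        assert lo < 0 < hi and abs(fit.beta) < 0.01

    def test_score_shift_moves_only_the_intercept(self):
        rng = np.random.default_rng(69)
        x = rng.normal(0, 2, size=20_000)
        y = rng.random(len(x)) < 1 / (1 + np.exp(-(-1.0 + 0.8 * x)))
        f1 = ev.fit_log_odds(x, y)
        f2 = ev.fit_log_odds(x + 3.0, y)
        assert f2.beta == pytest.approx(f1.beta, abs=1e-6)
        assert f2.alpha == pytest.approx(f1.alpha - 3.0 * f1.beta, abs=1e-5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            ev.fit_log_odds(np.arange(10.0), np.zeros(10))


class TestProfiles:
    def test_single_site_profile_is_the_raw_flank(self):
        values = np.arange(100.0)
        prof = ev.average_profile(values, [50], halfwidth=5)
        np.testing.assert_allclose(prof, values[45:56])

    def test_two_sites_average_elementwise(self):
        values = np.arange(100.0)
        prof = ev.average_profile(values, [30, 60], halfwidth=3)
        np.testing.assert_allclose(prof, (values[27:34] + values[57:64]) / 2)

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(70)
        values = rng.normal(size=500)
        sites = rng.integers(20, 480, size=30)
        prof = ev.average_profile(values, sites, halfwidth=10)
        oracle = np.mean([values[s - 10 : s + 11] for s in sites], axis=0)
        np.testing.assert_allclose(prof, oracle, atol=1e-12)

    def test_sites_with_invalid_flanks_are_dropped(self):
        values = np.arange(100.0)
        values[20] = np.nan
        prof = ev.average_profile(values, [22, 50], halfwidth=5)
        np.testing.assert_allclose(prof, values[45:56])  # only site 50 usable

    def test_running_sum_width_one_is_identity(self):
        x = np.arange(10.0)
        np.testing.assert_allclose(ev.running_sum(x, 1), x)

    def test_running_sum_constant_interior(self):
        x = np.full(20, 2.0)
        out = ev.running_sum(x, 8)
        assert np.all(out[4:16] == pytest.approx(16.0))
        assert np.isnan(out[0]) and np.isnan(out[-1])

    def test_running_sum_matches_brute_force(self):
        rng = np.random.default_rng(71)
        x = rng.normal(size=60)
        out = ev.running_sum(x, 8)
        for j in range(60):
            lo, hi = j - 4, j + 4
            if lo < 0 or hi > 60:
                assert np.isnan(out[j])
            else:
                assert out[j] == pytest.approx(np.sum(x[lo:hi]), abs=1e-12)


class TestNullBand:
    def test_same_seed_reproduces_band_exactly(self):
        rng = np.random.default_rng(72)
        values = rng.normal(size=2000)
        cands = np.arange(50, 1950)
        sites = rng.choice(cands, size=40, replace=False)
        b1 = ev.null_band(values, sites, cands, halfwidth=10, n_resamples=50, seed=3)
        b2 = ev.null_band(values, sites, cands, halfwidth=10, n_resamples=50, seed=3)
        np.testing.assert_array_equal(b1.lo, b2.lo)
        np.testing.assert_array_equal(b1.hi, b2.hi)

    def test_single_resample_band_collapses(self):
        rng = np.random.default_rng(73)
        values = rng.normal(size=1000)
        cands = np.arange(20, 980)
        b = ev.null_band(values, cands[:30], cands, halfwidth=5, n_resamples=1, seed=4)
        np.testing.assert_array_equal(b.lo, b.hi)

    def test_band_brackets_resampled_means(self):
        rng = np.random.default_rng(74)
        values = rng.normal(size=3000)
        cands = np.arange(40, 2960)
        b = ev.null_band(values, cands[:100], cands, halfwidth=8, n_resamples=200, seed=5)
        assert np.all(b.lo <= b.hi)

    def test_oversized_site_set_rejected(self):
        values = np.zeros(100)
        with pytest.raises(ValueError, match="resample"):
            ev.null_band(values, np.arange(10, 90), np.arange(40, 50), halfwidth=5)


class TestExpressionFilter:
    def _tx(self, lengths):
        genome = {"c": "A" * sum(lengths)}
        genes, pos = [], 0
        for k, L in enumerate(lengths):
            genes.append(GeneInterval("c", pos, pos + L, "+", f"g{k}"))
            pos += L
        return build_concatenated_transcriptome(genome, genes)

    def test_retains_only_above_mean_density(self):
        tx = self._tx([100, 100])
        counts = np.concatenate([np.full(100, 1), np.full(100, 3)])
        mask = ev.expression_filter(CoverageTrack(counts, "WT"), tx)
        np.testing.assert_array_equal(mask, [False, True])

    def test_uniform_density_retains_nothing(self):
        tx = self._tx([100, 200])
        counts = np.full(300, 2)
        mask = ev.expression_filter(CoverageTrack(counts, "WT"), tx)
        assert not mask.any()

    def test_lognormal_retained_fraction_matches_expectation(self):
        # density_g ~ rate_g for equal-length genes; retained iff rate > mean
        rng = np.random.default_rng(75)
        n_genes, L = 400, 50
        rates = np.exp(rng.normal(0, 0.75, size=n_genes))
        counts = rng.poisson(np.repeat(rates, L))
        tx = self._tx([L] * n_genes)
        mask = ev.expression_filter(CoverageTrack(counts, "WT"), tx)
        # P(lognormal(0, s) > E) = Phi(-s/2 - ln(E)/s + ...) -- use empirical rates
        expected = np.mean(rates > rates.mean())
        assert mask.mean() == pytest.approx(expected, abs=0.08)
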