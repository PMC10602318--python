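import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylsink import (
    SignalMatrix,
    bin_regions_by_mean_signal,
    compare_to_null,
    filter_by_signal_above_input,
    filter_regions_by_peak_support,
    fit_locus_models,
    fit_negative_binomial_glm,
    group_compare_distances,
    make_promoters,
    make_regions,
    null_tvalues,
    peak_tss_distance,
    sum_overlapping_peak_widths,
)
from methylsink.chromatin import region_peak_overlap


def _genes(rows):
    return pd.DataFrame(rows, columns=["id", "chrom", "strand", "tss"])


def _peaks(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestMakePromoters:
    def test_plus_strand_window(self):
        regions = make_promoters(_genes([("g", "chr1", "+", 10000)]))
        assert (regions.loc[0, "start"], regions.loc[0, "end"]) == (8000, 10200)

    def test_minus_strand_mirrored(self):
        regions = make_promoters(_genes([("g", "chr1", "-", 10000)]))
        assert (regions.loc[0, "start"], regions.loc[0, "end"]) == (9800, 12000)

    def test_clipped_at_zero(self):
        regions = make_promoters(_genes([("g", "chr1", "+", 500)]))
        assert (regions.loc[0, "start"], regions.loc[0, "end"]) == (0, 700)

    def test_unknown_strand_warns_and_uses_plus(self):
        with pytest.warns(UserWarning, match="strand"):
            regions = make_promoters(_genes([("g", "chr1", "?", 10000)]))
        assert (regions.loc[0, "start"], regions.loc[0, "end"]) == (8000, 10200)


class TestPeakSupport:
    def _regions(self):
        return make_regions(["chr1"], [1000], [2000], ids=["r1"])

    def test_support_thresholds(self):
        regions = self._regions()
        hit = _peaks([("chr1", 1500, 1600)])
        miss = _peaks([("chr1", 5000, 5100)])
        peak_sets = {"s1": hit, "s2": hit, "s3": hit, "s4": miss}
        assert len(filter_regions_by_peak_support(regions, peak_sets, 0.75)) == 1
        assert len(filter_regions_by_peak_support(regions, peak_sets, 1.0)) == 0

    def test_abutting_peak_no_overlap(self):
        regions = self._regions()
        abut = _peaks([("chr1", 500, 1000)])  # peak.end == region.start
        assert not region_peak_overlap(regions, abut)[0]
        touch = _peaks([("chr1", 500, 1001)])
        assert region_peak_overlap(regions, touch)[0]

    def test_full_support_kept_at_any_fraction(self):
        regions = self._regions()
        hit = _peaks([("chr1", 900, 1100)])
        peak_sets = {f"s{i}": hit for i in range(5)}
        assert len(filter_regions_by_peak_support(regions, peak_sets, 1.0)) == 1

    def test_empty_peak_sets_rejected(self):
        with pytest.raises(ValueError):
            filter_regions_by_peak_support(self._regions(), {}, 0.5)

    def test_overlap_matches_per_base_oracle(self, rng):
        # randomized toy genome <= 10 kb, brute-force base-set oracle
        for _ in range(20):
            n_r, n_p = rng.integers(1, 8, size=2)
            rs = rng.integers(0, 9000, size=n_r)
            regions = make_regions(
                ["chrT"] * n_r, rs, rs + rng.integers(1, 1000, size=n_r),
                ids=[f"r{i}" for i in range(n_r)],
            )
            ps = rng.integers(0, 9000, size=n_p)
            peaks = _peaks(
                [("chrT", int(s), int(s + w)) for s, w in zip(ps, rng.integers(1, 800, size=n_p))]
            )
            got = region_peak_overlap(regions, peaks)
            peak_bases = set()
            for _, row in peaks.iterrows():
                peak_bases.update(range(row.start, row.end))
            for i, row in regions.iterrows():
                expected = bool(peak_bases & set(range(row.start, row.end)))
                assert got[i] == expected


class TestSignalFilters:
    def _signal(self, rows, ids=None):
        vals = pd.DataFrame(
            rows,
            index=ids or [f"r{i}" for i in range(len(rows))],
            columns=[f"s{i}" for i in range(len(rows[0]))],
        )
        return SignalMatrix(values=vals, mark="test")

    def test_mean_above_input_filter(self):
        sig = self._signal([[1.0, 0.0], [-0.3, 0.1], [0.1, -0.1]])
        kept = filter_by_signal_above_input(sig)
        assert kept.values.index.tolist() == ["r0"]

    def test_all_positive_unchanged(self):
        sig = self._signal([[0.5, 0.2], [0.1, 0.3]])
        assert len(filter_by_signal_above_input(sig).values) == 2

    def test_empty_result_warns(self):
        sig = self._signal([[-1.0, -1.0]])
        with pytest.warns(UserWarning):
            kept = filter_by_signal_above_input(sig)
        assert kept.values.empty

    def test_binning_even_split(self, rng):
        vals = rng.normal(size=(10, 3))
        sig = self._signal(vals.tolist())
        bins = bin_regions_by_mean_signal(sig, 2)
        assert bins.value_counts().tolist() == [5, 5]

    def test_bin_means_increasing(self, rng):
        vals = rng.normal(size=(30, 4))
        sig = self._signal(vals.tolist())
        bins = bin_regions_by_mean_signal(sig, 3)
        means = sig.values.mean(axis=1).groupby(bins).mean()
        assert means.is_monotonic_increasing

    def test_tie_breaking_deterministic(self):
        sig = self._signal([[1.0, 1.0]] * 4)
        b1 = bin_regions_by_mean_signal(sig, 2)
        b2 = bin_regions_by_mean_signal(sig, 2)
        pd.testing.assert_series_equal(b1, b2)
        assert b1.loc["r0"] == 0 and b1.loc["r3"] == 1

    def test_fewer_regions_than_bins(self):
        sig = self._signal([[1.0, 2.0]])
        with pytest.raises(ValueError):
            bin_regions_by_mean_signal(sig, 2)


class TestPeakWidths:
    def test_full_width_counted(self):
        regions = make_regions(["chr1"], [250], [400], ids=["r"])
        widths = sum_overlapping_peak_widths(regions, _peaks([("chr1", 100, 300)]))
        assert widths.loc["r"] == 200  # entire peak, not the clipped part

    def test_no_overlap_zero(self):
        regions = make_regions(["chr1"], [250], [400], ids=["r"])
        widths = sum_overlapping_peak_widths(regions, _peaks([("chr1", 500, 700)]))
        assert widths.loc["r"] == 0

    def test_additivity(self):
        regions = make_regions(["chr1"], [0], [1000], ids=["r"])
        peaks = _peaks([("chr1", 100, 200), ("chr1", 300, 350)])
        assert sum_overlapping_peak_widths(regions, peaks).loc["r"] == 150


class TestLocusModels:
    def _signal_from(self, Y, samples=None):
        df = pd.DataFrame(
            Y, index=[f"r{i}" for i in range(Y.shape[0])],
            columns=samples or [f"s{i}" for i in range(Y.shape[1])],
        )
        return SignalMatrix(values=df, mark="t")

    def test_planted_slope_recovered(self, rng):
        n = 30
        x = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        Y = 2.0 * x.to_numpy()[None, :] + rng.normal(0, 0.01, size=(5, n))
        res = fit_locus_models(self._signal_from(Y), x)
        assert (res.tvalues > 50).all()
        np.testing.assert_allclose(res.slopes, 2.0, atol=0.01)

    def test_permuted_predictor_null(self, rng):
        n = 30
        x = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        Y = rng.normal(size=(200, n))
        res = fit_locus_models(self._signal_from(Y), x)
        assert abs(res.tvalues.mean()) < 0.2

    def test_ols_matches_statsmodels_oracle(self, rng):
        import statsmodels.api as sm

        n = 6
        x = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        cohort = pd.Series(["a", "a", "a", "b", "b", "b"], index=x.index)
        Y = rng.normal(size=(4, n))
        res = fit_locus_models(self._signal_from(Y), x, cohort=cohort)
        X = np.column_stack(
            [np.ones(n), x, (cohort == "b").astype(float)]
        )
        for i in range(4):
            fit = sm.OLS(Y[i], X).fit()
            assert res.tvalues.iloc[i] == pytest.approx(fit.tvalues[1], abs=1e-8)
            assert res.slopes.iloc[i] == pytest.approx(fit.params[1], abs=1e-10)

    def test_interaction_term_included(self, rng):
        n = 40
        samples = [f"s{i}" for i in range(n)]
        x = pd.Series(rng.normal(size=n), index=samples)
        cohort = pd.Series(["a"] * 20 + ["b"] * 20, index=samples)
        # slope differs by cohort; the main effect is the cohort-a slope
        y = np.where(cohort == "a", 1.0 * x, 3.0 * x) + rng.normal(0, 0.05, n)
        res = fit_locus_models(
            self._signal_from(y[None, :]), x, cohort=cohort, interaction=True
        )
        assert res.slopes.iloc[0] == pytest.approx(1.0, abs=0.05)

    def test_small_cohorts_dropped(self, rng):
        n = 10
        samples = [f"s{i}" for i in range(n)]
        x = pd.Series(rng.normal(size=n), index=samples)
        cohort = pd.Series(["a"] * 8 + ["tiny"] * 2, index=samples)
        Y = rng.normal(size=(3, n))
        res = fit_locus_models(self._signal_from(Y), x, cohort=cohort)
        assert res.n_samples == 8

    def test_mixed_model_with_donor_grouping(self, rng):
        n_donors, per = 10, 3
        n = n_donors * per
        samples = [f"s{i}" for i in range(n)]
        donors = pd.Series(np.repeat([f"d{i}" for i in range(n_donors)], per), index=samples)
        x = pd.Series(rng.normal(size=n), index=samples)
        donor_eff = np.repeat(rng.normal(0, 1.0, n_donors), per)
        y = -0.8 * x.to_numpy() + donor_eff + rng.normal(0, 0.3, n)
        res = fit_locus_models(
            self._signal_from(y[None, :]), x, random_intercept=donors
        )
        assert res.model == "mixed"
        assert res.slopes.iloc[0] == pytest.approx(-0.8, abs=0.2)

    def test_trivial_donor_grouping_reduces_to_ols(self, rng):
        n = 12
        samples = [f"s{i}" for i in range(n)]
        donors = pd.Series([f"d{i}" for i in range(n)], index=samples)
        x = pd.Series(rng.normal(size=n), index=samples)
        Y = rng.normal(size=(3, n))
        res = fit_locus_models(self._signal_from(Y), x, random_intercept=donors)
        assert res.model == "ols"


class TestNullTvalues:
    def test_degenerate_pool_equals_observed(self, rng):
        n = 20
        samples = [f"s{i}" for i in range(n)]
        x = pd.Series(rng.normal(size=n), index=samples)
        Y = 1.5 * x.to_numpy()[None, :] + rng.normal(0, 0.5, size=(10, n))
        sig = SignalMatrix(
            values=pd.DataFrame(Y, index=[f"r{i}" for i in range(10)], columns=samples)
        )
        expr = pd.DataFrame([x.to_numpy()], index=["thegene"], columns=samples)
        observed = fit_locus_models(sig, x)
        null = null_tvalues(sig, expr, n_random=1, seed=0)
        np.testing.assert_allclose(null, observed.tvalues, atol=1e-10)

    def test_independent_signal_null_near_zero(self, rng):
        n = 25
        samples = [f"s{i}" for i in range(n)]
        Y = rng.normal(size=(100, n))
        sig = SignalMatrix(
            values=pd.DataFrame(Y, index=[f"r{i}" for i in range(100)], columns=samples)
        )
        expr = pd.DataFrame(
            rng.normal(size=(60, n)),
            index=[f"g{i}" for i in range(60)],
            columns=samples,
        )
        null = null_tvalues(sig, expr, n_random=50, seed=1)
        assert abs(null.mean()) < 0.2

    def test_seed_changes_sample_but_results_correlate(self, rng):
        n = 25
        samples = [f"s{i}" for i in range(n)]
        base = rng.normal(size=n)
        Y = base[None, :] + rng.normal(0, 0.5, size=(50, n))
        sig = SignalMatrix(
            values=pd.DataFrame(Y, index=[f"r{i}" for i in range(50)], columns=samples)
        )
        expr = pd.DataFrame(
            base[None, :] + rng.normal(0, 1.0, size=(80, n)),
            index=[f"g{i}" for i in range(80)],
            columns=samples,
        )
        n1 = null_tvalues(sig, expr, n_random=30, seed=1)
        n2 = null_tvalues(sig, expr, n_random=30, seed=2)
        assert not np.allclose(n1, n2)
        assert np.corrcoef(n1, n2)[0, 1] > 0.5

    def test_pool_too_small(self, rng):
        sig = SignalMatrix(
            values=pd.DataFrame(
                rng.normal(size=(5, 10)),
                index=[f"r{i}" for i in range(5)],
                columns=[f"s{i}" for i in range(10)],
            )
        )
        expr = pd.DataFrame(
            rng.normal(size=(3, 10)),
            index=["a", "b", "c"],
            columns=sig.sample_ids,
        )
        with pytest.raises(ValueError, match="pool"):
            null_tvalues(sig, expr, n_random=10, seed=0)


class TestCompareToNull:
    def test_identical_p_one(self):
        t = pd.Series([1.0, 2, 3, -1, 0.5], index=[f"r{i}" for i in range(5)])
        stat, p = compare_to_null(t, t.copy())
        assert p == 1.0

    def test_exact_enumeration_n6(self):
        obs = pd.Series(np.arange(6, dtype=float), index=[f"r{i}" for i in range(6)])
        null = obs + np.linspace(0.5, 1.0, 6)
        _, p = compare_to_null(obs, null)
        assert p == pytest.approx(2 / 2**6)  # 0.03125

    def test_antisymmetry(self, rng):
        obs = pd.Series(rng.normal(size=30), index=[f"r{i}" for i in range(30)])
        null = pd.Series(rng.normal(size=30), index=obs.index)
        s1, p1 = compare_to_null(obs, null)
        s2, p2 = compare_to_null(null, obs)
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_too_few_regions(self):
        t = pd.Series([1.0, 2, 3], index=["a", "b", "c"])
        with pytest.raises(ValueError):
            compare_to_null(t, t + 1)


class TestNegativeBinomialGLM:
    def test_intercept_only_recovers_mean(self, rng):
        y = rng.poisson(20, size=100)
        table = fit_negative_binomial_glm(y)
        assert np.exp(table.loc["intercept", "coef"]) == pytest.approx(
            y.mean(), rel=1e-3
        )

    def test_poisson_limit_matches_poisson_oracle(self, rng):
        import statsmodels.api as sm

        n = 400
        x = rng.normal(size=n)
        mu = np.exp(1.0 + 0.4 * x)
        y = rng.poisson(mu)
        table = fit_negative_binomial_glm(y, x)
        X = np.column_stack([np.ones(n), x])
        oracle = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(
            table["coef"].to_numpy(), oracle.params, atol=1e-3
        )

    def test_nb_coefficients_recovered(self, rng):
        n = 500
        x = rng.normal(size=n)
        mu = np.exp(1.0 - 0.5 * x)
        alpha = 0.3
        y = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu))
        table = fit_negative_binomial_glm(y, x)
        assert table.loc["x1", "coef"] == pytest.approx(-0.5, abs=0.15)
        assert table.attrs["family"] == "negative_binomial"
        assert table.attrs["alpha"] == pytest.approx(alpha, abs=0.15)

    def test_ci_coverage_calibrated(self, rng):
        n = 300
        alpha = 0.2
        hits = 0
        n_sims = 60
        for _ in range(n_sims):
            x = rng.normal(size=n)
            mu = np.exp(1.0 - 0.5 * x)
            y = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu))
            tab = fit_negative_binomial_glm(y, x)
            lo = tab.loc["x1", "coef"] - 1.96 * tab.loc["x1", "se"]
            hi = tab.loc["x1", "coef"] + 1.96 * tab.loc["x1", "se"]
            hits += lo <= -0.5 <= hi
        assert 0.85 <= hits / n_sims <= 1.0

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            fit_negative_binomial_glm([1, 2, 3], np.ones((3, 1)))


class TestPeakTssDistance:
    def test_spanning_peak_zero(self):
        genes = _genes([("g", "chr1", "+", 1000)])
        d = peak_tss_distance(genes, _peaks([("chr1", 900, 1100)]))
        assert d.loc["g"] == 0.0

    def test_downstream_positive_on_plus_strand(self):
        genes = _genes([("g", "chr1", "+", 1000)])
        d = peak_tss_distance(genes, _peaks([("chr1", 1200, 1300)]))
        assert d.loc["g"] == 200.0

    def test_upstream_negative_on_plus_strand(self):
        genes = _genes([("g", "chr1", "+", 1000)])
        d = peak_tss_distance(genes, _peaks([("chr1", 700, 800)]))
        assert d.loc["g"] == -201.0

    def test_minus_strand_flips_sign(self):
        genes = _genes([("g", "chr1", "-", 1000)])
        d = peak_tss_distance(genes, _peaks([("chr1", 1200, 1300)]))
        assert d.loc["g"] == -200.0  # genomically right = upstream on minus strand

    def test_missing_chromosome_missing_distance(self):
        genes = _genes([("g", "chrX", "+", 1000)])
        d = peak_tss_distance(genes, _peaks([("chr1", 1200, 1300)]))
        assert np.isnan(d.loc["g"])

    def test_identical_groups_p_one(self):
        a = pd.Series([100.0, -50, 200], index=["g1", "g2", "g3"])
        _, p = group_compare_distances(a, a.copy())
        assert p == 1.0

    def test_shifted_groups_significant(self, rng):
        a = pd.Series(rng.normal(0, 10, 40))
        b = pd.Series(rng.normal(100, 10, 40))
        _, p = group_compare_distances(a, b)
        assert p < 1e-6
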