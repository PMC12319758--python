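import numpy as np
import pandas as pd
import pytest

from fibertract.cohort import CohortSpec, make_feature_table_direct
from fibertract.harmonize import (
    AveragedHistogram,
    averaged_site_histogram,
    apply_harmonization,
    fit_harmonization,
    mode_scaling_factor,
    zscore_standardize,
)
from fibertract.stats import site_effect_check


class TestAveragedHistogram:
    def test_single_subject_equals_own_histogram(self):
        vals = np.array([0.4, 0.5, 0.5, 0.6, 0.7])
        edges = np.linspace(0, 1, 11)
        avg = averaged_site_histogram([vals], edges)
        own, _ = np.histogram(vals, bins=edges, density=True)
        assert np.allclose(avg.counts, own)

    def test_two_disjoint_subjects_half_mass_each(self):
        edges = np.linspace(0, 1, 21)
        a = np.full(50, 0.25)
        b = np.full(50, 0.75)
        avg = averaged_site_histogram([a, b], edges)
        width = edges[1] - edges[0]
        mass = avg.counts * width
        assert mass[mass > 0].size == 2
        assert np.allclose(mass[mass > 0], 0.5)

    def test_converges_to_true_density(self):
        """20 subjects from one normal: the averaged histogram tracks the
        true density within a Monte-Carlo envelope."""
        from scipy.stats import norm

        rng = np.random.default_rng(0)
        edges = np.linspace(-4, 4, 41)
        subs = [rng.normal(0, 1, 2000) for _ in range(20)]
        avg = averaged_site_histogram(subs, edges)
        centers = avg.centers
        true = norm.pdf(centers)
        assert np.max(np.abs(avg.counts - true)) < 0.03

    def test_empty_subject_skipped_with_warning(self):
        edges = np.linspace(0, 1, 5)
        with pytest.warns(UserWarning, match="skipped"):
            avg = averaged_site_histogram([np.array([]), np.array([0.5])], edges)
        assert avg.counts.sum() > 0

    def test_zero_subjects_raises(self):
        with pytest.raises(ValueError, match="no subjects"):
            averaged_site_histogram([np.array([])], np.linspace(0, 1, 5))


class TestModeFactor:
    def _hist(self, counts, lo=0.0, hi=None):
        counts = np.asarray(counts, float)
        hi = hi if hi is not None else counts.size
        edges = np.linspace(lo, hi, counts.size + 1)
        return AveragedHistogram(bin_edges=edges, counts=counts)

    def test_reciprocal_of_peak(self):
        # peak bin center at 0.8 -> factor 1.25
        edges = np.linspace(0.75, 0.85, 2)
        h = AveragedHistogram(bin_edges=edges, counts=np.array([1.0]))
        mode, fac = mode_scaling_factor(h, smoothing_window=1)
        assert mode == pytest.approx(0.8)
        assert fac == pytest.approx(1.25)

    def test_peak_at_one_identity(self):
        edges = np.array([0.9, 0.95, 1.05, 1.15])
        h = AveragedHistogram(bin_edges=edges, counts=np.array([1.0, 5.0, 1.0]))
        mode, fac = mode_scaling_factor(h, smoothing_window=1)
        assert mode == pytest.approx(1.0)
        assert fac == pytest.approx(1.0)

    def test_tie_breaks_to_lowest_center(self):
        # equal maxima at centers 0.6 and 0.9 -> mode 0.6, factor ~1.667
        edges = np.array([0.55, 0.65, 0.85, 0.95])
        h = AveragedHistogram(bin_edges=edges, counts=np.array([5.0, 1.0, 5.0]))
        mode, fac = mode_scaling_factor(h, smoothing_window=1)
        assert mode == pytest.approx(0.6)
        assert fac == pytest.approx(1.0 / 0.6, rel=1e-6)

    def test_all_zero_counts_raises(self):
        with pytest.raises(ValueError, match="zero"):
            mode_scaling_factor(self._hist([0, 0, 0]))

    def test_nonpositive_mode_raises(self):
        edges = np.array([-1.0, -0.5, 0.5])
        h = AveragedHistogram(bin_edges=edges, counts=np.array([5.0, 1.0]))
        with pytest.raises(ValueError, match="not positive"):
            mode_scaling_factor(h, smoothing_window=1)


class TestApplyHarmonization:
    def test_unit_factors_near_identity(self):
        """No site effect: estimated factors agree across sites — tightly at
        map granularity, coarsely on 36-value bundle summaries."""
        from fibertract.cohort import make_subject_scalar_samples
        from fibertract.harmonize import fit_harmonization_values

        spec = CohortSpec(site_factors={"siteA": 1.0, "siteB": 1.0, "siteC": 1.0},
                          sham_missing_rate=0.0, tbi_missing_rate=0.0)
        samples = make_subject_scalar_samples(spec, seed=0)
        fv = fit_harmonization_values(samples)
        for m in ("FA", "MD", "RD", "AD"):
            fs = [fv.factor(s, m) for s in ("siteA", "siteB", "siteC")]
            assert np.ptp(fs) / np.mean(fs) < 0.02
        tab, _ = make_feature_table_direct(spec, seed=0)
        ft_tab = fit_harmonization(tab)
        for m in ("FA", "MD"):
            fs = [ft_tab.factor(s, m) for s in ("siteA", "siteB", "siteC")]
            assert np.ptp(fs) / np.mean(fs) < 0.12

    def test_value_times_factor(self):
        spec = CohortSpec(sham_missing_rate=0.0, tbi_missing_rate=0.0)
        tab, _ = make_feature_table_direct(spec, seed=0)
        factors = fit_harmonization(tab)
        harm = apply_harmonization(tab, factors)
        col = "fornix_L__MD"
        for site in ("siteA", "siteB", "siteC"):
            f = factors.factor(site, "MD")
            sub = tab.site == site
            assert np.allclose(harm.loc[sub, col], tab.loc[sub, col] * f)

    def test_missing_cells_untouched(self):
        tab, _ = make_feature_table_direct(CohortSpec(), seed=1)
        harm = apply_harmonization(tab, fit_harmonization(tab))
        assert harm.filter(like="__").isna().equals(tab.filter(like="__").isna())

    def test_unknown_site_raises(self):
        tab, _ = make_feature_table_direct(CohortSpec(), seed=0)
        factors = fit_harmonization(tab)
        tab2 = tab.copy()
        tab2.loc[0, "site"] = "siteX"
        with pytest.raises(KeyError, match="siteX"):
            apply_harmonization(tab2, factors)

    def test_site_modes_align_after_harmonization(self):
        """Multiplicative site factors (1.0, 1.15, 0.9): after reciprocal-
        mode scaling the per-site intensity modes agree within a bin width
        and recovered factors match the injected ones."""
        from fibertract.cohort import make_subject_scalar_samples
        from fibertract.harmonize import fit_harmonization_values

        spec = CohortSpec(sham_missing_rate=0.0, tbi_missing_rate=0.0)
        samples = make_subject_scalar_samples(spec, seed=5)
        fv = fit_harmonization_values(samples)
        for m in ("FA", "MD", "RD", "AD"):
            # recovered relative factors track the injected 1.0/1.15/0.9
            fA = fv.factor("siteA", m)
            assert fv.factor("siteB", m) / fA == pytest.approx(1 / 1.15, rel=0.03)
            assert fv.factor("siteC", m) / fA == pytest.approx(1 / 0.9, rel=0.03)
            # and rescaled samples share a common mode
            rescaled = {
                m: {
                    s: [v * fv.factor(s, m) for v in samples[m][s]]
                    for s in samples[m]
                }
            }
            refit = fit_harmonization_values(rescaled)
            modes = [refit.modes[(s, m)] for s in ("siteA", "siteB", "siteC")]
            h = refit.histograms[("siteA", m)]
            bin_w = h.bin_edges[1] - h.bin_edges[0]
            assert np.ptp(modes) <= 3 * bin_w


class TestZScore:
    def test_printed_example(self):
        tab = pd.DataFrame({
            "subject": [f"s{i}" for i in range(6)], "site": "A",
            "group": ["sham"] * 5 + ["TBI"], "timepoint": "2d", "apnea": 1.0,
            "b__MD": [0.5 - 0.1 * np.sqrt(2), 0.5, 0.5, 0.5,
                      0.5 + 0.1 * np.sqrt(2), 0.3],
        })
        # sham mean 0.5, sd 0.1; TBI value 0.3 -> z = -2
        out, ref = zscore_standardize(tab)
        assert ref.mu["b__MD"] == pytest.approx(0.5)
        assert ref.sigma["b__MD"] == pytest.approx(0.1)
        assert out.loc[5, "b__MD"] == pytest.approx(-2.0)
        out_abs, _ = zscore_standardize(tab, zmode="absolute")
        assert out_abs.loc[5, "b__MD"] == pytest.approx(2.0)

    def test_sham_rows_standardized_to_unit(self):
        tab, _ = make_feature_table_direct(
            CohortSpec(sham_missing_rate=0.0, tbi_missing_rate=0.0), seed=0
        )
        out, _ = zscore_standardize(tab)
        sham = out[out.group == "sham"].filter(like="__")
        assert np.allclose(sham.mean(), 0.0, atol=1e-10)
        assert np.allclose(sham.std(ddof=1), 1.0, atol=1e-10)

    def test_invariant_to_feature_rescaling(self):
        """z is unchanged under x -> a x when the reference is recomputed."""
        tab, _ = make_feature_table_direct(
            CohortSpec(sham_missing_rate=0.0, tbi_missing_rate=0.0), seed=2
        )
        out1, _ = zscore_standardize(tab)
        tab2 = tab.copy()
        feats = [c for c in tab.columns if "__" in c]
        tab2[feats] = tab2[feats] * 3.7
        out2, _ = zscore_standardize(tab2)
        assert np.allclose(out1[feats].to_numpy(), out2[feats].to_numpy(),
                           atol=1e-9)

    def test_zero_sigma_named_in_error(self):
        tab = pd.DataFrame({
            "subject": ["s0", "s1", "s2"], "site": "A",
            "group": ["sham", "sham", "TBI"], "timepoint": "2d", "apnea": 1.0,
            "flat__MD": [1.0, 1.0, 2.0],
        })
        with pytest.raises(ValueError, match="flat__MD"):
            zscore_standardize(tab)


class TestSiteEffectRemoval:
    def test_site_coefficient_shrinks_80_percent(self):
        """Fixed-effects site term shrinks >= 80% after harmonization while
        the group term keeps its sign.  Factors are fitted at map granularity
        (per-subject intensity samples) and applied to the bundle table, the
        architecture the harmonization is designed for."""
        from fibertract.cohort import make_subject_scalar_samples
        from fibertract.harmonize import fit_harmonization_values

        spec = CohortSpec()
        tab, _ = make_feature_table_direct(spec, seed=1)
        factors = fit_harmonization_values(
            make_subject_scalar_samples(spec, seed=1)
        )
        harm = apply_harmonization(tab, factors)
        col = "fimbria_L__MD"
        pre = site_effect_check(tab, col)
        post = site_effect_check(harm, col)
        site_terms = [i for i in pre.index if i.startswith("site")]
        rel_pre = np.abs(pre.loc[site_terms, "coef"] / pre.loc["const", "coef"])
        rel_post = np.abs(post.loc[site_terms, "coef"] / post.loc["const", "coef"])
        shrink = 1.0 - rel_post.mean() / rel_pre.mean()
        assert shrink >= 0.80
        assert np.sign(pre.loc["group[TBI]", "coef"]) == np.sign(
            post.loc["group[TBI]", "coef"]
        )

    def test_pipeline_invariant_to_global_rescaling(self):
        """Rescaling all sites by one constant changes nothing after
        harmonize -> standardize."""
        from fibertract.pipeline import prepare_features

        tab, _ = make_feature_table_direct(CohortSpec(), seed=3)
        res1 = prepare_features(tab)
        tab2 = tab.copy()
        feats = [c for c in tab.columns if "__" in c]
        tab2[feats] = tab2[feats] * 2.5
        res2 = prepare_features(tab2)
        assert np.allclose(
            res1.table[res1.table.columns[5:]].to_numpy(),
            res2.table[res2.table.columns[5:]].to_numpy(),
            atol=1e-8,
        )
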