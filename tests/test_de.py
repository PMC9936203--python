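import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from hypothesis import given, settings
from hypothesis import strategies as st_h

from ncscreen import de, simulate
from ncscreen.intervals import AnnotatedFeature, AnnotationSet, GenomicInterval


class TestSizeFactors:
    def test_identical_columns_unit_factors(self):
        c = pd.DataFrame({"a": [5, 9, 2], "b": [5, 9, 2]})
        assert np.allclose(de.size_factors(c), 1.0)

    def test_hand_median_of_ratios(self):
        c = pd.DataFrame([[2, 8], [4, 16], [6, 24]], columns=["a", "b"])
        assert np.allclose(de.size_factors(c), [0.5, 2.0])

    def test_scale_equivariance_of_factor_ratios(self, counts_sim):
        """Multiplying one column by c multiplies its factor by c, relative
        to the other samples (the absolute factors share the geometric-mean
        reference, so only ratios are scale-equivariant exactly)."""
        counts, _, _ = counts_sim
        sf = de.size_factors(counts)
        scaled = counts.copy()
        scaled.iloc[:, 0] = scaled.iloc[:, 0] * 3
        sf2 = de.size_factors(scaled)
        assert sf2.iloc[0] / sf2.iloc[1] == pytest.approx(
            3 * sf.iloc[0] / sf.iloc[1], rel=1e-9
        )

    def test_rejects_without_allpositive_gene(self):
        c = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError):
            de.size_factors(c)

    def test_recovers_planted_factors(self, counts_sim):
        counts, design, truth = counts_sim
        sf = de.size_factors(counts)
        planted = np.array([truth.size_factors[s] for s in design.index])
        r = np.corrcoef(sf, planted)[0, 1]
        assert r > 0.99


class TestFilterFeatures:
    def _ann(self):
        feats = [
            AnnotatedFeature(GenomicInterval("chr", i * 100, i * 100 + 50, "+"), fid, cls)
            for i, (fid, cls) in enumerate(
                [("g1", "coding_gene"), ("g2", "coding_gene"),
                 ("r1", "rRNA"), ("r2", "rRNA"), ("t1", "tmRNA"), ("s1", "SRP")]
            )
        ]
        return AnnotationSet(features=feats, seq_lengths={"chr": 10_000})

    def test_no_exclusions_identity(self):
        c = pd.DataFrame({"a": [1, 2]}, index=["x", "y"])
        out, n = de.filter_features(c, None)
        assert out.equals(c) and n == 0

    def test_excluded_classes_removed(self):
        ann = self._ann()
        c = pd.DataFrame(
            np.arange(12).reshape(6, 2), index=["g1", "g2", "r1", "r2", "t1", "s1"]
        )
        out, n = de.filter_features(c, ann)
        assert list(out.index) == ["g1", "g2"] and n == 4

    def test_bookkeeping(self):
        ann = self._ann()
        c = pd.DataFrame(np.ones((6, 2)), index=["g1", "g2", "r1", "r2", "t1", "s1"])
        out, n = de.filter_features(c, ann, excluded_ids={"g2"})
        assert len(out) == len(c) - n


class TestFitting:
    def test_matches_statsmodels_glm(self, counts_sim):
        """Independent cross-check: the batched IRLS equals statsmodels'
        NB GLM (fixed dispersion) coefficient for coefficient."""
        import statsmodels.api as sm

        counts, design, _ = counts_sim
        sub = counts.iloc[:8]
        sf = de.size_factors(counts)
        alpha = pd.Series(0.1, index=sub.index)
        fit = de.fit_all(sub, design, sf, alpha=alpha, quasi=False)
        X = de.design_matrix(design)
        for i in range(len(sub)):
            m = sm.GLM(
                sub.iloc[i].to_numpy(),
                X,
                family=sm.families.NegativeBinomial(alpha=0.1),
                offset=np.log(sf.to_numpy()),
            ).fit()
            assert np.allclose(fit.beta[i], m.params, atol=1e-5)

    def test_poisson_limit_dispersion_near_zero(self):
        rng = np.random.default_rng(0)
        design = simulate.make_design(n_reps=20)
        counts = pd.DataFrame(
            rng.poisson(200, size=(300, len(design))),
            index=[f"g{i}" for i in range(300)], columns=design.index,
        )
        sf = pd.Series(1.0, index=design.index)
        alpha = de.estimate_dispersions(counts, design, sf)
        assert np.median(alpha) < 0.02

    def test_planted_logfc_recovered(self):
        counts, design, truth = simulate.simulate_counts(
            n_genes=500, n_reps=8, fraction_de=0.2,
            dispersion_range=(0.01, 0.05), seed=21,
        )
        res = de.run_de(counts, design, apply_independent_filter=False,
                        recalibrate_contrast=None)
        de_genes = [g for g, v in truth.de_truth.items() if abs(v[1]) > 1]
        est = res.logfc.loc[de_genes, "strain_day3"].to_numpy()
        planted = np.array([truth.de_truth[g][1] for g in de_genes])
        assert np.corrcoef(est, planted)[0, 1] > 0.98
        assert np.median(np.abs(est - planted)) < 0.3

    def test_interaction_is_contrast_difference(self, counts_sim):
        counts, design, _ = counts_sim
        res = de.run_de(counts, design, recalibrate_contrast=None)
        diff = res.logfc["strain_day3"] - res.logfc["strain_day1"]
        assert np.allclose(diff.dropna(), res.logfc["interaction"].dropna(), atol=1e-8)


class TestNullCalibration:
    def test_contrast_p_uniform_under_null(self, counts_sim):
        counts, design, truth = counts_sim
        res = de.run_de(counts, design, recalibrate_contrast=None,
                        apply_independent_filter=False)
        nulls = res.p_raw.index.isin(truth.null_genes())
        for c in de.CONTRAST_NAMES:
            p = res.p_raw.loc[nulls, c].dropna()
            assert st.kstest(p, "uniform").statistic < 0.05

    def test_screening_p_approx_uniform_under_null(self, counts_sim):
        counts, design, truth = counts_sim
        sf = de.size_factors(counts)
        fit = de.fit_all(counts, design, sf)
        ps = de.screening_test(fit)
        p = ps[ps.index.isin(truth.null_genes())].dropna()
        assert st.kstest(p, "uniform").statistic < 0.05

    def test_screening_power_on_planted_effects(self, counts_sim):
        counts, design, truth = counts_sim
        sf = de.size_factors(counts)
        fit = de.fit_all(counts, design, sf)
        ps = de.screening_test(fit)
        strong = [g for g, v in truth.de_truth.items() if np.abs(v).max() > 2]
        assert np.median(ps[strong]) < 1e-3

    def test_wald_and_lr_rejections_overlap_at_large_n(self):
        """The omnibus Wald test (3 df quadratic form on the non-intercept
        coefficients) and the LR screening test reject nearly the same genes
        on large-n planted data."""
        counts, design, _ = simulate.simulate_counts(
            n_genes=400, n_reps=12, fraction_de=0.3, seed=31
        )
        sf = de.size_factors(counts)
        fit = de.fit_all(counts, design, sf, quasi=False)
        b = fit.beta[:, 1:]
        cov = fit.cov[:, 1:, 1:]
        wald = np.einsum("gi,gij,gj->g", b, np.linalg.inv(cov), b)
        p_wald = st.chi2.sf(wald, df=3)
        p_lr = de.screening_test(fit).to_numpy()
        wald_rej = p_wald < 0.01
        lr_rej = p_lr < 0.01
        both = (wald_rej & lr_rej).sum()
        either = (wald_rej | lr_rej).sum()
        assert both / either > 0.95


class TestRecalibration:
    def test_standard_normal_z_unchanged(self, rng):
        z = rng.normal(0, 1, 4000)
        p = 2 * st.norm.sf(abs(z))
        r = de.empirical_null_recalibration(p, np.sign(z))
        assert np.median(np.abs(np.log(r / p))) < 0.12

    def test_inflated_null_recalibrated_to_uniform(self, rng):
        z = rng.normal(0, 2, 4000)
        p = 2 * st.norm.sf(abs(z))
        r = de.empirical_null_recalibration(p, np.sign(z))
        assert st.kstest(p, "uniform").statistic > 0.3
        assert st.kstest(r, "uniform").statistic < 0.05

    def test_p_one_stays_one(self, rng):
        p = np.concatenate([[1.0], rng.uniform(0, 1, 400)])
        r = de.empirical_null_recalibration(p, np.ones_like(p))
        assert r[0] == pytest.approx(1.0)

    def test_degenerate_input_returned_with_warning(self):
        p = np.full(300, 0.5)
        with pytest.warns(UserWarning):
            r = de.empirical_null_recalibration(p, np.ones_like(p))
        assert np.array_equal(r, p)


class TestIndependentFilter:
    def test_uniform_base_mean_keeps_all(self, rng):
        p = pd.Series(rng.uniform(0, 1, 500))
        bm = pd.Series(np.full(500, 7.0))
        theta, keep = de.independent_filter(p, bm)
        assert theta == 0.0 and keep.all()

    def test_no_signal_threshold_zero(self, rng):
        p = pd.Series(rng.uniform(0.2, 1, 500))
        bm = pd.Series(rng.uniform(1, 100, 500))
        theta, keep = de.independent_filter(p, bm)
        assert theta == 0.0

    def test_filtering_gains_rejections(self, rng):
        """Low-expressed all null, high-expressed enriched for signal."""
        n = 1000
        bm = pd.Series(np.concatenate([rng.uniform(1, 5, n // 2),
                                       rng.uniform(50, 500, n // 2)]))
        p_low = rng.uniform(0, 1, n // 2)
        p_high = np.concatenate([rng.beta(0.08, 1, 150), rng.uniform(0, 1, n // 2 - 150)])
        p = pd.Series(np.concatenate([p_low, p_high]))
        theta, keep = de.independent_filter(p, bm)
        assert theta > 0
        rej_filtered = (de.bh_adjust(p[keep].to_numpy()) <= 0.05).sum()
        rej_plain = (de.bh_adjust(p.to_numpy()) <= 0.05).sum()
        assert rej_filtered >= rej_plain


class TestStagewise:
    def test_shaffer_worked_example(self):
        got = de.shaffer_holm(np.array([0.01, 0.02, 0.03, 0.04, 0.05]))
        assert np.allclose(got, [0.02, 0.04, 0.06, 0.08, 0.08])

    @given(
        st_h.lists(st_h.floats(0.0, 1.0), min_size=5, max_size=5)
    )
    @settings(max_examples=200, deadline=None)
    def test_shaffer_dominates_classical_holm(self, p):
        p = np.asarray(p)
        shaffer = de.shaffer_holm(p)
        order = np.argsort(p, kind="stable")
        holm_sorted = np.minimum(
            np.maximum.accumulate(p[order] * np.array([5, 4, 3, 2, 1])), 1.0
        )
        holm = np.empty(5)
        holm[order] = holm_sorted
        assert (shaffer <= holm + 1e-12).all()
        assert (shaffer >= p - 1e-12).all()  # adjusted >= raw

    def test_no_screening_pass_nothing_significant(self):
        idx = [f"g{i}" for i in range(10)]
        p_screen = pd.Series(1.0, index=idx)
        p_raw = pd.DataFrame(1e-6, index=idx, columns=list(de.CONTRAST_NAMES))
        _, flags, screened = de.stagewise_adjust(p_screen, p_raw)
        assert not flags.any().any() and not screened.any()

    def test_alpha_validated(self):
        idx = ["g"]
        ps = pd.Series([0.5], index=idx)
        pr = pd.DataFrame(0.5, index=idx, columns=list(de.CONTRAST_NAMES))
        with pytest.raises(ValueError):
            de.stagewise_adjust(ps, pr, alpha=1.5)

    def test_stage_two_level_scales_with_screening_rejections(self):
        idx = [f"g{i}" for i in range(100)]
        p_screen = pd.Series([1e-6] * 10 + [0.9] * 90, index=idx)
        p_raw = pd.DataFrame(1.0, index=idx, columns=list(de.CONTRAST_NAMES))
        p_raw.iloc[0, 0] = 0.004  # adj 0.008 > 0.05*10/100 = 0.005 -> not sig
        p_raw.iloc[1, 0] = 0.002  # adj 0.004 <= 0.005 -> significant
        _, flags, _ = de.stagewise_adjust(p_screen, p_raw, alpha=0.05)
        assert not flags.iloc[0, 0]
        assert flags.iloc[1, 0]


class TestSummaries:
    def test_max_abs_logfc_single_contrast(self):
        logfc = pd.DataFrame([[2.0, -3.0, 0.5, 0.1, 0.2]],
                             columns=list(de.CONTRAST_NAMES), index=["g"])
        flags = pd.DataFrame([[False, True, False, False, False]],
                             columns=list(de.CONTRAST_NAMES), index=["g"])
        assert de.max_abs_logfc(logfc, flags)["g"] == 3.0

    def test_max_abs_logfc_excludes_unflagged_gene(self):
        logfc = pd.DataFrame([[2.0] * 5], columns=list(de.CONTRAST_NAMES), index=["g"])
        flags = pd.DataFrame([[False] * 5], columns=list(de.CONTRAST_NAMES), index=["g"])
        assert np.isnan(de.max_abs_logfc(logfc, flags)["g"])

    def test_ks_identical_groups_zero(self, rng):
        a = rng.normal(0, 1, 300)
        stat, _ = de.compare_logfc_distributions(a, a)
        assert stat == 0.0

    def test_ks_shifted_groups_significant(self, rng):
        a = rng.exponential(1.0, 500) + 0.8
        b = rng.exponential(1.0, 500)
        stat, p = de.compare_logfc_distributions(a, b, alternative="greater")
        assert p < 0.01
        # and not significant the other way
        _, p_rev = de.compare_logfc_distributions(b, a, alternative="greater")
        assert p_rev > 0.2
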