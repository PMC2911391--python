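"""Polygenic ML, exposure LRT, tetrachoric and cotinine validation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import multivariate_normal

from pedexpress.association import (
    AssociationInputError,
    PolygenicFitter,
    build_design,
    classify_cotinine,
    fit_polygenic,
    lrt_covariate,
    tetrachoric,
    transcriptome_scan,
)
from pedexpress.normalization import NormalizedExpression
from pedexpress.pedigree import Individual, Pedigree, compute_kinship


def _trio_kin():
    ped = Pedigree([
        Individual("F", "F", None, None, "male"),
        Individual("F", "M", None, None, "female"),
        Individual("F", "C", "F", "M", "male"),
    ])
    return compute_kinship(ped)


def _singleton_kin(n):
    ped = Pedigree([Individual(f"S{k}", f"S{k}", None, None, "male")
                    for k in range(n)])
    return compute_kinship(ped)


class TestPolygenicLikelihood:
    @pytest.mark.parametrize("h2", [0.0, 0.3, 0.6, 0.95])
    def test_loglik_matches_dense_mvn_density(self, h2, rng):
        """Block log-likelihood at fixed (h2, sigma2=1, beta=0) equals a
        direct multivariate-normal density with covariance
        h2*2Phi + (1-h2)*I, evaluated independently via scipy."""
        kin = _trio_kin()
        y = rng.normal(size=3)
        X = np.ones((3, 1))
        fitter = PolygenicFitter(kin, X)
        yr = fitter.rotate(y)
        # fix beta=0, sigma2=1 by hand using the eigenvalue form
        w = h2 * fitter.lam + (1 - h2)
        ll = -0.5 * (3 * np.log(2 * np.pi) + np.sum(np.log(w)) + np.sum(yr**2 / w))
        cov = h2 * 2 * kin.phi + (1 - h2) * np.eye(3)
        ll_direct = multivariate_normal.logpdf(y, mean=np.zeros(3), cov=cov)
        assert ll == pytest.approx(ll_direct, abs=1e-8)

    def test_all_singletons_reduces_to_ols(self, rng):
        """With 2Phi = I, h2 is unidentifiable and the LRT equals the
        ordinary linear-model likelihood-ratio statistic."""
        n = 80
        kin = _singleton_kin(n)
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        X_full = np.column_stack([np.ones(n), x])
        X_null = np.ones((n, 1))
        fit = fit_polygenic(y, X_full, kin)
        assert not fit.identifiable and np.isnan(fit.h2)
        lrt, p = lrt_covariate(y, X_full, X_null, kin)
        rss_full = np.sum((y - X_full @ np.linalg.lstsq(X_full, y, rcond=None)[0]) ** 2)
        rss_null = np.sum((y - y.mean()) ** 2)
        lrt_ols = n * np.log(rss_null / rss_full)
        assert lrt == pytest.approx(lrt_ols, abs=1e-6)

    def test_h2_recovered_on_family_data(self):
        """Mean h2-hat close to truth on a quick 40-replicate version of
        the recovery design (the full-scale check lives with the
        acceptance suite)."""
        from pedexpress.validation import h2_recovery

        est = h2_recovery(n_replicates=40, seed=3)
        assert np.nanmean(est) == pytest.approx(0.5, abs=0.08)

    def test_misaligned_and_rank_deficient_designs_rejected(self, rng):
        kin = _singleton_kin(10)
        X = np.ones((10, 2))
        with pytest.raises(AssociationInputError, match="rank"):
            PolygenicFitter(kin, X)
        with pytest.raises(AssociationInputError, match="rows"):
            PolygenicFitter(kin, np.ones((5, 1)))


class TestLRT:
    def test_affine_age_invariance(self):
        """Centering/scaling age (with the interaction rebuilt) leaves
        the exposure LRT unchanged."""
        from pedexpress.simulate import SimulationConfig, simulate_study

        cfg = SimulationConfig(n_families=12, n_singletons=6, n_transcripts=5,
                               n_controls=30, seed=17)
        sim = simulate_study(cfg)
        from pedexpress.normalization import normalize_expression

        expr = normalize_expression(sim.study, n_bins=2)
        pheno = sim.phenotypes
        scan1 = transcriptome_scan(expr, pheno, sim.kinship)
        pheno2 = pheno.copy()
        pheno2["age"] = (pheno2["age"] - 40.0) / 17.0
        scan2 = transcriptome_scan(expr, pheno2, sim.kinship)
        np.testing.assert_allclose(
            scan1.table["lrt"], scan2.table["lrt"], atol=1e-5
        )

    def test_power_against_strong_effect(self):
        """beta = 0.8 at n = 600 singletons: p well below 0.001."""
        rng = np.random.default_rng(2)
        n = 600
        kin = _singleton_kin(n)
        smoker = (rng.random(n) < 0.24).astype(float)
        y = 0.8 * smoker + rng.normal(size=n)
        X_full = np.column_stack([np.ones(n), smoker])
        X_null = np.ones((n, 1))
        lrt, p = lrt_covariate(y, X_full, X_null, kin)
        assert p < 1e-3


class TestTranscriptomeScan:
    def test_fdr_zero_means_no_hits(self, small_study):
        from pedexpress.normalization import normalize_expression

        expr = normalize_expression(small_study.study)
        scan = transcriptome_scan(expr, small_study.phenotypes,
                                  small_study.kinship, fdr=0.0)
        assert scan.table["significant"].sum() == 0

    def test_constant_exposure_rejected(self, small_study):
        from pedexpress.normalization import normalize_expression

        expr = normalize_expression(small_study.study)
        pheno = small_study.phenotypes.copy()
        pheno["smoker"] = 1
        with pytest.raises(AssociationInputError, match="constant"):
            transcriptome_scan(expr, pheno, small_study.kinship)

    def test_sign_consistency_with_negative_truth(self):
        """All-negative true effects: every significant transcript
        reports a negative coefficient."""
        from pedexpress.pedigree import compute_kinship
        from pedexpress.simulate import (
            SimulationConfig,
            generate_pedigrees,
            simulate_normalized_expression,
            simulate_phenotypes,
        )

        cfg = SimulationConfig(
            n_families=60, n_singletons=20, n_transcripts=600, n_controls=100,
            prop_affected_transcripts=0.05, prob_effect_negative=1.0,
            effect_size_range=(0.6, 0.9), seed=23,
        )
        ped = generate_pedigrees(cfg)
        kin = compute_kinship(ped)
        pheno = simulate_phenotypes(ped, cfg, kin=kin)
        Y, transcripts, truth = simulate_normalized_expression(ped, pheno, cfg, kin=kin)
        expr = NormalizedExpression(sample_ids=kin.ids, transcript_ids=transcripts,
                                    values=Y, provenance={})
        scan = transcriptome_scan(expr, pheno, kin)
        sig = scan.table[scan.table["significant"]]
        assert len(sig) > 10
        # every truly affected discovery carries the (negative) truth sign;
        # the few false discoveries FDR admits may go either way, so the
        # overall direction split is merely dominated by negatives
        true_hits = sig[sig["transcript"].isin(truth.affected)]
        assert (true_hits["beta"] < 0).all()
        assert (sig["beta"] < 0).mean() > 0.85
        s = scan.summary()
        assert s["implied_p_threshold"] == pytest.approx(sig["p"].max())
        assert s["n_negative"] + s["n_positive"] == len(sig)

    def test_quantitative_exposure_supported(self, small_study):
        from pedexpress.normalization import normalize_expression

        expr = normalize_expression(small_study.study)
        scan = transcriptome_scan(expr, small_study.phenotypes,
                                  small_study.kinship, exposure="cigs_per_day")
        assert len(scan.table) == len(expr.transcript_ids)


class TestBuildDesign:
    def test_unknown_covariate_rejected(self, small_study):
        with pytest.raises(AssociationInputError, match="unknown covariate"):
            build_design(small_study.phenotypes, covariates=("sex", "bmi"))

    def test_interaction_column_is_product(self, small_study):
        X = build_design(small_study.phenotypes)
        np.testing.assert_allclose(X[:, 3], X[:, 1] * X[:, 2])


class TestTetrachoric:
    def test_independence_table(self):
        rho, se = tetrachoric(np.array([[25, 25], [25, 25]]))
        assert rho == pytest.approx(0.0, abs=1e-6)
        assert 0.0 < se < 1.0

    def test_recovers_latent_correlation(self):
        """rho = 0.5 bivariate normal thresholded at the medians,
        n = 1e5: the MLE lands within Monte-Carlo error."""
        rng = np.random.default_rng(11)
        n = 100_000
        z1 = rng.normal(size=n)
        z2 = 0.5 * z1 + np.sqrt(1 - 0.25) * rng.normal(size=n)
        a, b = z1 > 0, z2 > 0
        table = np.array([
            [np.sum(~a & ~b), np.sum(~a & b)],
            [np.sum(a & ~b), np.sum(a & b)],
        ])
        rho, se = tetrachoric(table)
        assert rho == pytest.approx(0.5, abs=4 * se)
        assert se < 0.01

    def test_perfect_concordance_hits_boundary(self):
        with pytest.warns(UserWarning, match="boundary"):
            rho, _ = tetrachoric(np.array([[50, 0], [0, 50]]))
        assert rho >= 0.99

    def test_zero_margin_rejected(self):
        with pytest.raises(AssociationInputError, match="margin"):
            tetrachoric(np.array([[10, 10], [0, 0]]))


class TestClassifyCotinine:
    def test_cut_points_are_inclusive(self):
        classes, _ = classify_cotinine(np.array([19.9, 20.0, 299.9, 300.0, 0.0]))
        assert classes.tolist() == [
            "non-smoker", "smoker", "smoker", "heavy", "non-smoker"
        ]

    def test_missing_stays_missing(self):
        classes, conflicts = classify_cotinine(
            np.array([np.nan, 25.0]), reported_smoker=np.array([1, 1])
        )
        assert classes[0] is None
        assert conflicts == 0

    def test_conflict_count(self):
        cot = np.array([5.0, 250.0, 500.0, 10.0])
        rep = np.array([1, 0, 1, 0])
        _, conflicts = classify_cotinine(cot, reported_smoker=rep)
        assert conflicts == 2  # reported smoker at 5; reported non-smoker at 250

    def test_negative_rejected(self):
        with pytest.raises(AssociationInputError, match="nonnegative"):
            classify_cotinine(np.array([-1.0]))
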