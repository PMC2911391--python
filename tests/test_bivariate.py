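"""Discrete-continuous bivariate model: likelihood identities, orthant
integration accuracy, and identifiability behavior."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import multivariate_normal

from pedexpress._stats import bvn_cdf, mvn_rect_prob, sobol_points
from pedexpress.bivariate import (
    BivariateFitter,
    BivariateInputError,
    BivariateModel,
    bivariate_loglik,
    threshold_from_prevalence,
)
from pedexpress.pedigree import Individual, Pedigree, compute_kinship


def _trio():
    ped = Pedigree([
        Individual("F", "F", None, None, "male"),
        Individual("F", "M", None, None, "female"),
        Individual("F", "C", "F", "M", "male"),
    ])
    return ped, compute_kinship(ped)


def _pheno(kin, smoker, rng):
    n = len(kin.ids)
    return pd.DataFrame({
        "id": kin.ids,
        "smoker": smoker,
        "cigs_per_day": np.zeros(n, dtype=int),
        "cotinine": np.full(n, 5.0),
        "age": rng.uniform(20, 70, size=n),
        "sex": rng.choice(["male", "female"], size=n),
    })


class TestOrthantIntegration:
    def test_reproduces_closed_form_bivariate_rectangles(self):
        """Genz QMC on 2-member blocks matches the closed-form bivariate
        normal CDF to 1e-5."""
        pts = sobol_points(1, 2**13, seed=3)
        for rho in (-0.8, -0.3, 0.0, 0.4, 0.9):
            cov = np.array([[1.0, rho], [rho, 1.0]])
            L = np.linalg.cholesky(cov)
            cases = [
                ((-np.inf, -np.inf), (0.3, 1.1)),
                ((0.0, -np.inf), (np.inf, 0.0)),
                ((-1.0, -0.5), (0.5, 2.0)),
            ]
            for lo, hi in cases:
                est = mvn_rect_prob(np.array([lo]), np.array([hi]), L, pts)[0]
                a1, a2 = lo
                b1, b2 = hi
                exact = (
                    bvn_cdf(b1, b2, rho) - bvn_cdf(a1, b2, rho)
                    - bvn_cdf(b1, a2, rho) + bvn_cdf(a1, a2, rho)
                )
                assert est == pytest.approx(exact, abs=1e-5)

    def test_bvn_cdf_against_scipy(self):
        """Independent cross-check of the closed-form bivariate CDF."""
        for rho in (-0.6, 0.0, 0.5, 0.95):
            cov = [[1.0, rho], [rho, 1.0]]
            for h, k in ((0.0, 0.0), (-1.2, 0.7), (2.0, 1.5)):
                ref = multivariate_normal(mean=[0, 0], cov=cov).cdf([h, k])
                assert bvn_cdf(h, k, rho) == pytest.approx(float(ref), abs=1e-6)


class TestThreshold:
    def test_values(self):
        assert threshold_from_prevalence(0.5) == 0.0
        assert threshold_from_prevalence(0.24) == pytest.approx(0.7063, abs=1e-4)

    def test_domain(self):
        with pytest.raises(BivariateInputError):
            threshold_from_prevalence(1.2)


class TestLoglikIdentities:
    def test_factorizes_when_correlations_vanish(self, rng):
        """rho_g = rho_e = 0: the joint log-likelihood is the univariate
        expression log-likelihood plus the liability-only orthant
        log-probability, each computed independently."""
        ped, kin = _trio()
        smoker = np.array([1, 0, 0])
        pheno = _pheno(kin, smoker, rng)
        y = rng.normal(size=3)
        fitter = BivariateFitter(pheno, kin, covariates=(), n_qmc=512)
        model = BivariateModel(
            h2_expr=0.5, h2_liab=0.4, rho_g=0.0, rho_e=0.0,
            threshold=0.7, beta=np.zeros(fitter.p), sigma2=1.2,
        )
        ll = fitter.loglik(model, y)
        cov_y = 1.2 * (0.5 * 2 * kin.phi + 0.5 * np.eye(3))
        ll_expr = multivariate_normal.logpdf(y, mean=np.zeros(3), cov=cov_y)
        cov_l = 0.4 * 2 * kin.phi + 0.6 * np.eye(3)
        lower = np.where(smoker == 1, 0.7, -np.inf)
        upper = np.where(smoker == 1, np.inf, 0.7)
        p_orthant = mvn_rect_prob(
            lower[None, :], upper[None, :], np.linalg.cholesky(cov_l),
            fitter._points[3],
        )[0]
        assert ll == pytest.approx(ll_expr + np.log(p_orthant), abs=1e-9)

    def test_single_smoker_liability_term_is_tail_probability(self, rng):
        """One singleton smoker: the liability part is log(1 - Phi(t))."""
        ped = Pedigree([Individual("S", "S", None, None, "male")])
        kin = compute_kinship(ped)
        pheno = _pheno(kin, np.array([1]), rng)
        y = np.array([0.4])
        fitter = BivariateFitter(pheno, kin, covariates=())
        t = 0.9
        model = BivariateModel(h2_expr=0.3, h2_liab=0.5, rho_g=0.0, rho_e=0.0,
                               threshold=t, beta=np.zeros(fitter.p), sigma2=1.0)
        ll = fitter.loglik(model, y)
        ll_expr = stats.norm.logpdf(y[0])
        assert ll == pytest.approx(ll_expr + np.log(stats.norm.sf(t)), abs=1e-10)

    def test_matches_brute_force_monte_carlo_integration(self, rng):
        """3-member pedigree, nonzero rho_g/rho_e: the conditional
        decomposition matches a 10^7-draw Monte-Carlo estimate of the
        same integral, conditioning the opposite way (y | liability),
        within 3 MC standard errors."""
        ped, kin = _trio()
        smoker = np.array([1, 0, 1])
        pheno = _pheno(kin, smoker, rng)
        y = np.array([0.8, -0.2, 0.5])
        fitter = BivariateFitter(pheno, kin, covariates=(), n_qmc=4096)
        model = BivariateModel(
            h2_expr=0.5, h2_liab=0.4, rho_g=0.3, rho_e=0.4,
            threshold=0.7, beta=np.zeros(fitter.p), sigma2=1.0,
        )
        ll = fitter.loglik(model, y)

        P2 = 2 * kin.phi
        eye = np.eye(3)
        Vy = model.sigma2 * (model.h2_expr * P2 + (1 - model.h2_expr) * eye)
        Vl = model.h2_liab * P2 + (1 - model.h2_liab) * eye
        C = np.sqrt(model.sigma2) * (
            model.rho_g * np.sqrt(model.h2_expr * model.h2_liab) * P2
            + model.rho_e * np.sqrt((1 - model.h2_expr) * (1 - model.h2_liab)) * eye
        )
        # E_l[f(y | l) 1{l in orthant}] = f(y) P(orthant | y)
        A = C @ np.linalg.inv(Vl)          # regression of y on l
        cov_cond = Vy - C @ np.linalg.inv(Vl) @ C.T
        n_draws, chunk = 10_000_000, 1_000_000
        mc_rng = np.random.default_rng(99)
        Ll = np.linalg.cholesky(Vl)
        total, total_sq = 0.0, 0.0
        for _ in range(n_draws // chunk):
            lam = (Ll @ mc_rng.standard_normal((3, chunk))).T
            inside = ((lam > model.threshold) == (smoker == 1)).all(axis=1)
            mean_y = lam @ A.T
            w = np.zeros(chunk)
            dev = y[None, :] - mean_y[inside]
            w[inside] = multivariate_normal(mean=np.zeros(3), cov=cov_cond).pdf(dev)
            total += w.sum()
            total_sq += (w**2).sum()
        est = total / n_draws
        var = total_sq / n_draws - est**2
        se_log = np.sqrt(var / n_draws) / est
        assert ll == pytest.approx(np.log(est), abs=max(3 * se_log, 1e-3))

    def test_exchangeable_under_within_block_relabeling(self, rng):
        ped, kin = _trio()
        smoker = np.array([1, 0, 0])
        pheno = _pheno(kin, smoker, rng)
        y = rng.normal(size=3)
        model_kw = dict(h2_expr=0.4, h2_liab=0.5, rho_g=0.2, rho_e=0.3,
                        threshold=0.7, sigma2=1.0)
        f1 = BivariateFitter(pheno, kin, covariates=(), n_qmc=2048)
        ll1 = f1.loglik(BivariateModel(beta=np.zeros(f1.p), **model_kw), y)
        perm = [2, 0, 1]
        pheno2 = pheno.iloc[perm].reset_index(drop=True)
        f2 = BivariateFitter(pheno2, kin.subset([kin.ids[i] for i in perm]),
                             covariates=(), n_qmc=2048)
        ll2 = f2.loglik(BivariateModel(beta=np.zeros(f2.p), **model_kw), y[perm])
        assert ll1 == pytest.approx(ll2, abs=2e-3)

    def test_module_level_wrapper(self, rng):
        ped, kin = _trio()
        pheno = _pheno(kin, np.array([0, 0, 1]), rng)
        y = rng.normal(size=3)
        model = BivariateModel(h2_expr=0.2, h2_liab=0.2, rho_g=0.0, rho_e=0.1,
                               threshold=0.5, beta=np.zeros(1), sigma2=1.0)
        ll = bivariate_loglik(model, y, pheno, kin, covariates=())
        assert np.isfinite(ll) and ll < 0


class TestFitting:
    def test_rho_g_unidentifiable_without_liability_heritability(self, rng):
        """h2_liab pinned at 0 makes rho_g meaningless; the fit must
        flag it rather than return a number."""
        from pedexpress.validation import _recovery_pedigree
        from pedexpress.simulate import (
            simulate_normalized_expression,
            simulate_phenotypes,
        )

        cfg, ped = _recovery_pedigree(12, 5, seed=3)
        cfg = dataclasses.replace(cfg, n_transcripts=1, h2_range=(0.4, 0.4),
                                  prop_affected_transcripts=0.0)
        kin = compute_kinship(ped)
        pheno = simulate_phenotypes(ped, cfg, kin=kin)
        Y, tr, _ = simulate_normalized_expression(ped, pheno, cfg, kin=kin)
        fitter = BivariateFitter(pheno, kin, n_qmc=32)
        with pytest.warns(UserWarning, match="unidentifiable"):
            row = fitter.fit_transcript(tr[0], Y[:, 0], compute_se=False,
                                        fix={"h2_liab": 0.0})
        assert np.isnan(row.rho_g) and np.isnan(row.p_rho_g)
        assert not row.rho_g_identifiable
        assert np.isfinite(row.rho_e)

    def test_block_size_cap_enforced(self, rng):
        rows = [Individual("F", "P1", None, None, "male"),
                Individual("F", "P2", None, None, "female")]
        rows += [Individual("F", f"C{k}", "P1", "P2", "male") for k in range(24)]
        ped = Pedigree(rows)
        kin = compute_kinship(ped)
        pheno = _pheno(kin, np.zeros(len(kin.ids), dtype=int), rng)
        with pytest.raises(BivariateInputError, match="cap"):
            BivariateFitter(pheno, kin)

    def test_invalid_parameters_rejected(self):
        m = BivariateModel(h2_expr=1.4, h2_liab=0.2, rho_g=0.0, rho_e=0.0,
                           threshold=0.0, beta=np.zeros(1))
        with pytest.raises(BivariateInputError, match="h2_expr"):
            m.validate()
        m2 = BivariateModel(h2_expr=0.4, h2_liab=0.2, rho_g=1.5, rho_e=0.0,
                            threshold=0.0, beta=np.zeros(1))
        with pytest.raises(BivariateInputError, match="rho_g"):
            m2.validate()
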