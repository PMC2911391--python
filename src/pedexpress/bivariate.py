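"""Combined discrete-continuous bivariate variance-components model.

A phenotypic correlation between a binary exposure (smoking) and a
quantitative trait (a transcript's normalized expression) can arise
from shared genes, shared environment, or both.  This module decomposes
it by modeling, jointly over each pedigree block:

* expression  y = X beta + g_y + e_y, with Var(g_y) = sigma^2 h2_expr 2Phi
  and Var(e_y) = sigma^2 (1 - h2_expr) I;
* a latent standard-normal smoking liability l = g_l + e_l with
  Var(g_l) = h2_liab 2Phi, Var(e_l) = (1 - h2_liab) I, observed only
  through the indicator smoker = 1{l > t};
* Corr(g_y, g_l) = rho_g * 2Phi-structure, Corr(e_y, e_l) = rho_e * I.

The implied phenotypic correlation is
rho_p = rho_g sqrt(h2_expr h2_liab) + rho_e sqrt((1-h2_expr)(1-h2_liab)).

The block likelihood is evaluated by conditional decomposition: the
exact multivariate-normal density of the expression sub-vector times
the probability that the conditional liability (still multivariate
normal) falls in the orthant dictated by the observed smoker pattern
and threshold t.  Orthant probabilities use Genz's quasi-Monte-Carlo
construction with a fixed scrambled-Sobol point set, so the likelihood
is deterministic and smooth in the parameters and can be optimized
directly.  Tests of rho_g = 0 and rho_e = 0 are likelihood-ratio tests
against the constrained fits (chi-square, 1 df).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_solve, solve_triangular
from scipy.special import ndtri

from ._stats import mvn_rect_prob, sobol_points
from .association import DEFAULT_COVARIATES, PolygenicFitter, build_design
from .normalization import NormalizedExpression
from .pedigree import KinshipMatrix


class BivariateInputError(ValueError):
    pass


def threshold_from_prevalence(prev: float) -> float:
    """Liability threshold t = Phi^{-1}(1 - prevalence)."""
    if not 0.0 < prev < 1.0:
        raise BivariateInputError(f"prevalence must be in (0, 1), got {prev}")
    return float(ndtri(1.0 - prev))


@dataclass
class BivariateModel:
    """Parameters of the joint expression-liability model."""

    h2_expr: float
    h2_liab: float
    rho_g: float
    rho_e: float
    threshold: float
    beta: np.ndarray
    sigma2: float = 1.0
    loglik: float = np.nan
    # optional covariate effects shifting the liability mean
    liability_beta: np.ndarray | None = None

    @property
    def rho_p(self) -> float:
        return self.rho_g * np.sqrt(self.h2_expr * self.h2_liab) + self.rho_e * np.sqrt(
            (1.0 - self.h2_expr) * (1.0 - self.h2_liab)
        )

    def validate(self) -> None:
        for name in ("h2_expr", "h2_liab"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise BivariateInputError(f"{name} must be in [0, 1], got {v}")
        for name in ("rho_g", "rho_e"):
            if abs(getattr(self, name)) > 1.0:
                raise BivariateInputError(f"|{name}| must not exceed 1")
        if abs(self.rho_p) > 1.0 + 1e-12:
            raise BivariateInputError(f"implied rho_p {self.rho_p:.3f} exceeds 1")


@dataclass
class BivariateRow:
    """One transcript's bivariate decomposition."""

    transcript: str
    rho_g: float
    rho_g_se: float
    p_rho_g: float
    rho_e: float
    rho_e_se: float
    p_rho_e: float
    h2_expr: float
    h2_liab: float
    threshold: float
    loglik: float
    converged: bool
    rho_g_identifiable: bool = True


_FREE_PARAMS = ("h2_expr", "h2_liab", "rho_g", "rho_e", "threshold", "log_sigma")
_BOUNDS = {
    "h2_expr": (0.0, 0.995),
    "h2_liab": (0.0, 0.995),
    "rho_g": (-0.995, 0.995),
    "rho_e": (-0.995, 0.995),
    "threshold": (-3.5, 3.5),
    "log_sigma": (np.log(0.2), np.log(5.0)),
}


class BivariateFitter:
    """Shared machinery for bivariate fits on one cohort.

    Blocks with identical 2*Phi share all matrix factorizations at each
    likelihood evaluation, and one fixed Sobol point set per block size
    is reused for every orthant integral.
    """

    def __init__(
        self,
        pheno: pd.DataFrame,
        kin: KinshipMatrix,
        covariates: tuple[str, ...] = DEFAULT_COVARIATES,
        liability_covariates: tuple[str, ...] | None = None,
        n_qmc: int = 256,
        qmc_seed: int = 20_407,
        max_block: int = 20,
    ):
        ids = list(pheno["id"])
        if ids != kin.ids:
            kin = kin.subset(ids)
        self.kin = kin
        self.smoker = pheno["smoker"].to_numpy(dtype=float)
        self.X = build_design(pheno, covariates)
        self.p = self.X.shape[1]
        # liability covariates (no intercept: the threshold plays that role);
        # default none — the threshold alone locates the liability scale
        self.Xl = (
            build_design(pheno, liability_covariates)[:, 1:]
            if liability_covariates else None
        )
        self.nl = 0 if self.Xl is None else self.Xl.shape[1]
        self.n = len(ids)
        self.n_qmc = n_qmc
        # group blocks by identical relationship structure
        groups: dict[bytes, list[np.ndarray]] = {}
        for block in kin.blocks:
            if len(block) > max_block:
                raise BivariateInputError(
                    f"pedigree block of size {len(block)} exceeds the cap of "
                    f"{max_block}; orthant integration tolerance is not "
                    "guaranteed — raise max_block knowingly or split the block"
                )
            key = np.round(2.0 * kin.phi[np.ix_(block, block)], 12).tobytes()
            groups.setdefault(key, []).append(block)
        self.groups = []
        self._points: dict[int, np.ndarray] = {}
        for key, blocks in groups.items():
            d = len(blocks[0])
            two_phi = np.frombuffer(key).reshape(d, d)
            idx = np.stack(blocks)                      # (B, d)
            self.groups.append(
                {
                    "two_phi": two_phi,
                    "idx": idx,
                    "X": self.X[idx],                   # (B, d, p)
                    "Xl": None if self.Xl is None else self.Xl[idx],
                    "smoker": self.smoker[idx],         # (B, d)
                }
            )
            if d > 1 and d not in self._points:
                self._points[d] = sobol_points(d - 1, n_qmc, seed=qmc_seed + d)
        self._poly = PolygenicFitter(kin, self.X)

    # -- likelihood ---------------------------------------------------

    def loglik(self, model: BivariateModel, y: np.ndarray) -> float:
        """Joint log-likelihood of expression values and smoker pattern."""
        model.validate()
        h2e, h2l = model.h2_expr, model.h2_liab
        rg, re = model.rho_g, model.rho_e
        sig = np.sqrt(model.sigma2)
        t = model.threshold
        total = 0.0
        for grp in self.groups:
            P2 = grp["two_phi"]
            d = P2.shape[0]
            eye = np.eye(d)
            Vy = model.sigma2 * (h2e * P2 + (1.0 - h2e) * eye)
            Vl = h2l * P2 + (1.0 - h2l) * eye
            C = sig * (
                rg * np.sqrt(h2e * h2l) * P2
                + re * np.sqrt((1.0 - h2e) * (1.0 - h2l)) * eye
            )
            try:
                Ly = np.linalg.cholesky(Vy)
            except np.linalg.LinAlgError:
                Ly = np.linalg.cholesky(Vy + 1e-10 * eye)
            M = cho_solve((Ly, True), C)                      # Vy^{-1} C
            Sc = Vl - C.T @ M
            try:
                Lc = np.linalg.cholesky(Sc)
            except np.linalg.LinAlgError:
                Lc = np.linalg.cholesky(Sc + 1e-10 * eye)
            resid = y[grp["idx"]] - grp["X"] @ model.beta     # (B, d)
            z = solve_triangular(Ly, resid.T, lower=True)
            logdet = 2.0 * np.sum(np.log(np.diag(Ly)))
            total += float(
                -0.5 * (resid.size * np.log(2.0 * np.pi)
                        + resid.shape[0] * logdet + np.sum(z * z))
            )
            mu = resid @ M                                     # conditional mean
            if grp["Xl"] is not None and model.liability_beta is not None:
                mu = mu + grp["Xl"] @ model.liability_beta
            smk = grp["smoker"]
            lower = np.where(smk == 1.0, t - mu, -np.inf)
            upper = np.where(smk == 1.0, np.inf, t - mu)
            probs = mvn_rect_prob(lower, upper, Lc, self._points.get(d))
            total += float(np.sum(np.log(probs)))
        return total

    # -- fitting ------------------------------------------------------

    def _pack(self, model: BivariateModel, free: list[str]) -> np.ndarray:
        vals = {
            "h2_expr": model.h2_expr,
            "h2_liab": model.h2_liab,
            "rho_g": model.rho_g,
            "rho_e": model.rho_e,
            "threshold": model.threshold,
            "log_sigma": 0.5 * np.log(model.sigma2),
        }
        gamma = [] if self.nl == 0 else list(
            model.liability_beta if model.liability_beta is not None
            else np.zeros(self.nl)
        )
        return np.array([vals[k] for k in free] + list(model.beta) + gamma)

    def _unpack(self, theta: np.ndarray, free: list[str], fixed: dict) -> BivariateModel:
        vals = dict(fixed)
        for k, v in zip(free, theta[: len(free)]):
            vals[k] = float(v)
        k = len(free)
        beta = np.asarray(theta[k : k + self.p], dtype=float)
        gamma = (
            np.asarray(theta[k + self.p :], dtype=float) if self.nl else None
        )
        return BivariateModel(
            h2_expr=vals["h2_expr"],
            h2_liab=vals["h2_liab"],
            rho_g=vals["rho_g"],
            rho_e=vals["rho_e"],
            threshold=vals["threshold"],
            beta=beta,
            sigma2=float(np.exp(2.0 * vals["log_sigma"])),
            liability_beta=gamma,
        )

    def _start(self, y: np.ndarray) -> BivariateModel:
        uni = self._poly.fit(y)
        h2e = 0.3 if not np.isfinite(uni.h2) else float(np.clip(uni.h2, 0.02, 0.95))
        prev = float(np.clip(self.smoker.mean(), 1e-3, 1 - 1e-3))
        resid = y - self.X @ uni.beta
        r_pb = float(np.corrcoef(resid, self.smoker)[0, 1])
        return BivariateModel(
            h2_expr=h2e,
            h2_liab=0.3,
            rho_g=0.0,
            rho_e=float(np.clip(1.4 * r_pb, -0.9, 0.9)),
            threshold=threshold_from_prevalence(prev),
            beta=uni.beta.copy(),
            sigma2=max(uni.sigma2, 0.05),
        )

    def _maximize(
        self, y: np.ndarray, start: BivariateModel, fix: dict | None = None
    ) -> tuple[BivariateModel, bool]:
        fix = dict(fix or {})
        if "sigma2" in fix:
            fix["log_sigma"] = 0.5 * np.log(fix.pop("sigma2"))
        free = [k for k in _FREE_PARAMS if k not in fix]
        fixed_vals = {
            "h2_expr": start.h2_expr, "h2_liab": start.h2_liab,
            "rho_g": start.rho_g, "rho_e": start.rho_e,
            "threshold": start.threshold, "log_sigma": 0.5 * np.log(start.sigma2),
        }
        fixed_vals.update(fix)

        def respect_rho_p(m: BivariateModel) -> bool:
            return abs(m.rho_p) <= 1.0

        def nll(theta: np.ndarray) -> float:
            m = self._unpack(theta, free, fixed_vals)
            if not respect_rho_p(m):
                return 1e10
            try:
                return -self.loglik(m, y)
            except (np.linalg.LinAlgError, BivariateInputError):
                return 1e10

        theta0 = self._pack(start, free)
        bounds = [_BOUNDS[k] for k in free] + [(None, None)] * (self.p + self.nl)
        res = optimize.minimize(
            nll, theta0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 200, "ftol": 1e-9, "gtol": 1e-5, "eps": 1e-5},
        )
        model = self._unpack(res.x, free, fixed_vals)
        model.loglik = -float(res.fun)
        return model, bool(res.success)

    def fit(
        self,
        y: np.ndarray,
        fix: dict | None = None,
        start: BivariateModel | None = None,
    ) -> tuple[BivariateModel, bool]:
        """Maximize the joint likelihood, optionally with fixed parameters."""
        start = start if start is not None else self._start(y)
        return self._maximize(y, start, fix=fix)

    def _hessian_se(self, model: BivariateModel, y: np.ndarray) -> dict[str, float]:
        """SEs for rho_g/rho_e from the numerical observed information."""
        free = list(_FREE_PARAMS)
        fixed_vals: dict = {}
        theta = self._pack(model, free)
        k = len(theta)

        def f(th):
            m = self._unpack(th, free, fixed_vals)
            if abs(m.rho_p) > 1.0:
                return np.nan
            try:
                return -self.loglik(m, y)
            except np.linalg.LinAlgError:
                return np.nan

        eps = 1e-4
        # clip interior so the stencil stays inside the bounds
        for i, name in enumerate(free):
            lo, hi = _BOUNDS[name]
            theta[i] = np.clip(theta[i], lo + 2 * eps, hi - 2 * eps)
        H = np.empty((k, k))
        f0 = f(theta)
        fp = np.empty(k)
        fm = np.empty(k)
        for i in range(k):
            e_i = np.zeros(k); e_i[i] = eps
            fp[i] = f(theta + e_i)
            fm[i] = f(theta - e_i)
            H[i, i] = (fp[i] - 2 * f0 + fm[i]) / eps**2
        for i in range(k):
            for j in range(i + 1, k):
                e_i = np.zeros(k); e_i[i] = eps
                e_j = np.zeros(k); e_j[j] = eps
                fpp = f(theta + e_i + e_j)
                H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + f0) / eps**2
        try:
            cov = np.linalg.inv(H)
            diag = np.diag(cov)
            ses = np.sqrt(np.where(diag > 0, diag, np.nan))
        except np.linalg.LinAlgError:
            ses = np.full(k, np.nan)
        return {name: float(ses[i]) for i, name in enumerate(free)}

    def fit_transcript(
        self,
        transcript: str,
        y: np.ndarray,
        compute_se: bool = True,
        fix: dict | None = None,
    ) -> BivariateRow:
        """Full fit plus LRTs of rho_g = 0 and rho_e = 0 for one transcript.

        ``fix`` pins parameters (e.g. the threshold, or h2_liab) in the
        full and constrained fits alike.
        """
        fix = dict(fix or {})
        full, ok_full = self.fit(y, fix=fix)
        null_g, _ = self.fit(y, fix={**fix, "rho_g": 0.0},
                             start=_copy_with(full, rho_g=0.0))
        null_e, _ = self.fit(y, fix={**fix, "rho_e": 0.0},
                             start=_copy_with(full, rho_e=0.0))
        # a constrained fit occasionally beats a stuck full fit: recover
        best_null = max(null_g.loglik, null_e.loglik)
        if full.loglik < best_null - 1e-6:
            restart = null_g if null_g.loglik >= null_e.loglik else null_e
            full2, ok2 = self.fit(y, fix=fix, start=restart)
            if full2.loglik > full.loglik:
                full, ok_full = full2, ok2
        lrt_g = max(0.0, 2.0 * (full.loglik - null_g.loglik))
        lrt_e = max(0.0, 2.0 * (full.loglik - null_e.loglik))
        identifiable = full.h2_liab > 0.01
        if not identifiable:
            warnings.warn(
                f"{transcript}: h2_liab estimated at ~0; rho_g is unidentifiable",
                stacklevel=2,
            )
        ses = {"rho_g": np.nan, "rho_e": np.nan}
        if compute_se and ok_full:
            ses = self._hessian_se(full, y)
        return BivariateRow(
            transcript=transcript,
            rho_g=full.rho_g if identifiable else np.nan,
            rho_g_se=ses["rho_g"] if identifiable else np.nan,
            p_rho_g=float(stats.chi2.sf(lrt_g, 1)) if identifiable else np.nan,
            rho_e=full.rho_e,
            rho_e_se=ses["rho_e"],
            p_rho_e=float(stats.chi2.sf(lrt_e, 1)),
            h2_expr=full.h2_expr,
            h2_liab=full.h2_liab,
            threshold=full.threshold,
            loglik=full.loglik,
            converged=ok_full,
            rho_g_identifiable=identifiable,
        )


def _copy_with(model: BivariateModel, **kw) -> BivariateModel:
    out = BivariateModel(
        h2_expr=model.h2_expr, h2_liab=model.h2_liab, rho_g=model.rho_g,
        rho_e=model.rho_e, threshold=model.threshold, beta=model.beta.copy(),
        sigma2=model.sigma2,
    )
    for k, v in kw.items():
        setattr(out, k, v)
    return out


def bivariate_loglik(
    model: BivariateModel,
    y: np.ndarray,
    pheno: pd.DataFrame,
    kin: KinshipMatrix,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    n_qmc: int = 256,
) -> float:
    """Evaluate the joint log-likelihood at fixed parameters."""
    fitter = BivariateFitter(pheno, kin, covariates=covariates, n_qmc=n_qmc)
    return fitter.loglik(model, np.asarray(y, dtype=float))


def fit_bivariate(
    transcript: str,
    y: np.ndarray,
    pheno: pd.DataFrame,
    kin: KinshipMatrix,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    liability_covariates: tuple[str, ...] | None = None,
    compute_se: bool = True,
) -> BivariateRow:
    """Fit the bivariate model for a single transcript."""
    fitter = BivariateFitter(pheno, kin, covariates=covariates,
                             liability_covariates=liability_covariates)
    return fitter.fit_transcript(transcript, np.asarray(y, dtype=float), compute_se=compute_se)


def bivariate_scan(
    expr: NormalizedExpression,
    transcripts: list[str],
    pheno: pd.DataFrame,
    kin: KinshipMatrix,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    top: int | None = 50,
    compute_se: bool = True,
) -> pd.DataFrame:
    """Bivariate decomposition for a ranked list of transcripts.

    By default restricted to the first ``top`` entries (the scan's most
    significant hits); pass ``top=None`` for all, which is warned as
    expensive.
    """
    if top is not None:
        transcripts = transcripts[:top]
    else:
        warnings.warn("full-transcriptome bivariate run requested; this is expensive",
                      stacklevel=2)
    pheno = pheno.set_index("id").loc[expr.sample_ids].reset_index()
    fitter = BivariateFitter(pheno, kin.subset(expr.sample_ids), covariates=covariates)
    rows = []
    for t in transcripts:
        row = fitter.fit_transcript(t, expr.column(t), compute_se=compute_se)
        rows.append(row.__dict__)
    return pd.DataFrame(rows)
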