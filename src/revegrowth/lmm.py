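"""Linear mixed models with crossed and nested random intercepts.

The growth models carry four random-intercept factors — biogeographic
subregion, planting, plot (spatially nested) and focal species (crossed
with the spatial factors) — over designs with thousands of levels.  The
fitter profiles both the fixed effects and the residual variance out of the
(restricted) likelihood and optimizes over the log relative standard
deviations ``s_f = log(sigma_f / sigma_e)`` only, so each objective
evaluation is a dense Cholesky factorization of a (q + p) system built from
precomputed cross-products (q = total random levels, p = fixed effects) and
is independent of the number of observations.

With ``Z`` the sparse incidence of all factor levels and ``D`` the diagonal
of relative SDs, one evaluation solves the penalized least squares system

    [ D Z'Z D + I   D Z'X ] [u]   [D Z'y]
    [ X'Z D         X'X   ] [b] = [X'y  ]

and the profiled deviances are

    ML:    log|A| + n (1 + log(2 pi r2 / n))
    REML:  log|A| + log|X' V^-1 X * s2| + (n-p)(1 + log(2 pi r2 / (n-p)))

with ``A = D Z'Z D + I`` and ``r2`` the penalized residual sum of squares.
REML is used for all reported estimates; ML refits feed AIC and
likelihood-ratio comparisons.  Variance estimates on the boundary
(sigma_f -> 0) are reported as exact zeros with a flag and p-values of
boundary likelihood-ratio tests are left uncorrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy import optimize, stats
from scipy.linalg import lapack

from .design import ModelSpec, build_design

__all__ = [
    "FitResult",
    "ComparisonResult",
    "MixedModelMatrices",
    "fit_lmm",
    "aic",
    "lrt",
    "pseudo_r2",
]

_BOUNDARY_LAMBDA = 1e-4  # relative SD below which a component is reported as 0
_LOG_LAMBDA_BOUNDS = (-12.0, 6.0)


@dataclass
class FitResult:
    """Estimates from one (restricted) maximum-likelihood fit."""

    spec: ModelSpec
    method: str
    beta: pd.Series
    beta_cov: pd.DataFrame
    varcomps: pd.Series  # per-factor variances plus 'resid'
    loglik: float
    n_obs: int
    n_params: int  # fixed effects + variance components (incl. residual)
    converged: bool
    boundary: dict = field(default_factory=dict)  # factor -> True when at 0
    var_fixed: float = float("nan")  # population variance of X @ beta
    theta: np.ndarray | None = None  # log relative SDs at the optimum
    blups: dict = field(default_factory=dict)  # factor -> pd.Series of intercepts

    @property
    def beta_se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.beta_cov)), index=self.beta.index)


@dataclass
class ComparisonResult:
    """A likelihood-ratio comparison of two nested model fits."""

    chi2: float
    df: int
    p_value: float
    delta_aic: float


class MixedModelMatrices:
    """Precomputed cross-products for one fixed/random design.

    Construction is the only part whose cost scales with n; subsequent fits
    (e.g. on permuted responses) reuse the cached ``Z'Z``, ``Z'X`` and
    ``X'X`` blocks.
    """

    def __init__(self, x: pd.DataFrame, factors: dict[str, np.ndarray]):
        self.term_names = list(x.columns)
        self.x = np.ascontiguousarray(x.to_numpy(dtype=float))
        self.n, self.p = self.x.shape
        if np.linalg.matrix_rank(self.x) < self.p:
            raise np.linalg.LinAlgError("fixed-effect design is rank deficient")

        self.factor_names: list[str] = []
        self.factor_levels: dict[str, np.ndarray] = {}
        codes_list = []
        sizes = []
        for name, raw in factors.items():
            codes, levels = pd.factorize(np.asarray(raw), sort=True)
            if len(levels) < 2:
                warnings.warn(
                    f"random factor {name!r} has < 2 levels and was dropped",
                    stacklevel=2,
                )
                continue
            self.factor_names.append(name)
            self.factor_levels[name] = np.asarray(levels)
            codes_list.append(codes)
            sizes.append(len(levels))
        self.q_sizes = np.array(sizes, dtype=int)
        self.q = int(self.q_sizes.sum())
        self.n_factors = len(self.factor_names)

        if self.n_factors:
            offsets = np.concatenate([[0], np.cumsum(self.q_sizes[:-1])])
            cols = np.concatenate([c + o for c, o in zip(codes_list, offsets)])
            rows = np.tile(np.arange(self.n), self.n_factors)
            self.z = sp.csr_matrix(
                (np.ones(len(cols)), (rows, cols)), shape=(self.n, self.q)
            )
            self.ztz = np.asarray((self.z.T @ self.z).todense())
            self.ztx = np.asarray(self.z.T @ self.x)
            # column -> factor index, for scaling by relative SDs
            self.col_factor = np.repeat(np.arange(self.n_factors), self.q_sizes)
        else:
            self.z = None
        self.xtx = self.x.T @ self.x
        if self.n_factors:
            self.xtz = np.ascontiguousarray(self.ztx.T)
            self._m_buf = np.zeros((self.q + self.p, self.q + self.p))
            self._m_buf[self.q :, self.q :] = self.xtx
            self._diag_idx = np.diag_indices(self.q)
            self._rhs_buf = np.empty(self.q + self.p)

    # -- likelihood machinery -------------------------------------------------

    def _solve(self, lam: np.ndarray, zty: np.ndarray, xty: np.ndarray, yty: float):
        """Penalized least squares at relative SDs ``lam`` (>= 0).

        One bordered Cholesky of ``[[D Z'Z D + I, D Z'X], [X'Z D, X'X]]``
        yields log|A| (leading q diagonal entries), log|S| (trailing p
        entries, S the fixed-effect information) and the joint solve for
        (u, beta).  Returns (logdet_A, logdet_S, r2, beta, u, chol_S).
        """
        q, p = self.q, self.p
        lam_col = lam[self.col_factor]
        m = self._m_buf
        np.multiply(self.ztz, lam_col[:, None], out=m[:q, :q])
        m[:q, :q] *= lam_col[None, :]
        m[:q, :q][self._diag_idx] += 1.0
        np.multiply(self.xtz, lam_col[None, :], out=m[q:, :q])
        lm, info = lapack.dpotrf(m, lower=1, overwrite_a=0)
        if info != 0:
            raise np.linalg.LinAlgError("mixed-model system is not positive definite")
        diag = np.diag(lm)
        logdet_a = 2.0 * np.sum(np.log(diag[:q]))
        logdet_s = 2.0 * np.sum(np.log(diag[q:]))
        rhs = self._rhs_buf
        np.multiply(lam_col, zty, out=rhs[:q])
        rhs[q:] = xty
        v, info = lapack.dpotrs(lm, rhs, lower=1)
        r2 = yty - rhs @ v
        return (
            logdet_a,
            logdet_s,
            max(float(r2), 1e-300),
            v[q:],
            v[:q],
            (lm[q:, q:], lam_col),
        )

    def _deviance(self, lam, zty, xty, yty, method) -> float:
        logdet_a, logdet_s, r2, _, _, _ = self._solve(lam, zty, xty, yty)
        n, p = self.n, self.p
        if method == "ML":
            return logdet_a + n * (1.0 + np.log(2.0 * np.pi * r2 / n))
        return logdet_a + logdet_s + (n - p) * (1.0 + np.log(2.0 * np.pi * r2 / (n - p)))

    def _ols(self, y, method) -> FitResult:
        """Closed form when no random factor survives."""
        beta, _, _, _ = np.linalg.lstsq(self.x, y, rcond=None)
        resid = y - self.x @ beta
        r2 = float(resid @ resid)
        n, p = self.n, self.p
        sigma2 = r2 / n if method == "ML" else r2 / (n - p)
        ll = (
            -0.5 * (n * (1.0 + np.log(2.0 * np.pi * r2 / n)))
            if method == "ML"
            else -0.5
            * (
                np.linalg.slogdet(self.xtx)[1]
                + (n - p) * (1.0 + np.log(2.0 * np.pi * r2 / (n - p)))
            )
        )
        cov = sigma2 * np.linalg.inv(self.xtx)
        fitted = self.x @ beta
        return FitResult(
            spec=None,
            method=method,
            beta=pd.Series(beta, index=self.term_names),
            beta_cov=pd.DataFrame(cov, index=self.term_names, columns=self.term_names),
            varcomps=pd.Series({"resid": sigma2}),
            loglik=float(ll),
            n_obs=n,
            n_params=p + 1,
            converged=True,
            var_fixed=float(np.var(fitted)),
            theta=np.empty(0),
        )

    def fit(
        self,
        y: np.ndarray,
        method: str = "REML",
        theta0: np.ndarray | None = None,
        accurate: bool = True,
        spec: ModelSpec | None = None,
        want_blups: bool = False,
    ) -> FitResult:
        """Fit by Nelder-Mead on the profiled deviance.

        ``theta0`` warm-starts the search (e.g. from the observed-data fit
        when refitting permuted responses); ``accurate=False`` relaxes the
        convergence tolerances for permutation refits where only the fixed
        effects are harvested.  Non-convergence triggers restarts from a
        fixed grid of starting values before the fit is flagged.
        """
        if method not in ("REML", "ML"):
            raise ValueError("method must be 'REML' or 'ML'")
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n,):
            raise ValueError("response length does not match the design")
        if self.n_factors == 0:
            res = self._ols(y, method)
            res.spec = spec
            return res

        zty = self.z.T @ y
        xty = self.x.T @ y
        yty = float(y @ y)

        # The search runs on the relative-SD scale with absolute-value
        # folding: |lam| makes sigma_f -> 0 an ordinary interior point of a
        # smooth symmetric surface instead of a log-scale cliff, which keeps
        # the simplex search fast when components sit on the boundary.
        def objective(lam):
            return self._deviance(np.abs(lam), zty, xty, yty, method)

        if self.n_factors == 1:
            # one variance ratio: bounded Brent on the log scale is cheap
            # and very precise (used by the closed-form equivalence checks)
            res = optimize.minimize_scalar(
                lambda t: objective(np.array([np.exp(t)])),
                bounds=_LOG_LAMBDA_BOUNDS,
                method="bounded",
                options={"xatol": 1e-10 if accurate else 1e-5},
            )
            best = optimize.OptimizeResult(
                x=np.array([np.exp(res.x)]), fun=res.fun, success=bool(res.success)
            )
            return self._finalize(best, bool(res.success), zty, xty, yty, method, spec, want_blups)

        if accurate:
            options = {"xatol": 1e-5, "fatol": 1e-9, "maxfev": 4000}
        else:
            # permutation refits: variance ratios only steer the GLS weights,
            # so ~1e-2 accuracy in the relative SDs is ample
            options = {"xatol": 5e-3, "fatol": 1e-2, "maxfev": 400}

        starts = []
        if theta0 is not None:
            # warm start; boundary components are lifted off 0 so the
            # initial simplex has room to move
            starts.append(np.maximum(np.exp(np.asarray(theta0, dtype=float)), 0.02))
        starts.append(np.full(self.n_factors, 0.5))
        best = None
        converged = False
        for s0 in starts:
            res = optimize.minimize(objective, s0, method="Nelder-Mead", options=options)
            if best is None or res.fun < best.fun - 1e-10:
                best = res
            if res.success:
                converged = True
                best = res if res.fun <= best.fun + 1e-10 else best
                break
        if not converged:
            # multi-start from a fixed grid of shared relative SDs
            for g in (0.05, 0.2, 1.0, 2.5):
                res = optimize.minimize(
                    objective, np.full(self.n_factors, g), method="Nelder-Mead", options=options
                )
                if res.fun < best.fun:
                    best = res
                if res.success:
                    converged = True
                    break
        return self._finalize(best, converged, zty, xty, yty, method, spec, want_blups)

    def fit_beta_only(
        self, y: np.ndarray, method: str = "REML", lam0: np.ndarray | None = None
    ) -> tuple[np.ndarray, bool, np.ndarray]:
        """Fast path for permutation refits: fixed effects and convergence only.

        Re-estimates the variance components exactly like :meth:`fit` (loose
        tolerances, warm start at relative SDs ``lam0``) but skips
        covariance, BLUP and summary construction, which dominate the cost
        of thousands of small refits.  Returns (beta, converged, lam_hat)
        so successive refits can chain their warm starts.
        """
        y = np.asarray(y, dtype=float)
        if self.n_factors == 0:
            beta, _, _, _ = np.linalg.lstsq(self.x, y, rcond=None)
            return beta, True, np.empty(0)
        zty = self.z.T @ y
        xty = self.x.T @ y
        yty = float(y @ y)

        def objective(lam):
            return self._deviance(np.abs(lam), zty, xty, yty, method)

        start = (
            np.maximum(np.abs(np.asarray(lam0, dtype=float)), 0.02)
            if lam0 is not None
            else np.full(self.n_factors, 0.5)
        )
        res = optimize.minimize(
            objective,
            start,
            method="Nelder-Mead",
            options={"xatol": 1e-2, "fatol": 5e-2, "maxfev": 300},
        )
        lam_hat = np.abs(res.x)
        _, _, _, beta, _, _ = self._solve(lam_hat, zty, xty, yty)
        return beta, bool(res.success), lam_hat

    def _finalize(self, best, converged, zty, xty, yty, method, spec, want_blups) -> FitResult:
        lam = np.abs(np.asarray(best.x, dtype=float))
        logdet_a, logdet_s, r2, beta, u, (ls, lam_col) = self._solve(lam, zty, xty, yty)
        n, p = self.n, self.p
        sigma2 = r2 / (n - p) if method == "REML" else r2 / n
        boundary = {}
        varcomps = {}
        for i, name in enumerate(self.factor_names):
            at_zero = lam[i] < _BOUNDARY_LAMBDA
            boundary[name] = bool(at_zero)
            varcomps[name] = 0.0 if at_zero else float(lam[i] ** 2 * sigma2)
        varcomps["resid"] = float(sigma2)

        s_inv = sla.cho_solve((ls, True), np.eye(p), check_finite=False)
        cov = sigma2 * s_inv
        fitted = self.x @ beta

        blups = {}
        if want_blups:
            b_all = lam_col * u
            off = 0
            for i, name in enumerate(self.factor_names):
                k = self.q_sizes[i]
                blups[name] = pd.Series(b_all[off : off + k], index=self.factor_levels[name])
                off += k

        return FitResult(
            spec=spec,
            method=method,
            beta=pd.Series(beta, index=self.term_names),
            beta_cov=pd.DataFrame(cov, index=self.term_names, columns=self.term_names),
            varcomps=pd.Series(varcomps),
            loglik=float(-0.5 * best.fun),
            n_obs=n,
            n_params=p + self.n_factors + 1,
            converged=bool(converged),
            boundary=boundary,
            var_fixed=float(np.var(fitted)),
            theta=np.log(np.maximum(lam, 1e-12)),
            blups=blups,
        )


def make_matrices(spec: ModelSpec, data: pd.DataFrame) -> MixedModelMatrices:
    """Build the reusable cross-product cache for ``spec`` over ``data``."""
    x = build_design(data, spec)
    factors = {f: data[f].to_numpy() for f in spec.random_factors if f in data.columns}
    return MixedModelMatrices(x, factors)


def fit_lmm(y, spec: ModelSpec, data: pd.DataFrame, method: str = "REML") -> FitResult:
    """Fit one model of the ladder on ``data``.

    ``data`` carries the standardized predictors, the ``genus`` column and
    the random-factor columns named in ``spec.random_factors``.
    """
    mats = make_matrices(spec, data)
    return mats.fit(np.asarray(y, dtype=float), method=method, spec=spec, want_blups=True)


def aic(fit: FitResult) -> float:
    """Akaike information criterion, ``-2 lnL + 2k``; ML fits only.

    k counts fixed effects plus all variance components including the
    residual.
    """
    if fit.method != "ML":
        raise ValueError("AIC requires an ML fit; refit with method='ML'")
    return -2.0 * fit.loglik + 2.0 * fit.n_params


def lrt(fit_small: FitResult, fit_big: FitResult) -> ComparisonResult:
    """Chi-square likelihood-ratio test between two nested ML fits."""
    for f in (fit_small, fit_big):
        if f.method != "ML":
            raise ValueError("likelihood-ratio tests require ML fits")
    if fit_small.spec is not None and fit_big.spec is not None:
        if not fit_small.spec.is_nested_in(fit_big.spec):
            raise ValueError(
                f"model {fit_small.spec.name!r} is not nested in {fit_big.spec.name!r}"
            )
    if fit_small.n_obs != fit_big.n_obs:
        raise ValueError("fits must use identical rows")
    chi2 = max(0.0, 2.0 * (fit_big.loglik - fit_small.loglik))
    df = fit_big.n_params - fit_small.n_params
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else float(chi2 == 0.0)
    return ComparisonResult(chi2=chi2, df=df, p_value=p, delta_aic=aic(fit_big) - aic(fit_small))


def pseudo_r2(fit: FitResult) -> tuple[float, float]:
    """Marginal and conditional pseudo-R-squared.

    Marginal is the share of variance explained by the fixed effects,
    ``var(X b) / (var(X b) + sum(sigma2_random) + sigma2_resid)``;
    conditional adds the random-intercept variances to the numerator.
    """
    var_f = fit.var_fixed
    var_r = float(sum(v for k, v in fit.varcomps.items() if k != "resid"))
    var_e = float(fit.varcomps["resid"])
    denom = var_f + var_r + var_e
    return var_f / denom, (var_f + var_r) / denom
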