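"""Regression layer: VIF screening, OLS, Gamma GLM (identity link),
Moran's I permutation tests, and maximum-likelihood spatial error models.

The module follows the statsmodels idiom: each estimator is a model class
constructed from data whose ``fit()`` returns a :class:`ModelResult` carrying
estimates, standard errors, test statistics, diagnostics and a ``summary()``
table.  OLS and the Gamma GLM delegate to statsmodels internally; the spatial
error model

    y = X beta + u,   u = lambda W u + eps,   eps ~ N(0, sigma^2 I)

is fitted by concentrated maximum likelihood with an eigenvalue-based
log-determinant Jacobian, exact at the problem sizes this package targets
(hundreds of spatial units).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.spatial import cKDTree


# ---------------------------------------------------------------------------
# spatial weights
# ---------------------------------------------------------------------------

@dataclass
class SpatialWeights:
    """Spatial weights matrix over a fixed unit ordering.

    ``w`` is the (possibly row-standardized) weight matrix actually used in
    statistics; ``binary`` keeps the symmetric 0/1 adjacency it was derived
    from, which makes the eigenvalue computation for the spatial error model
    exact and real-valued.
    """

    unit_ids: list
    w: np.ndarray
    row_standardized: bool
    binary: np.ndarray | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if np.any(np.diag(w) != 0):
            raise ValueError("self-neighbors are not allowed")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        if self.row_standardized:
            rs = w.sum(axis=1)
            nonempty = rs > 0
            if not np.allclose(rs[nonempty], 1.0):
                raise ValueError("row-standardized weights must have rows summing to 1")
        self.w = w

    @property
    def n(self) -> int:
        return self.w.shape[0]

    @property
    def s0(self) -> float:
        return float(self.w.sum())

    def eigenvalues(self) -> np.ndarray:
        """Real eigenvalues of W.

        A row-standardized matrix built from a symmetric binary adjacency B is
        similar to the symmetric D^{-1/2} B D^{-1/2}, so its spectrum is real.
        """
        if self.row_standardized and self.binary is not None:
            deg = self.binary.sum(axis=1)
            if (deg == 0).any():
                raise ValueError("isolated units have no admissible eigen-decomposition")
            dinv = 1.0 / np.sqrt(deg)
            sym = self.binary * np.outer(dinv, dinv)
            return np.linalg.eigvalsh(sym)
        ev = np.linalg.eigvals(self.w)
        if np.abs(ev.imag).max() > 1e-8:
            raise ValueError("weight matrix has complex eigenvalues")
        return np.sort(ev.real)


def build_weights(
    unit_coords: pd.DataFrame | np.ndarray,
    k: int = 8,
    row_standardize: bool = True,
) -> SpatialWeights:
    """Symmetric-by-union k-nearest-neighbour spatial weights.

    Distance ties are broken deterministically by unit order.  The union
    symmetrization guarantees no isolated units and a symmetric underlying
    adjacency, so the spatial error model's Jacobian uses a real spectrum.
    """
    if isinstance(unit_coords, pd.DataFrame):
        ids = list(unit_coords.index)
        xy = unit_coords[["x", "y"]].to_numpy(dtype=float)
    else:
        xy = np.asarray(unit_coords, dtype=float)
        ids = list(range(len(xy)))
    n = len(xy)
    if not np.isfinite(xy).all():
        raise ValueError("coordinates must be finite")
    if k < 1 or k >= n:
        raise ValueError(f"k must satisfy 1 <= k < n_units (k={k}, n={n})")

    # query k+1 because the point itself is returned; ties broken by index
    # because np.argsort on (distance, index) pairs is made stable below
    dist = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)) if n <= 2048 else None
    b = np.zeros((n, n))
    if dist is None:
        tree = cKDTree(xy)
        dd, ii = tree.query(xy, k=k + 1)
        for i in range(n):
            neigh = [j for j in ii[i] if j != i][:k]
            b[i, neigh] = 1.0
    else:
        np.fill_diagonal(dist, np.inf)
        order = np.lexsort((np.tile(np.arange(n), (n, 1)), dist), axis=1)
        for i in range(n):
            b[i, order[i, :k]] = 1.0
    b = np.maximum(b, b.T)  # symmetrize by union
    w = b / b.sum(axis=1, keepdims=True) if row_standardize else b
    return SpatialWeights(ids, w, row_standardize, binary=b)


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------

@dataclass
class ModelResult:
    """Unified fit result for OLS / Gamma GLM / spatial error models."""

    response: str
    family: str  # gaussian-ols | gamma-identity-glm | sar-error
    params: pd.Series
    bse: pd.Series
    statistics: pd.Series  # t (OLS) or z values
    pvalues: pd.Series
    llf: float
    resid: np.ndarray
    fittedvalues: np.ndarray
    nobs: int
    stat_name: str = "t value"
    lam: float | None = None
    lam_se: float | None = None
    lam_pvalue: float | None = None
    moran_i: float | None = None
    moran_p: float | None = None
    vif: pd.Series | None = None
    transform: str = "none"  # none | log-with-back-transform
    branch: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if ((self.pvalues < 0) | (self.pvalues > 1)).any():
            raise ValueError("p-values outside [0, 1]")

    @property
    def fitted_response(self) -> np.ndarray:
        """Fitted values on the original response scale (back-transformed)."""
        if self.transform == "log-with-back-transform":
            return np.exp(self.fittedvalues)
        return self.fittedvalues

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "Estimate": self.params,
            "Std. error": self.bse,
            self.stat_name: self.statistics,
            "p value": self.pvalues,
        })

    def summary(self) -> str:
        lines = [
            f"Response: {self.response}    family: {self.family}"
            + (f"    transform: {self.transform}" if self.transform != "none" else ""),
            f"n = {self.nobs}    log-likelihood = {self.llf:.4f}",
            self.coef_table().to_string(float_format=lambda v: f"{v: .4g}"),
        ]
        if self.lam is not None:
            lines.append(
                f"lambda = {self.lam:.4f} (SE {self.lam_se:.4f}, p = {self.lam_pvalue:.4g})"
            )
        if self.moran_i is not None:
            lines.append(f"residual Moran's I = {self.moran_i:.4f} (perm. p = {self.moran_p:.4g})")
        if self.vif is not None:
            lines.append("VIF: " + ", ".join(f"{k}={v:.2f}" for k, v in self.vif.items()))
        if self.branch is not None:
            lines.append(f"model chooser branch: {self.branch}")
        return "\n".join(lines)


def _full_design(y: np.ndarray, exog, names) -> tuple[np.ndarray, list[str]]:
    """Design matrix with intercept; ``exog=None`` gives an intercept-only model."""
    if exog is None:
        return np.ones((len(y), 1)), []
    X, names = _design(exog, names)
    return sm.add_constant(X, has_constant="raise"), names


def _design(X, names=None) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if names is None:
            names = [f"x{i+1}" for i in range(X.shape[1])]
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in design matrix")
    return X, names


# ---------------------------------------------------------------------------
# VIF screening
# ---------------------------------------------------------------------------

def vif(X, names=None) -> pd.Series:
    """Variance inflation factors 1/(1-R^2_j) per predictor.

    Each predictor is regressed (with intercept) on all others.  Perfect
    collinearity raises, naming the offending predictors.
    """
    X, names = _design(X, names)
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF needs at least 2 predictors")
    if n <= p:
        raise ValueError("need more observations than predictors")
    corr = np.corrcoef(X, rowvar=False)
    dup = np.argwhere(np.triu(np.abs(corr) > 1 - 1e-10, k=1))
    if dup.size:
        i, j = dup[0]
        raise ValueError(f"perfectly collinear predictors: {names[i]} and {names[j]}")
    out = {}
    for j in range(p):
        others = sm.add_constant(np.delete(X, j, axis=1))
        r2 = sm.OLS(X[:, j], others).fit().rsquared
        if r2 > 1 - 1e-12:
            raise ValueError(f"predictor {names[j]} is perfectly collinear with the others")
        out[names[j]] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


# ---------------------------------------------------------------------------
# OLS and Gamma GLM (statsmodels-backed)
# ---------------------------------------------------------------------------

class OrdinaryLeastSquares:
    """Gaussian linear model; thin wrapper producing a :class:`ModelResult`."""

    def __init__(self, endog, exog=None, names=None, response: str = "y"):
        self.y = np.asarray(endog, dtype=float)
        self.X, self.names = _full_design(self.y, exog, names)
        self.response = response
        n, p = self.X.shape
        if n <= p:
            raise ValueError("need n > p + 1 observations")
        if not np.isfinite(self.y).all():
            raise ValueError("non-finite response values")
        if np.linalg.matrix_rank(self.X) < p:
            raise ValueError("rank-deficient design matrix")

    def fit(self) -> ModelResult:
        res = sm.OLS(self.y, self.X).fit()
        idx = ["Intercept"] + self.names
        return ModelResult(
            response=self.response, family="gaussian-ols",
            params=pd.Series(res.params, index=idx),
            bse=pd.Series(res.bse, index=idx),
            statistics=pd.Series(res.tvalues, index=idx),
            pvalues=pd.Series(res.pvalues, index=idx),
            llf=float(res.llf), resid=np.asarray(res.resid),
            fittedvalues=np.asarray(res.fittedvalues), nobs=len(self.y),
            stat_name="t value",
        )


class GammaIdentityGLM:
    """Gamma-family GLM with identity link, OLS starting values."""

    def __init__(self, endog, exog=None, names=None, response: str = "y"):
        self.y = np.asarray(endog, dtype=float)
        if (self.y <= 0).any():
            raise ValueError("Gamma GLM requires a strictly positive response")
        self.X, self.names = _full_design(self.y, exog, names)
        self.response = response

    def fit(self) -> ModelResult:
        start = sm.OLS(self.y, self.X).fit().params
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # identity-link Gamma warns about domain
            model = sm.GLM(self.y, self.X,
                           family=sm.families.Gamma(sm.families.links.Identity()))
            res = model.fit(start_params=start, maxiter=500)
        mu = np.asarray(res.fittedvalues)
        if not res.converged or (mu <= 0).any():
            raise RuntimeError(
                "Gamma identity-link GLM failed to converge to positive fitted means; "
                "consider rescaling the response"
            )
        idx = ["Intercept"] + self.names
        return ModelResult(
            response=self.response, family="gamma-identity-glm",
            params=pd.Series(res.params, index=idx),
            bse=pd.Series(res.bse, index=idx),
            statistics=pd.Series(res.tvalues, index=idx),
            pvalues=pd.Series(res.pvalues, index=idx),
            llf=float(res.llf), resid=np.asarray(res.resid_response),
            fittedvalues=mu, nobs=len(self.y), stat_name="t value",
        )


def fit_ols(y, X=None, names=None, response: str = "y") -> ModelResult:
    return OrdinaryLeastSquares(y, X, names, response).fit()


def fit_gamma_glm(y, X=None, names=None, response: str = "y") -> ModelResult:
    return GammaIdentityGLM(y, X, names, response).fit()


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------

def morans_i(x: np.ndarray, weights: SpatialWeights) -> float:
    """Global Moran's I = (n / S0) * (z' W z) / (z' z) with z centered."""
    x = np.asarray(x, dtype=float)
    if len(x) != weights.n:
        raise ValueError("value vector length does not match weights")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("Moran's I undefined for a constant vector")
    s0 = weights.s0
    if s0 == 0:
        raise ValueError("all spatial weights are zero")
    return float(len(x) / s0 * (z @ weights.w @ z) / denom)


def moran_test(
    residuals: np.ndarray,
    weights: SpatialWeights,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Permutation test for Moran's I.

    Returns (I, p) with a two-sided p-value centered on the permutation mean,
    using the +1 correction p = (1 + #{|I* - E| >= |I - E|}) / (n_perm + 1).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(residuals, dtype=float)
    i_obs = morans_i(x, weights)

    z = x - x.mean()
    denom = float(z @ z)
    scale = len(x) / weights.s0
    perms = np.empty((n_perm, len(z)))
    for r in range(n_perm):
        perms[r] = rng.permutation(z)
    i_perm = scale * np.einsum("ri,ri->r", perms @ weights.w, perms) / denom
    e = i_perm.mean()
    p = (1.0 + np.sum(np.abs(i_perm - e) >= abs(i_obs - e))) / (n_perm + 1.0)
    return i_obs, float(p)


# ---------------------------------------------------------------------------
# spatial error model
# ---------------------------------------------------------------------------

class SpatialErrorModel:
    """ML spatial error model y = X beta + u, u = lambda W u + eps.

    The likelihood is concentrated over (beta, sigma^2): for a trial lambda,
    beta is GLS on the spatially filtered variables (I - lambda W) y and
    (I - lambda W) X, and the profile log-likelihood

        l(lambda) = const - (n/2) log sigma^2(lambda) + log |I - lambda W|

    uses the exact eigenvalue form log|I - lambda W| = sum log(1 - lambda e_i).
    lambda is constrained to the admissible interval (1/e_min, 1/e_max).
    """

    def __init__(self, endog, exog, weights: SpatialWeights, names=None,
                 response: str = "y"):
        self.y = np.asarray(endog, dtype=float)
        self.X, self.names = _full_design(self.y, exog, names)
        self.W = weights
        self.response = response
        n, p = self.X.shape
        if n != weights.n:
            raise ValueError("response length does not match spatial weights")
        if n <= p + 2:
            raise ValueError("need n > p + 2 observations")
        self._eig = weights.eigenvalues()

    def _profile(self, lam: float) -> tuple[float, np.ndarray, np.ndarray, float]:
        """Profile log-likelihood and (beta, eps, sigma^2) at fixed lambda."""
        n = len(self.y)
        a_y = self.y - lam * (self.W.w @ self.y)
        a_x = self.X - lam * (self.W.w @ self.X)
        beta, *_ = np.linalg.lstsq(a_x, a_y, rcond=None)
        eps = a_y - a_x @ beta
        sigma2 = float(eps @ eps) / n
        logdet = float(np.sum(np.log(1.0 - lam * self._eig)))
        llf = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet
        return llf, beta, eps, sigma2

    def fit(self, force_lambda: float | None = None) -> ModelResult:
        e_min, e_max = self._eig.min(), self._eig.max()
        lo = 1.0 / e_min + 1e-9 if e_min < 0 else -0.999999
        hi = 1.0 / e_max - 1e-9 if e_max > 0 else 0.999999

        if force_lambda is not None:
            lam = float(force_lambda)
        else:
            res = optimize.minimize_scalar(
                lambda lam: -self._profile(lam)[0],
                bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-8},
            )
            lam = float(res.x)
            if min(lam - lo, hi - lam) < 1e-5:
                warnings.warn(
                    f"lambda estimate {lam:.6f} is at the admissible boundary "
                    f"({lo:.4f}, {hi:.4f})", RuntimeWarning,
                )

        llf, beta, eps, sigma2 = self._profile(lam)
        if not np.isfinite(llf):
            raise RuntimeError("singular (I - lambda W) at the optimum")
        n, p = self.X.shape

        a_x = self.X - lam * (self.W.w @ self.X)
        cov_beta = sigma2 * np.linalg.inv(a_x.T @ a_x)
        bse = np.sqrt(np.diag(cov_beta))
        zvals = beta / bse
        pvals = 2 * stats.norm.sf(np.abs(zvals))

        # lambda SE from the curvature of the profile likelihood (beta and
        # lambda are information-orthogonal in this model)
        if force_lambda is None:
            h = 1e-5 * max(1.0, abs(lam))
            h = min(h, (hi - lam) / 2, (lam - lo) / 2) or 1e-8
            d2 = (self._profile(lam + h)[0] - 2 * llf + self._profile(lam - h)[0]) / h**2
            lam_se = float(np.sqrt(-1.0 / d2)) if d2 < 0 else np.nan
            lam_p = float(2 * stats.norm.sf(abs(lam / lam_se))) if lam_se and np.isfinite(lam_se) else np.nan
        else:
            lam_se = lam_p = np.nan

        # u = y - X beta are the spatially structured residuals; the
        # whitened innovations eps = (I - lambda W) u are what a post-fit
        # autocorrelation check should see
        u = self.y - self.X @ beta
        idx = ["Intercept"] + self.names
        return ModelResult(
            response=self.response, family="sar-error",
            params=pd.Series(beta, index=idx),
            bse=pd.Series(bse, index=idx),
            statistics=pd.Series(zvals, index=idx),
            pvalues=pd.Series(pvals, index=idx),
            llf=float(llf), resid=eps, fittedvalues=self.X @ beta,
            nobs=n, stat_name="z value",
            lam=lam, lam_se=lam_se, lam_pvalue=lam_p,
            extra={"sigma2": sigma2, "structured_resid": u,
                   "lambda_interval": (lo, hi)},
        )


def fit_sar_error(y, X, weights: SpatialWeights, names=None, response: str = "y",
                  force_lambda: float | None = None) -> ModelResult:
    return SpatialErrorModel(y, X, weights, names, response).fit(force_lambda=force_lambda)


def fit_log_sar_error(y, X, weights: SpatialWeights, names=None,
                      response: str = "y") -> ModelResult:
    """Spatial error model on ln(y); predictions back-transform via exp."""
    y = np.asarray(y, dtype=float)
    if (y <= 0).any():
        raise ValueError("log transform requires a strictly positive response")
    result = SpatialErrorModel(np.log(y), X, weights, names, response).fit()
    result.transform = "log-with-back-transform"
    return result


# ---------------------------------------------------------------------------
# the model chooser
# ---------------------------------------------------------------------------

def select_and_fit(
    y, X, weights: SpatialWeights, *,
    seed: int | np.random.Generator | None = None,
    names=None, response: str = "y",
    skew_threshold: float = 0.5,
    moran_alpha: float = 0.05,
    n_perm: int = 1000,
) -> ModelResult:
    """Deterministic version of the residual-diagnostics model chooser.

    (1) fit OLS; (2) if the OLS residuals are skewed beyond
    ``skew_threshold`` and the response is strictly positive, refit as a
    Gamma GLM with identity link; (3) run the Moran permutation test on the
    current model's residuals; if significant, refit as a spatial error
    model — on the log response if the skewed branch had fired (the GLM
    framework being unavailable for the spatial fit).  The returned result
    records the branch, Moran diagnostics and VIFs.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    vifs = vif(X, names)

    result = fit_ols(y, X, names, response)
    branch = "ols"
    gamma_fallback = False
    skew = float(stats.skew(result.resid))
    if abs(skew) > skew_threshold and (y > 0).all():
        try:
            result = fit_gamma_glm(y, X, names, response)
            branch = "gamma-glm"
        except RuntimeError:
            # a Gamma candidate that cannot reach positive fitted means falls
            # back to the OLS fit rather than aborting the whole analysis
            gamma_fallback = True

    i_obs, p = moran_test(result.resid, weights, n_perm=n_perm, seed=rng)
    if p < moran_alpha:
        if branch == "gamma-glm":
            result = fit_log_sar_error(y, X, weights, names, response)
            branch = "log-sar-error"
        else:
            result = fit_sar_error(y, X, weights, names, response)
            branch = "sar-error"
        i_obs, p = moran_test(result.resid, weights, n_perm=n_perm, seed=rng)

    result.branch = branch
    result.moran_i, result.moran_p = i_obs, p
    result.vif = vifs
    result.extra["ols_resid_skew"] = skew
    result.extra["gamma_fallback"] = gamma_fallback
    return result
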