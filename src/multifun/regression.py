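"""OLS and simultaneous-autoregressive (SAR) error regressions.

The SAR error model is the standard device in spatial ecology for
regressing a response on predictors while absorbing residual spatial
autocorrelation:

    y = X beta + u,    u = lambda W u + eps,   eps ~ N(0, sigma^2 I)

with W a row-standardized spatial weights matrix.  The fit maximizes the
profile (concentrated) log-likelihood over lambda, using the eigenvalues
of W for the log-determinant term, then recovers beta and sigma^2 by
generalized least squares at lambda-hat.  Models are compared with the
small-sample AICc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.stats import norm

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between points given in degrees."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


@dataclass
class SpatialWeights:
    """Row-standardized n x n spatial weights with zero diagonal."""

    matrix: np.ndarray
    k: int | None = None
    metric: str = "haversine"
    _eigvals: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        W = np.asarray(self.matrix, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weights must be square")
        if np.any(W < 0):
            raise ValueError("weights must be non-negative")
        if np.any(np.diag(W) != 0):
            raise ValueError("weights diagonal must be zero")
        self.matrix = W

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def eigenvalues(self) -> np.ndarray:
        if self._eigvals is None:
            self._eigvals = np.linalg.eigvals(self.matrix)
        return self._eigvals

    def lambda_interval(self) -> tuple[float, float]:
        """Admissible (open) interval for the SAR parameter."""
        ev = self.eigenvalues()
        re = ev.real
        emin = re.min() if re.size else 0.0
        lo = 1.0 / emin if emin < 0 else -1.0
        hi = 1.0 / re.max() if re.max() > 0 else 1.0
        return lo, hi

    def log_det(self, lam: float) -> float:
        """log |I - lambda W| via the eigenvalues of W."""
        ev = self.eigenvalues()
        vals = 1.0 - lam * ev
        return float(np.sum(np.log(np.abs(vals))))

    def to_triplets(self) -> pd.DataFrame:
        i, j = np.nonzero(self.matrix)
        return pd.DataFrame({"i": i, "j": j, "w": self.matrix[i, j]})


def build_spatial_weights(coords: np.ndarray, k: int = 8) -> SpatialWeights:
    """k-nearest-neighbour weights from (lat, lon) degrees, row-standardized.

    Distances are great-circle (haversine); ties break toward the smaller
    site index.  Duplicate coordinates are allowed (zero-distance points
    become mutual neighbours first).
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n={n}")
    lat = coords[:, 0][:, None]
    lon = coords[:, 1][:, None]
    D = haversine_km(lat, lon, lat.T, lon.T)
    np.fill_diagonal(D, np.inf)
    W = np.zeros((n, n))
    for i in range(n):
        # stable sort => ties broken by smallest index
        nb = np.argsort(D[i], kind="stable")[:k]
        W[i, nb] = 1.0
    rs = W.sum(axis=1, keepdims=True)
    W = np.divide(W, rs, out=np.zeros_like(W), where=rs > 0)
    return SpatialWeights(W, k=k)


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike criterion."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    aic = -2.0 * loglik + 2.0 * k
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class RegressionFit:
    """Common result container for OLS and SAR fits."""

    model: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    sigma2: float
    loglik: float
    r2: float
    aicc: float
    n: int
    k: int
    lam: float | None = None
    meta: dict = field(default_factory=dict)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"low": self.params - z * self.bse, "high": self.params + z * self.bse}
        )

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "pvalues": self.pvalues.to_dict(),
            "sigma2": self.sigma2,
            "loglik": self.loglik,
            "r2": self.r2,
            "aicc": self.aicc,
            "n": self.n,
            "k": self.k,
            "lambda": self.lam,
            "meta": self.meta,
        }


def _design(X, add_const: bool) -> pd.DataFrame:
    X = pd.DataFrame(X).copy()
    if X.columns.dtype.kind in "iu":
        X.columns = [f"x{j}" for j in range(X.shape[1])]
    if add_const:
        X = sm.add_constant(X, has_constant="add")
    return X


def ols_fit(y, X, add_const: bool = True) -> RegressionFit:
    """Ordinary least squares with Gaussian log-likelihood and AICc.

    k counts the regression coefficients plus the residual variance.
    """
    Xd = _design(X, add_const)
    y = np.asarray(y, dtype=float)
    n, p = Xd.shape
    if n <= p + 1:
        raise ValueError(f"too few observations: n={n}, parameters={p + 1}")
    if np.linalg.matrix_rank(Xd.to_numpy()) < p:
        raise ValueError("design matrix is rank deficient")
    res = sm.OLS(y, Xd).fit()
    k = p + 1  # + sigma^2
    return RegressionFit(
        model="OLS",
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        sigma2=float(res.ssr / n),
        loglik=float(res.llf),
        r2=float(res.rsquared),
        aicc=aicc(float(res.llf), k, n),
        n=n,
        k=k,
    )


def _sar_concentrated(lam, y, X, W, logdet) -> tuple[float, np.ndarray, float]:
    """Concentrated log-likelihood and GLS estimates at fixed lambda."""
    n = y.shape[0]
    Ay = y - lam * (W @ y)
    AX = X - lam * (W @ X)
    beta, *_ = np.linalg.lstsq(AX, Ay, rcond=None)
    e = Ay - AX @ beta
    sigma2 = float(e @ e) / n
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet(lam)
    return ll, beta, sigma2


def sar_error_fit(y, X, weights: SpatialWeights, add_const: bool = True,
                  tol: float = 1e-8) -> RegressionFit:
    """Maximum-likelihood SAR error fit by profile likelihood over lambda.

    Pseudo-R^2 is the squared Pearson correlation between y and the trend
    predictions X beta-hat (the "R^2" convention recorded in meta).
    """
    Xd = _design(X, add_const)
    names = list(Xd.columns)
    Xm = Xd.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    W = weights.matrix
    if W.shape[0] != n:
        raise ValueError("weights dimension does not match y")

    if not W.any():
        base = ols_fit(y, X, add_const=add_const)
        fit = RegressionFit(
            model="SAR-error",
            params=base.params,
            bse=base.bse,
            pvalues=base.pvalues,
            sigma2=base.sigma2,
            loglik=base.loglik,
            r2=base.r2,
            aicc=aicc(base.loglik, base.k + 1, n),
            n=n,
            k=base.k + 1,
            lam=0.0,
            meta={"no_neighbors": True, "pseudo_r2": "corr(y, X beta)^2"},
        )
        return fit

    lo, hi = weights.lambda_interval()
    eps = 1e-6
    bracket = (lo + eps, hi - eps)
    res = minimize_scalar(
        lambda lam: -_sar_concentrated(lam, y, Xm, W, weights.log_det)[0],
        bounds=bracket,
        method="bounded",
        options={"xatol": tol},
    )
    if not res.success:
        raise RuntimeError(
            f"SAR lambda optimization failed on bracket {bracket}: {res.message}"
        )
    lam = float(res.x)
    ll, beta, sigma2 = _sar_concentrated(lam, y, Xm, W, weights.log_det)

    AX = Xm - lam * (W @ Xm)
    XtX = AX.T @ AX
    cov = sigma2 * np.linalg.inv(XtX) * n / max(n - len(beta), 1)
    bse = np.sqrt(np.diag(cov))
    z = beta / bse
    pvals = 2 * norm.sf(np.abs(z))

    trend = Xm @ beta
    if np.std(trend) > 0:
        r2 = float(np.corrcoef(y, trend)[0, 1] ** 2)
    else:
        r2 = 0.0
    k = len(beta) + 2  # + sigma^2 + lambda
    return RegressionFit(
        model="SAR-error",
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        pvalues=pd.Series(pvals, index=names),
        sigma2=sigma2,
        loglik=float(ll),
        r2=r2,
        aicc=aicc(float(ll), k, n),
        n=n,
        k=k,
        lam=lam,
        meta={"pseudo_r2": "corr(y, X beta)^2", "lambda_bracket": bracket},
    )


def compare_models(fits: list[RegressionFit]) -> pd.DataFrame:
    """Delta-AICc table, sorted ascending (best model first)."""
    if not fits:
        raise ValueError("no fits to compare")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits have mismatched n: {sorted(ns)}")
    rows = [
        {"model": f.model, "loglik": f.loglik, "k": f.k, "r2": f.r2, "aicc": f.aicc}
        for f in fits
    ]
    df = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
    df["delta_aicc"] = df["aicc"] - df["aicc"].iloc[0]
    return df
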