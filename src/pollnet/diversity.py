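"""Assemblage descriptors and architecture-function statistics.

Covers per-population diversity summaries (abundance, observed richness,
Hurlbert's PIE, Bray-Curtis and Morisita-Horn dissimilarities), OLS
residualization of network metrics against assemblage covariates, spatially
lagged regression (response and predictor lags), Spearman partial Mantel
tests, and one-way ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "hurlbert_pie",
    "bray_curtis",
    "morisita_horn",
    "dissimilarity_matrix",
    "residualize",
    "SpatialWeights",
    "spatial_weights",
    "SarFit",
    "fit_sar_mix",
    "MantelResult",
    "partial_mantel",
    "one_way_anova",
]


# ---------------------------------------------------------------------------
# assemblage descriptors


def hurlbert_pie(counts) -> float:
    """Probability of an interspecific encounter, with small-sample correction.

    ``(N/(N-1)) * (1 - sum p_i^2)`` for species counts summing to ``N``.
    """
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be nonnegative")
    n = x.sum()
    if n < 2:
        raise ValueError("Hurlbert's PIE requires at least 2 individuals")
    p = x / n
    return float(n / (n - 1) * (1.0 - (p**2).sum()))


def _check_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("abundance vectors must have the same length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be nonnegative")
    if x.sum() == 0 and y.sum() == 0:
        raise ValueError("both abundance vectors are zero")
    return x, y


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity: 1 - 2*sum(min)/(sum x + sum y)."""
    x, y = _check_pair(x, y)
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / (x.sum() + y.sum()))


def morisita_horn(x, y) -> float:
    """Morisita-Horn dissimilarity (1 - similarity)."""
    x, y = _check_pair(x, y)
    tx, ty = x.sum(), y.sum()
    if tx == 0 or ty == 0:
        return 1.0
    dx = (x**2).sum() / tx**2
    dy = (y**2).sum() / ty**2
    sim = 2.0 * (x * y).sum() / ((dx + dy) * tx * ty)
    return float(1.0 - sim)


def dissimilarity_matrix(abundances: np.ndarray, method: str = "bray_curtis") -> np.ndarray:
    """Pairwise dissimilarity matrix over rows (populations) of a count matrix."""
    fn = {"bray_curtis": bray_curtis, "morisita_horn": morisita_horn}[method]
    a = np.asarray(abundances, dtype=float)
    n = a.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = fn(a[i], a[j])
    return d


# ---------------------------------------------------------------------------
# residualization


def residualize(metric, covariate) -> np.ndarray:
    """OLS residuals of ``metric`` on ``covariate`` (with intercept); mean zero."""
    y = np.asarray(metric, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("metric and covariate must be 1-D of equal length")
    if y.size < 3:
        raise ValueError("residualization requires at least 3 observations")
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


# ---------------------------------------------------------------------------
# spatial weights


@dataclass
class SpatialWeights:
    """Neighbour-weight matrix among spatial units (zero diagonal)."""

    W: np.ndarray
    scheme: str
    row_standardized: bool

    def __post_init__(self) -> None:
        w = np.asarray(self.W, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("W must be square")
        if (w < 0).any() or np.diagonal(w).any():
            raise ValueError("W must be nonnegative with zero diagonal")
        if self.row_standardized:
            sums = w.sum(axis=1)
            ok = np.isclose(sums, 1.0) | np.isclose(sums, 0.0)
            if not ok.all():
                raise ValueError("row-standardized W must have rows summing to 1 (or 0)")
        self.W = w

    @property
    def n(self) -> int:
        return self.W.shape[0]


def spatial_weights(
    coords,
    scheme: str = "inverse_distance",
    row_standardize: bool = True,
    k: int = 3,
) -> SpatialWeights:
    """Build neighbour weights from planar coordinates.

    Schemes: ``inverse_distance`` (default, w_ij = 1/d_ij), ``knn`` (binary
    k-nearest-neighbour), ``gabriel`` (binary Gabriel graph).  Duplicate
    coordinates are rejected.
    """
    pts = np.asarray(coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("coords must be n x 2")
    if not np.isfinite(pts).all():
        raise ValueError("coordinates must be finite")
    n = pts.shape[0]
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
    off = ~np.eye(n, dtype=bool)
    if (d[off] == 0).any():
        raise ValueError("duplicate coordinates produce zero distances")
    if scheme == "inverse_distance":
        w = np.zeros_like(d)
        w[off] = 1.0 / d[off]
    elif scheme == "knn":
        w = np.zeros_like(d)
        for i in range(n):
            order = np.argsort(d[i])
            nearest = [j for j in order if j != i][:k]
            w[i, nearest] = 1.0
    elif scheme == "gabriel":
        w = np.zeros_like(d)
        for i in range(n):
            for j in range(i + 1, n):
                mid = (pts[i] + pts[j]) / 2
                radius = d[i, j] / 2
                dm = np.sqrt(((pts - mid) ** 2).sum(axis=1))
                others = np.delete(dm, [i, j])
                if (others >= radius - 1e-12).all():
                    w[i, j] = w[j, i] = 1.0
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    if row_standardize:
        sums = w.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        w = w / sums
    return SpatialWeights(W=w, scheme=scheme, row_standardized=row_standardize)


# ---------------------------------------------------------------------------
# spatially lagged regression: y = rho W y + X beta + W X gamma + eps


@dataclass
class SarFit:
    """Maximum-likelihood fit of the lagged-response, lagged-predictor model."""

    rho: float
    intercept: float
    beta: np.ndarray
    gamma: np.ndarray
    sigma2: float
    loglik: float
    coef_names: list
    coef: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p_values: np.ndarray
    n: int
    rho_se: float = float("nan")

    def summary(self) -> dict:
        return {
            "rho": self.rho,
            "rho_se": self.rho_se,
            "sigma2": self.sigma2,
            "loglik": self.loglik,
            "n": self.n,
            "coefficients": {
                name: {"estimate": float(c), "se": float(s), "z": float(z), "p": float(p)}
                for name, c, s, z, p in zip(
                    self.coef_names, self.coef, self.se, self.z, self.p_values
                )
            },
        }


def _sar_loglik(rho, y, Z, W, eigvals):
    """Profile log-likelihood in rho (beta, sigma2 concentrated out)."""
    n = y.size
    ytil = y - rho * (W @ y)
    coef, *_ = np.linalg.lstsq(Z, ytil, rcond=None)
    resid = ytil - Z @ coef
    sigma2 = (resid @ resid) / n
    if sigma2 <= 0:
        return -np.inf, coef, sigma2
    logdet = np.sum(np.log(np.abs(1.0 - rho * eigvals)))
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet
    return ll, coef, sigma2


def fit_sar_mix(
    y,
    X,
    weights: SpatialWeights,
    predictor_names: list | None = None,
    lag_predictors: bool = True,
    small_sample_warning: int = 15,
    fix_rho: float | None = None,
) -> SarFit:
    """Fit ``y = rho W y + X beta + W X gamma + eps`` by maximum likelihood.

    ``rho`` is profiled over its feasible interval using the eigenvalues of
    ``W`` for the log-Jacobian ``ln|I - rho W|``; the remaining coefficients
    come from least squares on the spatially filtered response.  Standard
    errors are asymptotic, from the numerical Hessian of the full
    log-likelihood.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, n_pred = X.shape
    if y.size != n:
        raise ValueError("y and X have incompatible shapes")
    W = weights.W
    if W.shape[0] != n:
        raise ValueError("weight matrix does not match the number of observations")
    if n <= small_sample_warning:
        warnings.warn(
            f"SAR fit with only n={n} spatial units; inference is fragile",
            stacklevel=2,
        )
    names = list(predictor_names or [f"x{i+1}" for i in range(n_pred)])
    cols = [np.ones(n), X]
    coef_names = ["intercept"] + names
    if lag_predictors:
        cols.append(W @ X)
        coef_names += [f"W.{nm}" for nm in names]
    Z = np.column_stack(cols)
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("design matrix is rank-deficient (collinear predictors)")
    if Z.shape[1] + 1 >= n:
        raise ValueError("more parameters than observations")

    eigvals = np.linalg.eigvals(W)
    real = eigvals[np.abs(eigvals.imag) < 1e-10].real
    lo = 1.0 / real.min() if (real < 0).any() else -5.0
    hi = 1.0 / real.max() if (real > 0).any() else 5.0
    eps = 1e-6 * (hi - lo)

    if fix_rho is None:
        res = optimize.minimize_scalar(
            lambda r: -_sar_loglik(r, y, Z, W, eigvals)[0],
            bounds=(lo + eps, hi - eps),
            method="bounded",
            options={"xatol": 1e-10},
        )
        rho_hat = float(res.x)
    else:
        rho_hat = float(fix_rho)
    ll, coef, sigma2 = _sar_loglik(rho_hat, y, Z, W, eigvals)

    theta_hat = np.concatenate([[rho_hat], coef, [np.log(sigma2)]])

    def full_nll(theta):
        rho, c, logs2 = theta[0], theta[1:-1], theta[-1]
        s2 = np.exp(logs2)
        resid = y - rho * (W @ y) - Z @ c
        logdet = np.sum(np.log(np.abs(1.0 - rho * eigvals)))
        return 0.5 * n * np.log(2 * np.pi * s2) + 0.5 * (resid @ resid) / s2 - logdet

    hess = _numerical_hessian(full_nll, theta_hat)
    try:
        cov = np.linalg.inv(hess)
        se_all = np.sqrt(np.clip(np.diagonal(cov), 0, None))
    except np.linalg.LinAlgError:  # pragma: no cover - near-singular Hessian
        se_all = np.full(theta_hat.size, np.nan)
    se = se_all[1:-1]
    z = np.where(se > 0, coef / se, np.nan)
    p = 2 * stats.norm.sf(np.abs(z))

    n_beta = n_pred
    return SarFit(
        rho=rho_hat,
        intercept=float(coef[0]),
        beta=coef[1 : 1 + n_beta],
        gamma=coef[1 + n_beta :] if lag_predictors else np.array([]),
        sigma2=float(sigma2),
        loglik=float(np.real(ll)),
        coef_names=coef_names,
        coef=coef,
        se=se,
        z=z,
        p_values=p,
        n=n,
        rho_se=float(se_all[0]),
    )


def _numerical_hessian(f, x0, rel_step: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    k = x0.size
    h = rel_step * np.maximum(np.abs(x0), 1.0)
    hess = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpp = f(x0 + ei + ej)
            fpm = f(x0 + ei - ej)
            fmp = f(x0 - ei + ej)
            fmm = f(x0 - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return hess


# ---------------------------------------------------------------------------
# partial Mantel


@dataclass
class MantelResult:
    statistic: float
    p_value: float
    permutations: int
    method: str

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "permutations": self.permutations,
            "method": self.method,
        }


def _check_distance_matrix(m, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be a square matrix")
    if not np.allclose(m, m.T):
        raise ValueError(f"{name} must be symmetric")
    return m


def _partial_corr(a, b, c) -> float:
    r_ab = np.corrcoef(a, b)[0, 1]
    r_ac = np.corrcoef(a, c)[0, 1]
    r_bc = np.corrcoef(b, c)[0, 1]
    denom = np.sqrt((1 - r_ac**2) * (1 - r_bc**2))
    if denom == 0:
        return 0.0
    return (r_ab - r_ac * r_bc) / denom


def _partial_corr_batch(a_rows: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Partial correlation of each row of ``a_rows`` with ``b`` given ``c``."""
    az = a_rows - a_rows.mean(axis=1, keepdims=True)
    az /= np.linalg.norm(az, axis=1, keepdims=True)
    bz = (b - b.mean()) / np.linalg.norm(b - b.mean())
    cz = (c - c.mean()) / np.linalg.norm(c - c.mean())
    r_ab = az @ bz
    r_ac = az @ cz
    r_bc = float(bz @ cz)
    denom = np.sqrt(np.clip((1 - r_ac**2) * (1 - r_bc**2), 1e-300, None))
    return (r_ab - r_ac * r_bc) / denom


def partial_mantel(
    A,
    B,
    C,
    method: str = "spearman",
    permutations: int = 1000,
    seed: int | None = None,
) -> MantelResult:
    """Partial Mantel test between distance matrices A and B controlling for C.

    The statistic is the partial (rank, for ``spearman``) correlation of the
    upper-triangle entries.  Significance is obtained by jointly permuting
    rows and columns of A; two-sided ``p = (1 + b)/(perms + 1)``.
    """
    A = _check_distance_matrix(A, "A")
    B = _check_distance_matrix(B, "B")
    C = _check_distance_matrix(C, "C")
    n = A.shape[0]
    if B.shape[0] != n or C.shape[0] != n:
        raise ValueError("matrices must have matching dimensions")
    if n < 4:
        raise ValueError("partial Mantel requires at least 4 objects")
    iu = np.triu_indices(n, k=1)

    def vec(m):
        v = m[iu]
        return stats.rankdata(v) if method == "spearman" else v

    b_v, c_v = vec(B), vec(C)
    observed = _partial_corr(vec(A), b_v, c_v)

    rng = np.random.default_rng(seed)
    # all permuted upper-triangle vectors at once, then vectorized correlations
    perms = np.array([rng.permutation(n) for _ in range(permutations)])
    a_perm = A[perms[:, iu[0]], perms[:, iu[1]]]  # (permutations, n_pairs)
    if method == "spearman":
        a_perm = stats.rankdata(a_perm, axis=1)
    stats_vec = _partial_corr_batch(a_perm, b_v, c_v)
    exceed = int((np.abs(stats_vec) >= abs(observed) - 1e-12).sum())
    p = (1 + exceed) / (permutations + 1)
    return MantelResult(
        statistic=float(observed),
        p_value=float(p),
        permutations=permutations,
        method=method,
    )


# ---------------------------------------------------------------------------
# one-way ANOVA


def one_way_anova(values, group_labels) -> dict:
    """Standard between/within decomposition; returns F, dfs and p."""
    y = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if y.size != labels.size:
        raise ValueError("values and labels must align")
    groups = [y[labels == g] for g in np.unique(labels)]
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    grand = y.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = y.size - len(groups)
    if df2 < 1:
        raise ValueError("not enough residual degrees of freedom")
    if ss_within == 0:
        raise ValueError("zero within-group variance: F is undefined")
    f = (ss_between / df1) / (ss_within / df2)
    return {
        "F": float(f),
        "df1": df1,
        "df2": df2,
        "p_value": float(stats.f.sf(f, df1, df2)),
    }
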