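"""Gaussian linear mixed model with a single cluster random intercept.

The covariance is V = sigma^2 (I + lambda Z Z') with lambda the
school-to-residual variance ratio.  Because Z is a cluster-intercept
indicator, everything reduces to per-cluster sufficient statistics
(Woodbury), so each profile evaluation costs O(J p^2) after an O(n p^2)
precompute.  beta and sigma^2 are profiled out and a bounded 1-D search
over log(lambda) does the rest; ML is the default so AICs are
comparable across models, REML is available by flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DesignSpec",
    "LMEMFit",
    "fit_lmem",
    "compute_icc",
    "summarize_scalar_sdee",
    "anova_variance_components",
    "build_design",
]

_LOG2PI = math.log(2.0 * math.pi)

#: covariate name -> (column, positive level) encodings
CATEGORY_CODES = {
    "sex": ("sex", "boy"),
    "race": ("race", "white"),
    "desk": ("desk", "stand-biased"),
}


@dataclass(frozen=True)
class DesignSpec:
    """Named design: response column, fixed-effect columns, cluster column."""

    response: str = "log_bmi"
    fixed: tuple = ("mean_sdee", "age", "sex", "race", "desk")
    cluster: str = "school_id"
    intercept: bool = True


@dataclass
class LMEMFit:
    names: list
    beta_hat: np.ndarray
    se: np.ndarray
    p: np.ndarray
    sigma2_school: float
    sigma2_resid: float
    loglik: float
    loglik_ml: float
    aic: float
    n: int
    n_clusters: int
    method: str
    converged: bool
    cov_beta: np.ndarray = field(repr=False, default=None)

    @property
    def n_params(self) -> int:
        return len(self.beta_hat) + 2

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"name": self.names, "estimate": self.beta_hat, "se": self.se, "p": self.p}
        )


def summarize_scalar_sdee(curve, grid) -> float:
    """Overall (quadrature-weighted) mean of one SDEE curve."""
    curve = np.asarray(curve, dtype=float)
    if curve.size == 0:
        raise ValueError("cannot summarize an empty curve")
    if curve.shape[-1] != grid.m:
        raise ValueError(f"curve length {curve.shape[-1]} != grid m={grid.m}")
    return curve @ grid.weights / grid.weights.sum()


def build_design(study, spec: DesignSpec):
    """Build (y, X, cluster labels, names) from a StudyData per the spec.

    'mean_sdee' is computed from the curves; categorical covariates use
    the study's reference codings (boy/white/stand-biased = 1).
    """
    table = study.table
    y = table[spec.response].to_numpy(dtype=float)
    cols, names = [], []
    if spec.intercept:
        cols.append(np.ones(study.n))
        names.append("intercept")
    for name in spec.fixed:
        if name == "mean_sdee":
            cols.append(study.curves @ study.grid.weights)
        elif name in CATEGORY_CODES:
            col, positive = CATEGORY_CODES[name]
            cols.append((table[col] == positive).to_numpy(dtype=float))
        else:
            cols.append(table[name].to_numpy(dtype=float))
        names.append(name)
    X = np.column_stack(cols)
    return y, X, table[spec.cluster].to_numpy(), names


class _ClusterStats:
    """Per-cluster sufficient statistics for the profile likelihood."""

    def __init__(self, y: np.ndarray, X: np.ndarray, clusters: np.ndarray):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        clusters = np.asarray(clusters)
        order = np.argsort(clusters, kind="stable")
        c_sorted = clusters[order]
        starts = np.flatnonzero(
            np.r_[True, c_sorted[1:] != c_sorted[:-1]]
        )
        self.n, self.p = X.shape
        self.J = starts.size
        Xs, ys = X[order], y[order]
        self.sizes = np.diff(np.r_[starts, self.n]).astype(float)
        self.sx = np.add.reduceat(Xs, starts, axis=0)  # (J, p)
        self.sy = np.add.reduceat(ys, starts)  # (J,)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def profile(self, lam: float, reml: bool) -> dict:
        """Profile beta and sigma^2 at variance ratio lam >= 0."""
        c = lam / (1.0 + lam * self.sizes)  # (J,)
        A = self.XtX - self.sx.T @ (c[:, None] * self.sx)
        b = self.Xty - self.sx.T @ (c * self.sy)
        q = self.yty - float(c @ (self.sy**2))
        beta = np.linalg.solve(A, b)
        rss = max(q - float(b @ beta), 1e-300)
        logdet_v0 = float(np.sum(np.log1p(lam * self.sizes)))
        n, p = self.n, self.p
        sigma2_ml = rss / n
        ll_ml = -0.5 * (n * _LOG2PI + n * math.log(sigma2_ml) + logdet_v0 + n)
        if reml:
            sigma2 = rss / (n - p)
            sign, logdet_a = np.linalg.slogdet(A)
            ll = -0.5 * (
                (n - p) * (_LOG2PI + math.log(sigma2))
                + logdet_v0
                + logdet_a
                + (n - p)
            )
        else:
            sigma2 = sigma2_ml
            ll = ll_ml
        return {
            "lam": lam,
            "beta": beta,
            "sigma2": sigma2,
            "loglik": ll,
            "loglik_ml": ll_ml,
            "A": A,
        }


def anova_variance_components(y, clusters) -> tuple[float, float]:
    """Method-of-moments one-way ANOVA estimators (sigma2_school, sigma2_resid).

    Works on raw values or residuals; the between component is floored
    at zero.  Used as the optimizer's starting candidate and as an
    independent oracle in tests.
    """
    y = np.asarray(y, dtype=float)
    clusters = np.asarray(clusters)
    labels, inverse = np.unique(clusters, return_inverse=True)
    J = labels.size
    n = y.size
    if J < 2:
        raise ValueError("need at least 2 clusters")
    sizes = np.bincount(inverse).astype(float)
    means = np.bincount(inverse, weights=y) / sizes
    grand = y.mean()
    ssw = float(np.sum((y - means[inverse]) ** 2))
    ssb = float(np.sum(sizes * (means - grand) ** 2))
    msw = ssw / (n - J)
    msb = ssb / (J - 1)
    n0 = (n - float(np.sum(sizes**2)) / n) / (J - 1)
    sigma2_school = max((msb - msw) / n0, 0.0)
    return sigma2_school, msw


def _check_design(X: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pivoted QR flags the dependent columns by small diagonal entries
        from scipy.linalg import qr

        _, R, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(X.shape[1]) if diag[i] <= tol]
        raise ValueError(f"design matrix is singular; collinear columns: {bad}")


def fit_lmem(y, X, clusters, method: str = "ML", names=None) -> LMEMFit:
    """Fit the random-intercept LMEM by profiled (RE)ML.

    Parameters
    ----------
    y, X, clusters : response vector, fixed-effect design (including any
        intercept column), cluster labels.
    method : "ML" (default, AIC-comparable) or "REML".
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be 2-D and aligned with y")
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than fixed-effect parameters")
    names = list(names) if names is not None else [f"x{i}" for i in range(p)]
    _check_design(X, names)
    method = method.upper()
    if method not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")
    reml = method == "REML"
    stats_ = _ClusterStats(y, X, clusters)
    if stats_.J < 2:
        raise ValueError("need at least 2 clusters")

    def neg_ll(u: float) -> float:
        return -stats_.profile(math.exp(u), reml)["loglik"]

    # ANOVA-estimator start (on OLS residuals) plus the lam=0 boundary
    beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
    s2b0, s2w0 = anova_variance_components(y - X @ beta_ols, clusters)
    candidates = [0.0]
    if s2b0 > 0 and s2w0 > 0:
        candidates.append(s2b0 / s2w0)
    res = optimize.minimize_scalar(
        neg_ll,
        bounds=(-25.0, 12.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    converged = bool(res.success)
    best = stats_.profile(math.exp(res.x), reml)
    for lam in candidates:
        cand = stats_.profile(lam, reml)
        if cand["loglik"] > best["loglik"]:
            best = cand
    lam, sigma2 = best["lam"], best["sigma2"]
    # treat near-boundary solutions as lam = 0 exactly
    if lam < 1e-10:
        best = stats_.profile(0.0, reml)
        lam, sigma2 = 0.0, best["sigma2"]
    cov_beta = sigma2 * np.linalg.inv(best["A"])
    se = np.sqrt(np.diag(cov_beta))
    z = best["beta"] / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return LMEMFit(
        names=names,
        beta_hat=best["beta"],
        se=se,
        p=pvals,
        sigma2_school=lam * sigma2,
        sigma2_resid=sigma2,
        loglik=best["loglik"],
        loglik_ml=best["loglik_ml"],
        aic=2.0 * (p + 2) - 2.0 * best["loglik_ml"],
        n=n,
        n_clusters=stats_.J,
        method=method,
        converged=converged,
        cov_beta=cov_beta,
    )


def compute_icc(fit_or_sigma2_school, sigma2_resid: float | None = None) -> float:
    """Intraclass correlation sigma_school^2 / (sigma_school^2 + sigma_resid^2)."""
    if sigma2_resid is None:
        s2b = fit_or_sigma2_school.sigma2_school
        s2w = fit_or_sigma2_school.sigma2_resid
    else:
        s2b = float(fit_or_sigma2_school)
        s2w = float(sigma2_resid)
    if s2b < 0 or s2w < 0:
        raise ValueError("variance components must be nonnegative")
    total = s2b + s2w
    if total == 0:
        raise ValueError("ICC undefined when both variance components are zero")
    return s2b / total
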