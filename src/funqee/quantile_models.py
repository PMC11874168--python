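"""Linear quantile mixed-effects model built from first principles.

The working likelihood is the asymmetric Laplace (ALD) density; a
Gaussian cluster random intercept is integrated out of each cluster's
likelihood.  Because the check loss is piecewise linear in the random
intercept b, the cluster integral

    int prod_i ALD(y_i; x_i'beta + b, sigma, tau) phi(b; 0, sigma_b^2) db

is a sum of exp(linear) * Gaussian pieces between consecutive order
statistics of the residuals and therefore has an exact closed form in
terms of normal CDF differences.  That analytic marginalization is the
default likelihood path; an adaptive Gauss-Hermite route (nodes centered
and scaled at the per-cluster mode) is available for cross-checking.
The marginal log-likelihood is maximized numerically from a plain
quantile-regression warm start.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import log_ndtr, logsumexp

from ._quantile_kernels import exact_loglik_jit
from .mixed_models import fit_lmem

__all__ = [
    "QuantileLevel",
    "QMEMFit",
    "check_loss",
    "ald_loglik",
    "marginal_loglik_qmem",
    "fit_qmem",
]


def _validate_tau(tau: float) -> float:
    tau = float(tau)
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must lie strictly in (0, 1), got {tau}")
    return tau


@dataclass(frozen=True)
class QuantileLevel:
    tau: float

    def __post_init__(self) -> None:
        _validate_tau(self.tau)


@dataclass
class QMEMFit:
    tau: float
    names: list
    beta_hat: np.ndarray
    sigma_ald: float
    sigma_b: float
    loglik: float
    aic: float
    n: int
    n_clusters: int
    n_params: int
    converged: bool
    warnings: list = field(default_factory=list)
    bootstrap_se: np.ndarray | None = None
    bootstrap_p: np.ndarray | None = None

    @property
    def se(self):
        return self.bootstrap_se

    @property
    def p(self):
        return self.bootstrap_p

    def summary_frame(self) -> pd.DataFrame:
        nan = np.full(len(self.names), np.nan)
        return pd.DataFrame(
            {
                "name": self.names,
                "estimate": self.beta_hat,
                "se": self.bootstrap_se if self.bootstrap_se is not None else nan,
                "p": self.bootstrap_p if self.bootstrap_p is not None else nan,
            }
        )


def check_loss(u, tau):
    """Pinball loss rho_tau(u) = u (tau - 1[u < 0])."""
    tau = _validate_tau(tau)
    u = np.asarray(u, dtype=float)
    out = u * (tau - (u < 0))
    return float(out) if out.ndim == 0 else out


def ald_loglik(y, mu, sigma_ald, tau):
    """Asymmetric-Laplace log density, elementwise.

    log f = log(tau (1-tau) / sigma) - rho_tau((y - mu) / sigma).
    """
    tau = _validate_tau(tau)
    if sigma_ald <= 0:
        raise ValueError("sigma_ald must be positive")
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    out = math.log(tau * (1.0 - tau) / sigma_ald) - np.asarray(
        check_loss((y - mu) / sigma_ald, tau)
    )
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# piecewise-linear geometry of the cluster loss S(b) = sum_i rho((r_i-b)/sigma)
# ---------------------------------------------------------------------------


def _piecewise_terms(r_sorted: np.ndarray, tau: float, sigma_ald: float):
    """Slopes and intercepts of S(b) between consecutive order statistics.

    On the k-th interval (k residuals below b), S(b) = alpha_k + m_k b
    with m_k = (k - tau n)/sigma and alpha_k = (tau T_k - (1-tau) C_k)/sigma
    where C_k / T_k are the partial sums below/above the boundary.
    """
    n = r_sorted.size
    k = np.arange(n + 1)
    csum = np.r_[0.0, np.cumsum(r_sorted)]
    total = csum[-1]
    m = (k - tau * n) / sigma_ald
    alpha = (tau * (total - csum) - (1.0 - tau) * csum) / sigma_ald
    return m, alpha


def _log_ndtr_diff(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """log(Phi(hi) - Phi(lo)) elementwise, stable in both tails."""
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    # reflect intervals in the right tail onto the left tail
    flip = lo > 0
    lo_, hi_ = np.where(flip, -hi, lo), np.where(flip, -lo, hi)
    la, lb = log_ndtr(lo_), log_ndtr(hi_)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = la - lb
        # log(1 - e^d) for d <= 0
        log1m = np.where(d > -0.6931472, np.log(-np.expm1(d)), np.log1p(-np.exp(d)))
    out = lb + log1m
    return np.where(hi_ > lo_, out, -np.inf)


def _cluster_exact_logint(
    r_sorted: np.ndarray, tau: float, sigma_ald: float, sigma_b: float
) -> float:
    """Exact log of the ALD-product x Gaussian integral for one cluster."""
    n = r_sorted.size
    m, alpha = _piecewise_terms(r_sorted, tau, sigma_ald)
    lower = np.r_[-np.inf, r_sorted]
    upper = np.r_[r_sorted, np.inf]
    # int_L^U e^{-m b} phi(b;0,sb^2) db = e^{m^2 sb^2/2}[Phi((U+m sb^2)/sb)-Phi((L+m sb^2)/sb)]
    shift = m * sigma_b
    terms = (
        -alpha
        + 0.5 * shift**2
        + _log_ndtr_diff(lower / sigma_b + shift, upper / sigma_b + shift)
    )
    return n * math.log(tau * (1.0 - tau) / sigma_ald) + float(logsumexp(terms))


def _cluster_mode(
    r_sorted: np.ndarray, tau: float, sigma_ald: float, sigma_b: float
) -> float:
    """Minimizer of f(b) = S(b) + b^2/(2 sigma_b^2) (unique, convex)."""
    m, _ = _piecewise_terms(r_sorted, tau, sigma_ald)
    cand = -m * sigma_b**2  # stationary point on each interval
    lower = np.r_[-np.inf, r_sorted]
    upper = np.r_[r_sorted, np.inf]
    inside = (cand >= lower) & (cand <= upper)
    if inside.any():
        return float(cand[np.argmax(inside)])
    # derivative changes sign at a knot
    grads = r_sorted / sigma_b**2 + m[:-1]
    idx = np.flatnonzero(grads >= 0)
    return float(r_sorted[idx[0]] if idx.size else r_sorted[-1])


def _cluster_ghq_logint(
    r_sorted: np.ndarray,
    tau: float,
    sigma_ald: float,
    sigma_b: float,
    nodes: np.ndarray,
    logw: np.ndarray,
) -> float:
    """Gauss-Hermite version of the cluster integral.

    Nodes are centered at the per-cluster mode and scaled by the local
    width of exp(-f) (adaptive GHQ); with the substitution
    b = b0 + sqrt(2) s x the integral becomes
    sqrt(2) s sum_i w_i exp(g(b0 + sqrt(2) s x_i) + x_i^2) / sqrt(pi) * sqrt(pi)
    evaluated in the log domain.
    """
    n = r_sorted.size
    b0 = _cluster_mode(r_sorted, tau, sigma_ald, sigma_b)
    # local curvature proxy: Gaussian part plus kink density near the mode
    width = 1.0 / sigma_b**2
    window = 3.0 * sigma_b
    nearby = np.sum(np.abs(r_sorted - b0) <= window)
    if nearby > 1:
        width += (nearby / sigma_ald) / (2.0 * window)
    s = 1.0 / math.sqrt(width)
    b = b0 + math.sqrt(2.0) * s * nodes
    loss = check_loss((r_sorted[:, None] - b[None, :]) / sigma_ald, tau).sum(axis=0)
    log_g = (
        n * math.log(tau * (1.0 - tau) / sigma_ald)
        - loss
        - 0.5 * (b / sigma_b) ** 2
        - math.log(sigma_b)
        - 0.5 * math.log(2.0 * math.pi)
    )
    return float(
        logsumexp(log_g + nodes**2 + logw) + 0.5 * math.log(2.0) + math.log(s)
    )


class _ClusterIndex:
    """Cluster codes plus fixed segment/interval bookkeeping.

    Interval rows enumerate, for every cluster j, the n_j + 1 intervals
    between consecutive within-cluster order statistics; their layout
    depends only on the cluster sizes, so it is precomputed once.
    """

    def __init__(self, clusters: np.ndarray):
        clusters = np.asarray(clusters)
        _, codes = np.unique(clusters, return_inverse=True)
        self.codes = codes
        self.J = int(codes.max()) + 1
        order = np.argsort(codes, kind="stable")
        self.order_by_code = order
        sorted_codes = codes[order]
        starts = np.flatnonzero(np.r_[True, sorted_codes[1:] != sorted_codes[:-1]])
        self.bounds = np.r_[starts, codes.size]
        self.sizes = np.diff(self.bounds)
        # interval-row structures (total length n + J)
        self.row_starts = np.r_[0, np.cumsum(self.sizes + 1)][:-1]
        self.kloc = np.arange((self.sizes + 1).sum()) - np.repeat(
            self.row_starts, self.sizes + 1
        )
        self.sizes_rep = np.repeat(self.sizes, self.sizes + 1)
        self.seg_start_rep = np.repeat(self.bounds[:-1], self.sizes + 1)

    def sorted_segments(self, values: np.ndarray) -> np.ndarray:
        """Values ordered by (cluster, value)."""
        return values[np.lexsort((values, self.codes))]

    def segments(self, values: np.ndarray):
        v = self.sorted_segments(values)
        for j in range(self.J):
            yield v[self.bounds[j] : self.bounds[j + 1]]


def _exact_loglik_all(
    resid: np.ndarray, index: _ClusterIndex, tau: float,
    sigma_ald: float, sigma_b: float,
) -> float:
    """Vectorized closed-form marginal log-likelihood over all clusters."""
    r = index.sorted_segments(resid)
    n = r.size
    cs = np.r_[0.0, np.cumsum(r)]
    pos = index.seg_start_rep + index.kloc
    base = cs[index.seg_start_rep]
    Ck = cs[pos] - base
    total_seg = cs[index.seg_start_rep + index.sizes_rep] - base
    m = (index.kloc - tau * index.sizes_rep) / sigma_ald
    alpha = (tau * (total_seg - Ck) - (1.0 - tau) * Ck) / sigma_ald
    lower = np.where(index.kloc == 0, -np.inf, r[np.maximum(pos - 1, 0)])
    upper = np.where(
        index.kloc == index.sizes_rep, np.inf, r[np.minimum(pos, n - 1)]
    )
    shift = m * sigma_b
    with np.errstate(over="ignore"):
        terms = (
            -alpha
            + 0.5 * shift**2
            + _log_ndtr_diff(lower / sigma_b + shift, upper / sigma_b + shift)
        )
        mx = np.maximum.reduceat(terms, index.row_starts)
        mx_rep = np.repeat(mx, index.sizes + 1)
        sums = np.add.reduceat(np.exp(terms - mx_rep), index.row_starts)
    return n * math.log(tau * (1.0 - tau) / sigma_ald) + float(
        np.sum(mx + np.log(sums))
    )


def _marginal_loglik(
    y, X, index: _ClusterIndex, beta, sigma_ald, sigma_b, tau,
    method: str = "exact", nodes=None, logw=None,
) -> float:
    resid = y - X @ beta
    if sigma_b < 1e-8:
        return float(np.sum(ald_loglik(resid, 0.0, sigma_ald, tau)))
    if method == "exact":
        if exact_loglik_jit is not None:
            return float(
                exact_loglik_jit(
                    resid[index.order_by_code], index.bounds, tau,
                    float(sigma_ald), float(sigma_b),
                )
            )
        return _exact_loglik_all(resid, index, tau, sigma_ald, sigma_b)
    total = 0.0
    for r_sorted in index.segments(resid):
        total += _cluster_ghq_logint(r_sorted, tau, sigma_ald, sigma_b, nodes, logw)
    return total


def marginal_loglik_qmem(
    params, y, X, clusters, tau, n_nodes: int = 11, method: str = "exact"
) -> float:
    """Marginal log-likelihood at params = (beta..., sigma_ald, sigma_b).

    Each cluster contributes log int prod_i ALD(y_i; x_i'beta + b) phi(b;
    0, sigma_b^2) db.  ``method='exact'`` (default) uses the closed-form
    piecewise-Gaussian marginalization; ``method='ghq'`` uses adaptive
    n_nodes-point Gauss-Hermite quadrature.
    """
    tau = _validate_tau(tau)
    if n_nodes < 5 or n_nodes % 2 == 0:
        raise ValueError("n_nodes must be an odd integer >= 5")
    if method not in ("exact", "ghq"):
        raise ValueError("method must be 'exact' or 'ghq'")
    params = np.asarray(params, dtype=float)
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    beta, sigma_ald, sigma_b = params[:p], params[p], params[p + 1]
    if sigma_ald <= 0:
        raise ValueError("sigma_ald must be positive")
    if sigma_b < 0:
        raise ValueError("sigma_b must be nonnegative")
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    logw = np.log(weights)
    index = _ClusterIndex(clusters)
    return _marginal_loglik(
        np.asarray(y, float), X, index, beta, sigma_ald, sigma_b, tau,
        method=method, nodes=nodes, logw=logw,
    )


def _weighted_quantile(y: np.ndarray, tau: float) -> float:
    s = np.sort(y)
    k = int(math.ceil(tau * y.size)) - 1
    return float(s[min(max(k, 0), y.size - 1)])


def _warm_start_beta(y, X, tau) -> np.ndarray:
    if X.shape[1] == 1 and np.allclose(X[:, 0], X[0, 0]) and X[0, 0] != 0:
        return np.array([_weighted_quantile(y, tau) / X[0, 0]])
    try:
        from statsmodels.regression.quantile_regression import QuantReg

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return np.asarray(QuantReg(y, X).fit(q=tau).params, dtype=float)
    except Exception:
        return np.linalg.lstsq(X, y, rcond=None)[0]


def fit_qmem(
    y,
    X,
    clusters,
    tau,
    n_nodes: int = 11,
    fix_sigma_b: float | None = None,
    start: tuple | None = None,
    maxfev: int | None = None,
    fatol: float = 1e-8,
    xatol: float = 1e-8,
    names=None,
    method: str = "exact",
) -> QMEMFit:
    """Maximize the marginal ALD likelihood at quantile tau.

    ``fix_sigma_b`` pins the random-intercept scale (0 gives independent
    ALD regression).  ``start`` = (beta, sigma_ald, sigma_b) overrides the
    quantile-regression/LMEM warm start — useful for bootstrap refits.
    The search is Nelder-Mead on (beta, log sigma_ald[, log sigma_b]).
    """
    tau = _validate_tau(tau)
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than fixed-effect parameters")
    names = list(names) if names is not None else [f"x{i}" for i in range(p)]
    warn_list: list[str] = []
    if n * min(tau, 1.0 - tau) < 5:
        warn_list.append(
            f"tail guard: n*min(tau,1-tau)={n * min(tau, 1 - tau):.1f} < 5; "
            f"tau={tau} estimates may be unstable at n={n}"
        )
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    logw = np.log(weights)
    index = _ClusterIndex(clusters)

    if start is not None:
        beta0, sigma_ald0, sigma_b0 = start
        beta0 = np.asarray(beta0, dtype=float)
    else:
        beta0 = _warm_start_beta(y, X, tau)
        sigma_ald0 = max(float(np.mean(check_loss(y - X @ beta0, tau))), 1e-6)
        if fix_sigma_b is None:
            try:
                lmem = fit_lmem(y, X, clusters, method="ML", names=names)
                sigma_b0 = max(math.sqrt(lmem.sigma2_school), 1e-3)
            except Exception:
                sigma_b0 = 1e-2
        else:
            sigma_b0 = fix_sigma_b

    free_sigma_b = fix_sigma_b is None

    def unpack(theta):
        beta = theta[:p]
        sigma_ald = math.exp(min(theta[p], 50.0))
        sigma_b = math.exp(min(theta[p + 1], 50.0)) if free_sigma_b else float(fix_sigma_b)
        return beta, sigma_ald, sigma_b

    def neg_ll(theta):
        beta, sigma_ald, sigma_b = unpack(theta)
        return -_marginal_loglik(
            y, X, index, beta, sigma_ald, sigma_b, tau,
            method=method, nodes=nodes, logw=logw,
        )

    theta0 = np.r_[beta0, math.log(max(sigma_ald0, 1e-10))]
    if free_sigma_b:
        theta0 = np.r_[theta0, math.log(max(sigma_b0, 1e-6))]
    if maxfev is None:
        maxfev = 5000
    res = optimize.minimize(
        neg_ll,
        theta0,
        method="Nelder-Mead",
        options={
            "maxfev": maxfev,
            "fatol": fatol,
            "xatol": xatol,
            "adaptive": len(theta0) > 6,
        },
    )
    # a capped search that still improved on a good warm start is usable;
    # only label it non-converged if it failed to move the objective at all
    improved = res.fun <= neg_ll(theta0) + 1e-12
    beta_hat, sigma_ald, sigma_b = unpack(res.x)
    loglik = -float(res.fun)
    n_params = p + 1 + (1 if free_sigma_b else 0)
    converged = bool(res.success) or (start is not None and improved)
    if not converged:
        warn_list.append(f"optimizer did not converge: {res.message}")
    return QMEMFit(
        tau=tau,
        names=names,
        beta_hat=np.asarray(beta_hat, dtype=float),
        sigma_ald=sigma_ald,
        sigma_b=sigma_b,
        loglik=loglik,
        aic=2.0 * n_params - 2.0 * loglik,
        n=n,
        n_clusters=index.J,
        n_params=n_params,
        converged=converged,
        warnings=warn_list,
    )
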