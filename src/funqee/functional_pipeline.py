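"""Functional mean and quantile mixed-effects pipelines.

Composes B-spline scoring of the SDEE curves with the LMEM / QMEM
engines, selects the basis dimension G by AIC, and provides the
subject-level bootstrap for pointwise coefficient-curve bands and
covariate standard errors / p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fda_basis import (
    BasisSet,
    FunctionalCoefficient,
    build_bspline_basis,
    reconstruct_beta,
    score_functional_covariate,
)
from .mixed_models import CATEGORY_CODES, fit_lmem
from .quantile_models import fit_qmem
from .synthetic_data import StudyData

__all__ = [
    "FunctionalFit",
    "BootstrapBand",
    "fit_fmem",
    "fit_fqmem",
    "select_G_by_aic",
    "bootstrap_functional_inference",
    "bootstrap_scalar_inference",
    "significant_windows",
]

DEFAULT_COVARIATES = ("age", "sex", "race", "desk")


def functional_design(study: StudyData, basis: BasisSet, covariates):
    """[1 | scores Z_1..Z_G | covariates] design with names."""
    scores = score_functional_covariate(study.curves, study.grid, basis).values
    table = study.table
    cols = [np.ones(study.n), scores]
    names = ["intercept"] + [f"gamma{g + 1}" for g in range(basis.G)]
    for name in covariates:
        if name in CATEGORY_CODES:
            col, positive = CATEGORY_CODES[name]
            cols.append((table[col] == positive).to_numpy(dtype=float)[:, None])
        else:
            cols.append(table[name].to_numpy(dtype=float)[:, None])
        names.append(name)
    X = np.hstack([np.atleast_2d(c.T).T if c.ndim == 1 else c for c in cols])
    y = table["log_bmi"].to_numpy(dtype=float)
    return y, X, table["school_id"].to_numpy(), names


@dataclass
class FunctionalFit:
    """An FMEM or FQMEM fit: engine fit + reconstructed coefficient curve."""

    engine_fit: object  # LMEMFit or QMEMFit
    basis: BasisSet
    gamma_hat: np.ndarray
    beta_curve: FunctionalCoefficient
    names: list
    covariate_names: list
    tau: float | None = None

    @property
    def params(self) -> np.ndarray:
        return self.engine_fit.beta_hat

    @property
    def aic(self) -> float:
        return self.engine_fit.aic

    @property
    def converged(self) -> bool:
        return self.engine_fit.converged


def _make_functional_fit(engine_fit, basis, study, names, covariates, tau=None):
    gamma = engine_fit.beta_hat[1 : 1 + basis.G]
    curve = reconstruct_beta(gamma, basis, study.grid.points)
    return FunctionalFit(
        engine_fit=engine_fit,
        basis=basis,
        gamma_hat=gamma,
        beta_curve=curve,
        names=names,
        covariate_names=list(covariates),
        tau=tau,
    )


def fit_fmem(
    study: StudyData,
    G: int,
    degree: int = 3,
    covariates=DEFAULT_COVARIATES,
    method: str = "ML",
) -> FunctionalFit:
    """Scalar-on-function Gaussian mixed model via integrated spline scores."""
    basis = build_bspline_basis(G, degree)
    y, X, clusters, names = functional_design(study, basis, covariates)
    fit = fit_lmem(y, X, clusters, method=method, names=names)
    return _make_functional_fit(fit, basis, study, names, covariates)


def fit_fqmem(
    study: StudyData,
    tau: float,
    G: int,
    degree: int = 3,
    covariates=DEFAULT_COVARIATES,
    start=None,
    maxfev: int | None = None,
    **qmem_options,
) -> FunctionalFit:
    """Scalar-on-function quantile mixed model at level tau."""
    basis = build_bspline_basis(G, degree)
    y, X, clusters, names = functional_design(study, basis, covariates)
    fit = fit_qmem(
        y, X, clusters, tau, names=names, start=start, maxfev=maxfev, **qmem_options
    )
    return _make_functional_fit(fit, basis, study, names, covariates, tau=tau)


def select_G_by_aic(
    study: StudyData,
    model_kind: str = "FMEM",
    G_range=(4, 5, 6, 7),
    tau: float | None = None,
    degree: int = 3,
    covariates=DEFAULT_COVARIATES,
    **fit_options,
):
    """Fit every candidate G and return (best_G, aic_table, best_fit).

    Ties break toward smaller G; duplicate candidates are fitted once.
    Individual failures are recorded and skipped; if every candidate
    fails the selection is rejected.
    """
    kind = model_kind.upper()
    if kind not in ("FMEM", "FQMEM"):
        raise ValueError("model_kind must be 'FMEM' or 'FQMEM'")
    if kind == "FQMEM" and tau is None:
        raise ValueError("FQMEM selection requires tau")
    candidates = sorted(set(int(g) for g in G_range))
    if not candidates:
        raise ValueError("G_range must be nonempty")
    rows, fits = [], {}
    for G in candidates:
        try:
            if kind == "FMEM":
                fit = fit_fmem(study, G, degree=degree, covariates=covariates, **fit_options)
            else:
                fit = fit_fqmem(
                    study, tau, G, degree=degree, covariates=covariates, **fit_options
                )
            fits[G] = fit
            rows.append({"G": G, "aic": fit.aic, "status": "ok"})
        except Exception as exc:  # noqa: BLE001 - selection proceeds over the rest
            rows.append({"G": G, "aic": np.nan, "status": f"failed: {exc}"})
    table = pd.DataFrame(rows)
    if not fits:
        raise RuntimeError(f"all candidate G failed: {table['status'].tolist()}")
    ok = table[table["status"] == "ok"]
    best_g = int(ok.sort_values(["aic", "G"], kind="stable").iloc[0]["G"])
    return best_g, table, fits[best_g]


@dataclass
class BootstrapBand:
    """Pointwise percentile band for a coefficient curve plus covariate SEs."""

    points: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    B: int
    n_used: int
    n_failed: int
    param_names: list
    param_estimates: np.ndarray
    param_se: np.ndarray
    param_p: np.ndarray
    replicate_curves: np.ndarray = field(repr=False, default=None)
    replicate_params: np.ndarray = field(repr=False, default=None)
    warnings: list = field(default_factory=list)

    @property
    def excludes_zero(self) -> np.ndarray:
        return (self.lower > 0) | (self.upper < 0)

    def band_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.points,
                "estimate": self.estimate,
                "lower": self.lower,
                "upper": self.upper,
                "excludes_zero": self.excludes_zero,
            }
        )


def stratified_resample_indices(
    clusters: np.ndarray, rng: np.random.Generator, scheme: str = "nonparametric"
) -> np.ndarray:
    """Subject indices resampled within each cluster (sizes preserved).

    'nonparametric' samples with replacement; 'permutation' draws the
    same subjects in shuffled order (reproducing the original data, kept
    for comparison with the resample-without-replacement reading).
    """
    if scheme not in ("nonparametric", "permutation"):
        raise ValueError("resample scheme must be 'nonparametric' or 'permutation'")
    clusters = np.asarray(clusters)
    out = []
    for label in pd.unique(clusters):
        idx = np.flatnonzero(clusters == label)
        if scheme == "nonparametric":
            out.append(rng.choice(idx, size=idx.size, replace=True))
        else:
            out.append(rng.permutation(idx))
    return np.concatenate(out)


def _run_bootstrap(study, fitter, B, rng, scheme, collect_curve):
    clusters = study.table["school_id"].to_numpy()
    curves, params = [], []
    n_failed = 0
    for _ in range(B):
        idx = stratified_resample_indices(clusters, rng, scheme)
        try:
            fit = fitter(study.subset(idx))
        except Exception:  # noqa: BLE001 - failed replicates are dropped and counted
            n_failed += 1
            continue
        if not getattr(fit, "converged", True):
            n_failed += 1
            continue
        params.append(np.asarray(fit.params if collect_curve else fit.beta_hat))
        if collect_curve:
            curves.append(fit.beta_curve.values)
    return (
        np.array(curves) if collect_curve else None,
        np.array(params),
        n_failed,
    )


def _se_p(full_params: np.ndarray, replicate_params: np.ndarray):
    se = replicate_params.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, full_params / se, np.inf * np.sign(full_params))
    p = 2.0 * stats.norm.sf(np.abs(z))
    return se, p


def bootstrap_functional_inference(
    study: StudyData,
    fitter,
    B: int = 1000,
    level: float = 0.95,
    resample_scheme: str = "nonparametric",
    rng: np.random.Generator | None = None,
) -> BootstrapBand:
    """Pointwise percentile band for the coefficient curve of ``fitter``.

    ``fitter`` maps a StudyData to a FunctionalFit and must be
    deterministic.  Subjects are resampled with replacement within each
    school (cluster sizes preserved); non-converged replicates are
    dropped and counted, and >10% failures raises a recorded warning.
    """
    if B < 50:
        raise ValueError("B must be at least 50")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    full = fitter(study)
    curves, params, n_failed = _run_bootstrap(
        study, fitter, B, rng, resample_scheme, collect_curve=True
    )
    warns = []
    if n_failed > 0.1 * B:
        warns.append(f"{n_failed}/{B} bootstrap replicates failed or did not converge")
    alpha = (1.0 - level) / 2.0
    lower = np.percentile(curves, 100.0 * alpha, axis=0)
    upper = np.percentile(curves, 100.0 * (1.0 - alpha), axis=0)
    se, p = _se_p(full.params, params)
    return BootstrapBand(
        points=study.grid.points,
        estimate=full.beta_curve.values,
        lower=lower,
        upper=upper,
        level=level,
        B=B,
        n_used=params.shape[0],
        n_failed=n_failed,
        param_names=list(full.names),
        param_estimates=full.params,
        param_se=se,
        param_p=p,
        replicate_curves=curves,
        replicate_params=params,
        warnings=warns,
    )


def bootstrap_scalar_inference(
    study: StudyData,
    fitter,
    B: int = 1000,
    resample_scheme: str = "nonparametric",
    rng: np.random.Generator | None = None,
):
    """Bootstrap SEs and normal-approximation p-values for a scalar fit.

    ``fitter`` maps a StudyData to an object with ``beta_hat``/``names``
    (LMEMFit or QMEMFit).  Returns (se, p, n_failed).
    """
    if B < 50:
        raise ValueError("B must be at least 50")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    full = fitter(study)
    _, params, n_failed = _run_bootstrap(
        study, fitter, B, rng, resample_scheme, collect_curve=False
    )
    se, p = _se_p(np.asarray(full.beta_hat), params)
    return se, p, n_failed


def significant_windows(band: BootstrapBand) -> list[tuple[float, float]]:
    """Maximal runs of consecutive grid points whose band excludes zero."""
    mask = band.excludes_zero
    windows = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            windows.append((float(band.points[start]), float(band.points[i - 1])))
            start = None
    if start is not None:
        windows.append((float(band.points[start]), float(band.points[len(mask) - 1])))
    return windows
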