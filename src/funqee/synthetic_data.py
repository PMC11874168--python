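"""Synthetic study generator.

Emulates a cluster-randomized stand-biased-desk study: n subjects in a
small number of school clusters, each carrying a curve of hourly mean
school-day energy expenditure (SDEE, cal/min) on a common grid
reparameterized to (0, 1], scalar covariates, and a log(BMI) outcome
generated from a scalar-on-function mixed model with a school random
intercept.  Every generator is driven by a single ``numpy`` Generator so
that a seed fully determines the dataset.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TimeGrid",
    "SubjectRecord",
    "StudyData",
    "CurveModel",
    "SimulationTruth",
    "default_truth",
    "simulate_covariates",
    "simulate_curves",
    "simulate_outcome",
    "simulate_study",
]

SEX_LEVELS = ("boy", "girl")
RACE_LEVELS = ("white", "non-white")
DESK_LEVELS = ("stand-biased", "traditional")

#: Table-1-style population targets used for default calibration.
DEFAULT_P_BOY = 133 / 256
DEFAULT_P_WHITE = 176 / 256
DEFAULT_P_STAND = 150 / 256
DEFAULT_AGE_MEAN = 7.86
DEFAULT_AGE_SD = 0.80
DEFAULT_BMI_MEAN = 17.40
DEFAULT_BMI_SD = 2.98
DEFAULT_MEAN_SDEE = 1.32
DEFAULT_SD_SDEE = 0.32


@dataclass(frozen=True)
class TimeGrid:
    """Common observation grid on (0, 1] with quadrature weights.

    The default convention is the right-endpoint rule for m hourly means:
    t_k = k/m with weight 1/m each (each hourly mean represents a
    width-1/m interval of the unit-rescaled wear time).
    """

    points: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        points = np.asarray(self.points, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "points", points)
        object.__setattr__(self, "weights", weights)
        if points.ndim != 1 or weights.shape != points.shape:
            raise ValueError("points and weights must be 1-D and aligned")
        if not np.all(np.diff(points) > 0):
            raise ValueError("grid points must be strictly increasing")
        if points[0] <= 0 or points[-1] > 1 + 1e-12:
            raise ValueError("grid points must lie in (0, 1]")
        if np.any(weights <= 0):
            raise ValueError("quadrature weights must be positive")
        if abs(weights.sum() - 1.0) > 1e-12:
            raise ValueError("quadrature weights must sum to 1")

    @property
    def m(self) -> int:
        return self.points.size

    @classmethod
    def hourly(cls, m: int = 30) -> "TimeGrid":
        """Rectangle-rule grid t_k = k/m, weights 1/m."""
        k = np.arange(1, m + 1)
        return cls(points=k / m, weights=np.full(m, 1.0 / m))


@dataclass
class SubjectRecord:
    """One student's data: cluster id, covariates, SDEE curve, outcome."""

    subject_id: str
    school_id: str
    age: float
    sex: str
    race: str
    desk: str
    curve: np.ndarray
    bmi: float
    log_bmi: float

    def __post_init__(self) -> None:
        self.curve = np.asarray(self.curve, dtype=float)
        if self.bmi <= 0:
            raise ValueError(f"bmi must be positive, got {self.bmi}")
        if abs(self.log_bmi - math.log(self.bmi)) > 1e-12:
            raise ValueError("log_bmi is not ln(bmi)")
        if self.sex not in SEX_LEVELS:
            raise ValueError(f"unknown sex level {self.sex!r}")
        if self.race not in RACE_LEVELS:
            raise ValueError(f"unknown race level {self.race!r}")
        if self.desk not in DESK_LEVELS:
            raise ValueError(f"unknown desk level {self.desk!r}")


@dataclass
class StudyData:
    """A full study: covariate table plus the curve matrix on one grid.

    ``table`` columns: subject_id, school_id, age, sex, race, desk, bmi,
    log_bmi.  ``curves`` is n x m aligned with the table rows.
    """

    grid: TimeGrid
    table: pd.DataFrame
    curves: np.ndarray
    metadata: dict = field(default_factory=dict)
    validate: dataclasses.InitVar[bool] = True

    def __post_init__(self, validate: bool) -> None:
        self.curves = np.asarray(self.curves, dtype=float)
        if self.curves.ndim != 2 or self.curves.shape != (len(self.table), self.grid.m):
            raise ValueError(
                f"curves must be (n, m) = ({len(self.table)}, {self.grid.m}), "
                f"got {self.curves.shape}"
            )
        if validate:
            if self.table["school_id"].nunique() < 2:
                raise ValueError("study must contain at least 2 distinct schools")
            if (self.table["bmi"] <= 0).any():
                raise ValueError("bmi must be positive for every subject")
            if not np.allclose(
                self.table["log_bmi"], np.log(self.table["bmi"]), atol=1e-12
            ):
                raise ValueError("log_bmi column is not ln(bmi)")

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def subjects(self) -> list[SubjectRecord]:
        records = []
        for i, row in enumerate(self.table.itertuples(index=False)):
            records.append(
                SubjectRecord(
                    subject_id=row.subject_id,
                    school_id=row.school_id,
                    age=row.age,
                    sex=row.sex,
                    race=row.race,
                    desk=row.desk,
                    curve=self.curves[i],
                    bmi=row.bmi,
                    log_bmi=row.log_bmi,
                )
            )
        return records

    def content_hash(self) -> str:
        """Deterministic digest of grid, table and curves."""
        h = hashlib.sha256()
        h.update(self.grid.points.tobytes())
        h.update(self.grid.weights.tobytes())
        h.update(self.table.to_csv(index=False).encode())
        h.update(np.ascontiguousarray(self.curves).tobytes())
        return h.hexdigest()

    def subset(self, indices: np.ndarray) -> "StudyData":
        """Row subset/resample (used by the bootstrap); keeps the grid."""
        table = self.table.iloc[indices].reset_index(drop=True)
        return StudyData(
            grid=self.grid,
            table=table,
            curves=self.curves[indices],
            metadata=dict(self.metadata),
            validate=False,
        )


@dataclass
class CurveModel:
    """Parameters of the SDEE curve generator.

    Curves are A_i * mu(t) + e_ik with a smooth bimodal diurnal template
    mu(t) scaled so its grid mean is ``mean_sdee``, a lognormal subject
    amplitude A_i with mean 1, and Gaussian hourly noise; values are
    floored at ``floor`` cal/min.  ``amp_sd`` defaults so the per-subject
    overall mean SDEE has population sd ``sd_sdee``.
    """

    mean_sdee: float = DEFAULT_MEAN_SDEE
    sd_sdee: float = DEFAULT_SD_SDEE
    noise_sd: float = 0.25
    amp_sd: float | None = None
    floor: float = 0.05
    bump1: tuple[float, float, float] = (1.00, 0.25, 0.12)  # height, center, width
    bump2: tuple[float, float, float] = (0.85, 0.70, 0.15)
    baseline: float = 0.55

    def shape(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        h1, c1, w1 = self.bump1
        h2, c2, w2 = self.bump2
        return (
            self.baseline
            + h1 * np.exp(-(((t - c1) / w1) ** 2))
            + h2 * np.exp(-(((t - c2) / w2) ** 2))
        )

    def template(self, grid: TimeGrid) -> np.ndarray:
        """Template scaled so the quadrature mean over the grid is mean_sdee."""
        raw = self.shape(grid.points)
        return raw * (self.mean_sdee / float(grid.weights @ raw))

    def resolved_amp_sd(self, grid: TimeGrid) -> float:
        if self.amp_sd is not None:
            return self.amp_sd
        noise_var = self.noise_sd**2 * float(grid.weights @ grid.weights)
        amp_var = max(self.sd_sdee**2 - noise_var, 0.0)
        return math.sqrt(amp_var) / self.mean_sdee


def _as_beta_values(beta_fun, grid: TimeGrid) -> np.ndarray:
    """Evaluate a functional coefficient spec (scalar/array/callable) on the grid."""
    if callable(beta_fun):
        return np.asarray(beta_fun(grid.points), dtype=float)
    arr = np.asarray(beta_fun, dtype=float)
    if arr.ndim == 0:
        return np.full(grid.m, float(arr))
    if arr.shape != (grid.m,):
        raise ValueError(f"beta_fun array must have length m={grid.m}")
    return arr


@dataclass
class SimulationTruth:
    """Complete ground truth for one simulated study.

    ``sigma2_school``/``sigma2_resid``/``beta0`` left as None are
    calibrated at resolution time so that log(BMI) hits the configured
    BMI mean/sd targets with the configured ICC.
    """

    n: int = 256
    n_schools: int = 3
    m: int = 30
    beta0: float | None = None
    beta_age: float = -0.002
    beta_sex: float = -0.045  # boy vs girl
    beta_race: float = -0.017  # white vs non-white
    beta_desk: float = -0.049  # stand-biased vs traditional
    beta_fun: object = 0.366  # scalar, length-m array, or callable of t
    sigma2_school: float | None = None
    sigma2_resid: float | None = None
    icc: float = 0.10
    curve_model: CurveModel = field(default_factory=CurveModel)
    p_boy: float = DEFAULT_P_BOY
    p_white: float = DEFAULT_P_WHITE
    p_stand: float = DEFAULT_P_STAND
    age_mean: float = DEFAULT_AGE_MEAN
    age_sd: float = DEFAULT_AGE_SD
    bmi_mean: float = DEFAULT_BMI_MEAN
    bmi_sd: float = DEFAULT_BMI_SD
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_boy", "p_white", "p_stand"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"proportion {name}={p} must lie in [0, 1]")
        for name in ("sigma2_school", "sigma2_resid"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.icc < 1.0:
            raise ValueError("icc must lie in [0, 1)")
        if self.n < self.n_schools or self.n_schools < 1:
            raise ValueError("need n >= n_schools >= 1")

    @property
    def proportions(self) -> dict:
        return {"boy": self.p_boy, "white": self.p_white, "stand": self.p_stand}

    @property
    def age_mean_sd(self) -> tuple[float, float]:
        return (self.age_mean, self.age_sd)

    def grid(self) -> TimeGrid:
        return TimeGrid.hourly(self.m)

    def beta_fun_values(self, grid: TimeGrid) -> np.ndarray:
        return _as_beta_values(self.beta_fun, grid)

    def resolve(self) -> "SimulationTruth":
        """Fill calibrated defaults for beta0 and the variance components.

        Target moments: log(BMI) is approximately Gaussian with variance
        v = log(1 + (bmi_sd/bmi_mean)^2) and mean log(bmi_mean) - v/2, so
        exp(log_bmi) has mean/sd near the BMI targets.  The variance
        explained by covariates and the functional term is subtracted,
        and the remainder is split by the ICC.
        """
        if (
            self.beta0 is not None
            and self.sigma2_school is not None
            and self.sigma2_resid is not None
        ):
            return self
        grid = self.grid()
        beta_vals = self.beta_fun_values(grid)
        template = self.curve_model.template(grid)
        amp_sd = self.curve_model.resolved_amp_sd(grid)
        # functional term F_i = A_i * (w . beta*mu) + sum_k w_k beta_k e_ik
        fun_mean = float(grid.weights @ (beta_vals * template))
        fun_var = (fun_mean * amp_sd) ** 2 + self.curve_model.noise_sd**2 * float(
            (grid.weights * beta_vals) @ (grid.weights * beta_vals)
        )
        cov_mean = (
            self.beta_age * self.age_mean
            + self.beta_sex * self.p_boy
            + self.beta_race * self.p_white
            + self.beta_desk * self.p_stand
        )
        cov_var = (
            (self.beta_age * self.age_sd) ** 2
            + self.beta_sex**2 * self.p_boy * (1 - self.p_boy)
            + self.beta_race**2 * self.p_white * (1 - self.p_white)
            + self.beta_desk**2 * self.p_stand * (1 - self.p_stand)
        )
        target_var = math.log(1.0 + (self.bmi_sd / self.bmi_mean) ** 2)
        target_mean = math.log(self.bmi_mean) - target_var / 2.0
        resid_total = max(target_var - fun_var - cov_var, 1e-6)
        sigma2_school = self.sigma2_school
        sigma2_resid = self.sigma2_resid
        if sigma2_school is None and sigma2_resid is None:
            sigma2_school = self.icc * resid_total
            sigma2_resid = (1.0 - self.icc) * resid_total
        elif sigma2_school is None:
            sigma2_school = self.icc / (1.0 - self.icc) * sigma2_resid
        elif sigma2_resid is None:
            sigma2_resid = sigma2_school * (1.0 - self.icc) / max(self.icc, 1e-12)
        beta0 = self.beta0
        if beta0 is None:
            beta0 = target_mean - fun_mean - cov_mean
        return dataclasses.replace(
            self,
            beta0=beta0,
            sigma2_school=sigma2_school,
            sigma2_resid=sigma2_resid,
        )

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        if callable(self.beta_fun):
            d["beta_fun"] = list(self.beta_fun_values(self.grid()))
        elif isinstance(self.beta_fun, np.ndarray):
            d["beta_fun"] = list(map(float, self.beta_fun))
        return json.loads(json.dumps(d, default=float))


def default_truth(**overrides) -> SimulationTruth:
    """Fully-resolved default truth mirroring the study's descriptives."""
    return SimulationTruth(**overrides).resolve()


def _validate_proportions(proportions: dict) -> dict:
    required = ("boy", "white", "stand")
    for key in required:
        if key not in proportions:
            raise ValueError(f"proportions missing field {key!r}")
        p = proportions[key]
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"proportion {key}={p} must lie in [0, 1]")
    return proportions


def simulate_covariates(
    n: int,
    proportions: dict,
    age_mean_sd: tuple[float, float],
    n_schools: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw subject covariates and balanced school assignments.

    Schools are assigned round-robin over a shuffled subject order, so
    cluster sizes differ by at most one.
    """
    if not (n >= n_schools >= 1):
        raise ValueError("need n >= n_schools >= 1")
    proportions = _validate_proportions(proportions)
    age_mean, age_sd = age_mean_sd
    order = rng.permutation(n)
    school_idx = np.empty(n, dtype=int)
    school_idx[order] = np.arange(n) % n_schools
    sex = np.where(rng.random(n) < proportions["boy"], "boy", "girl")
    race = np.where(rng.random(n) < proportions["white"], "white", "non-white")
    desk = np.where(
        rng.random(n) < proportions["stand"], "stand-biased", "traditional"
    )
    age = rng.normal(age_mean, age_sd, size=n)
    width = len(str(n))
    return pd.DataFrame(
        {
            "subject_id": [f"s{i + 1:0{width}d}" for i in range(n)],
            "school_id": [f"sch{j + 1}" for j in school_idx],
            "age": age,
            "sex": sex,
            "race": race,
            "desk": desk,
        }
    )


def simulate_curves(
    n: int,
    grid: TimeGrid,
    curve_model: CurveModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw n nonnegative SDEE curves on the grid (n x m array)."""
    template = curve_model.template(grid)
    amp_sd = curve_model.resolved_amp_sd(grid)
    if amp_sd > 0:
        s2 = math.log1p(amp_sd**2)
        amps = rng.lognormal(mean=-s2 / 2.0, sigma=math.sqrt(s2), size=n)
    else:
        amps = np.ones(n)
    curves = amps[:, None] * template[None, :]
    if curve_model.noise_sd > 0:
        curves = curves + rng.normal(0.0, curve_model.noise_sd, size=(n, grid.m))
    return np.maximum(curves, curve_model.floor)


def simulate_outcome(
    covariates: pd.DataFrame,
    curves: np.ndarray,
    grid: TimeGrid,
    truth: SimulationTruth,
    rng: np.random.Generator,
) -> np.ndarray:
    """Generate log(BMI): beta0 + int beta1(t) Z(t) dt + covariates + b_school + eps."""
    truth = truth.resolve()
    n = len(covariates)
    if curves.shape != (n, grid.m):
        raise ValueError(
            f"curves shape {curves.shape} does not match (n, m)=({n}, {grid.m})"
        )
    beta_vals = truth.beta_fun_values(grid)
    functional = curves @ (grid.weights * beta_vals)
    x_age = covariates["age"].to_numpy(dtype=float)
    x_sex = (covariates["sex"] == "boy").to_numpy(dtype=float)
    x_race = (covariates["race"] == "white").to_numpy(dtype=float)
    x_desk = (covariates["desk"] == "stand-biased").to_numpy(dtype=float)
    linear = (
        truth.beta0
        + truth.beta_age * x_age
        + truth.beta_sex * x_sex
        + truth.beta_race * x_race
        + truth.beta_desk * x_desk
    )
    schools = pd.unique(covariates["school_id"])
    b = rng.normal(0.0, math.sqrt(truth.sigma2_school), size=len(schools))
    school_effect = covariates["school_id"].map(dict(zip(schools, b))).to_numpy()
    eps = rng.normal(0.0, math.sqrt(truth.sigma2_resid), size=n)
    return linear + functional + school_effect + eps


def simulate_study(truth: SimulationTruth | None = None, **overrides) -> StudyData:
    """Compose covariates, curves and outcome into a StudyData."""
    if truth is None:
        truth = SimulationTruth(**overrides)
    elif overrides:
        truth = dataclasses.replace(truth, **overrides)
    truth = truth.resolve()
    rng = np.random.default_rng(truth.seed)
    grid = truth.grid()
    covariates = simulate_covariates(
        truth.n, truth.proportions, truth.age_mean_sd, truth.n_schools, rng
    )
    curves = simulate_curves(truth.n, grid, truth.curve_model, rng)
    log_bmi = simulate_outcome(covariates, curves, grid, truth, rng)
    table = covariates.copy()
    table["bmi"] = np.exp(log_bmi)
    table["log_bmi"] = log_bmi
    return StudyData(
        grid=grid,
        table=table,
        curves=curves,
        metadata={"seed": truth.seed, "truth": truth.to_jsonable()},
    )
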