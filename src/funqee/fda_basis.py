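"""B-spline basis machinery for scalar-on-function regression.

A clamped B-spline basis on [0, 1] turns a functional covariate Z(t)
into a G-vector of integrated scores Z_g = int Z(t) c_g(t) dt, and turns
fitted spline coefficients gamma back into a coefficient curve
beta(t) = sum_g gamma_g c_g(t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "BasisSet",
    "FunctionalScores",
    "FunctionalCoefficient",
    "build_bspline_basis",
    "score_functional_covariate",
    "reconstruct_beta",
]


@dataclass(frozen=True)
class BasisSet:
    """G clamped B-spline basis functions on [lo, hi]."""

    G: int
    degree: int
    knots: np.ndarray

    @property
    def domain(self) -> tuple[float, float]:
        return (float(self.knots[self.degree]), float(self.knots[-self.degree - 1]))

    def design(self, points: np.ndarray) -> np.ndarray:
        """Evaluate all basis functions: returns len(points) x G matrix."""
        points = np.atleast_1d(np.asarray(points, dtype=float))
        lo, hi = self.domain
        if points.min() < lo - 1e-12 or points.max() > hi + 1e-12:
            raise ValueError(f"evaluation points must lie in [{lo}, {hi}]")
        # design_matrix treats the right endpoint as inside the last span
        mat = BSpline.design_matrix(
            np.clip(points, lo, hi), self.knots, self.degree, extrapolate=False
        )
        return np.asarray(mat.todense())


@dataclass(frozen=True)
class FunctionalScores:
    """Integrated functional-covariate scores, one G-vector per subject."""

    values: np.ndarray  # (G,) or (n, G)
    basis: BasisSet


@dataclass(frozen=True)
class FunctionalCoefficient:
    """A coefficient curve beta(t) = sum_g gamma_g c_g(t) on eval points."""

    points: np.ndarray
    values: np.ndarray
    gamma: np.ndarray


def build_bspline_basis(
    G: int, degree: int = 3, domain: tuple[float, float] = (0.0, 1.0)
) -> BasisSet:
    """Clamped basis: degree+1 repeated boundary knots, G-degree-1 equally
    spaced interior knots.

    With G = degree + 1 there are no interior knots and the basis reduces
    to the Bernstein polynomials of that degree.
    """
    if degree < 0:
        raise ValueError("degree must be nonnegative")
    if G < degree + 1:
        raise ValueError(
            f"G={G} is too small for degree {degree}; need at least G={degree + 1}"
        )
    lo, hi = domain
    if not hi > lo:
        raise ValueError("domain must be an increasing interval")
    n_interior = G - degree - 1
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.concatenate(
        [np.full(degree + 1, lo), interior, np.full(degree + 1, hi)]
    )
    return BasisSet(G=G, degree=degree, knots=knots)


def score_functional_covariate(curve, grid, basis: BasisSet) -> FunctionalScores:
    """Quadrature scores Z_g = sum_k w_k Z(t_k) c_g(t_k).

    ``curve`` may be a single length-m curve or an (n, m) matrix.
    """
    curve = np.asarray(curve, dtype=float)
    single = curve.ndim == 1
    mat = np.atleast_2d(curve)
    if mat.shape[1] != grid.m:
        raise ValueError(
            f"curve length {mat.shape[1]} does not match grid m={grid.m}"
        )
    design = basis.design(grid.points)  # (m, G)
    scores = (mat * grid.weights[None, :]) @ design
    return FunctionalScores(values=scores[0] if single else scores, basis=basis)


def reconstruct_beta(gamma, basis: BasisSet, eval_points) -> FunctionalCoefficient:
    """beta(t) = sum_g gamma_g c_g(t) at the requested points."""
    gamma = np.asarray(gamma, dtype=float)
    if gamma.shape != (basis.G,):
        raise ValueError(f"gamma must have length G={basis.G}, got {gamma.shape}")
    points = np.atleast_1d(np.asarray(eval_points, dtype=float))
    values = basis.design(points) @ gamma
    return FunctionalCoefficient(points=points, values=values, gamma=gamma)
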