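"""Estimation of the interaction parameter zw from melting-point data.

Thin functional layer over the estimators in :mod:`bwsle.estimators`,
expressed in the package's domain types (SLE datasets, fit results,
per-point estimate tables). Two routes to zw exist:

* a grid-search fit over all data points (:func:`fit_zw_grid`), minimising
  the average absolute deviation (AAD) between the model liquidus and the
  measured melting temperatures; and
* algebraic inversion point by point (:func:`estimate_zw_from_point`),
  each point yielding one estimate per branch, of which the numerically
  smaller is kept, combined across points by an inverse-variance weighted
  mean (:func:`estimate_zw_pointwise`).

First-order error propagation gives per-point uncertainties from three
separate sources: the measured temperature, the pure compound's enthalpy
of melting, and its melting temperature. Each scales as (1-x)^-2, so
compositions near 0 or 1 carry very large errors and near-zero weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import estimators as _est
from .estimators import (
    BraggWilliamsSLE,
    PointwiseZw,
    curve_sensitivity,
    weighted_mean_zw,
    zw_from_branch_point,
)
from .thermo import BOUNDARY_TOL, BinaryPair, BWModel, liquidus_temperature

__all__ = [
    "SLEPoint", "SLEDataset", "FitResult", "ZwPointEstimates",
    "estimate_zw_from_point", "estimate_zw_pointwise", "fit_zw_grid", "aad",
    "zw_error_from_temperature", "zw_error_from_enthalpy", "zw_error_from_tm",
    "curve_sensitivity", "weighted_mean_zw", "zw_from_branch_point",
]


@dataclass(frozen=True)
class SLEPoint:
    """One measured melting point: molar fraction of A, temperature (K),
    and an optional temperature uncertainty (K)."""

    x_a: float
    t: float
    t_err: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.x_a <= 1.0):
            raise ValueError(f"x_a must be in [0, 1], got {self.x_a}")
        if self.t <= 0:
            raise ValueError(f"melting temperature must be positive, got {self.t}")

    @property
    def is_interior(self) -> bool:
        return BOUNDARY_TOL < self.x_a < 1.0 - BOUNDARY_TOL


@dataclass(frozen=True)
class SLEDataset:
    """Measured or synthetic melting points for one binary pair.

    Points keep file order; duplicates (replicate measurements) are
    allowed. Boundary points are stored but excluded from estimation.
    """

    pair: BinaryPair
    points: tuple[SLEPoint, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))

    def __len__(self) -> int:
        return len(self.points)

    @property
    def x_a(self) -> np.ndarray:
        return np.array([p.x_a for p in self.points])

    @property
    def t(self) -> np.ndarray:
        return np.array([p.t for p in self.points])

    @property
    def t_err(self) -> np.ndarray:
        return np.array([np.nan if p.t_err is None else p.t_err for p in self.points])

    def interior(self) -> "SLEDataset":
        return SLEDataset(self.pair, tuple(p for p in self.points if p.is_interior))


@dataclass(frozen=True)
class FitResult:
    """Outcome of the grid-search fit. ``zw`` in J/mol; AADs in K."""

    zw: float
    aad_bw: float
    aad_ideal: float
    grid: tuple[float, float, float]
    n_points_used: int


@dataclass(frozen=True)
class ZwPointEstimates:
    """Per-point zw estimates and their inverse-variance weighted mean.

    All zw values and errors in J/mol. ``branch[i]`` records which
    branch supplied the chosen (numerically smaller) estimate;
    ``error_source``/``magnitude`` state the propagated uncertainty.
    """

    x_a: np.ndarray
    zw_a: np.ndarray
    zw_b: np.ndarray
    zw_chosen: np.ndarray
    err: np.ndarray
    branch: np.ndarray = field(repr=False)
    weighted_mean: float = 0.0
    weighted_mean_err: float = 0.0
    error_source: str = "temperature"
    magnitude: float = 5.0


def estimate_zw_from_point(pair: BinaryPair, point: SLEPoint):
    """Invert the branch equation at one interior melting point.

    Returns ``(zw_a, zw_b, zw_chosen)`` in J/mol: the A-branch estimate,
    the B-branch estimate, and the numerically smaller of the two — the
    larger one would imply, for the other compound, a melting temperature
    above the measured one.
    """
    if not point.is_interior:
        raise ValueError(
            f"x_a={point.x_a} is at (or within {BOUNDARY_TOL:g} of) a pure-"
            "compound boundary; the (1-x)^-2 inversion is singular there")
    zw_a = zw_from_branch_point(pair.a, point.x_a, point.t)
    zw_b = zw_from_branch_point(pair.b, 1.0 - point.x_a, point.t)
    return zw_a, zw_b, min(zw_a, zw_b)


def estimate_zw_pointwise(dataset: SLEDataset, error_source: str = "temperature",
                          magnitude: float = 5.0) -> ZwPointEstimates:
    """Per-point zw estimates with error bars and their weighted mean.

    ``magnitude`` is the assumed uncertainty of the chosen source: K for
    "temperature" and "tm", J/mol for "enthalpy"; default 5 K on the
    measured temperature.
    """
    est = PointwiseZw(dataset.pair, error_source=error_source,
                      magnitude=magnitude).fit(dataset.x_a, dataset.t)
    return ZwPointEstimates(
        x_a=est.x_, zw_a=est.zw_a_, zw_b=est.zw_b_, zw_chosen=est.zw_point_,
        err=est.err_point_, branch=est.branch_point_,
        weighted_mean=est.zw_, weighted_mean_err=est.zw_err_,
        error_source=error_source, magnitude=magnitude)


def fit_zw_grid(dataset: SLEDataset, grid_min: float = -100_000.0,
                grid_max: float = 100_000.0, step: float = 100.0,
                refine: bool = False) -> FitResult:
    """Grid-search fit of zw minimising the AAD over interior points.

    Defaults scan -100 to +100 kJ/mol in 0.1 kJ/mol steps; ties break
    toward the smallest |zw|. ``refine=True`` polishes the optimum by a
    bounded continuous search within one grid step (off by default: the
    plain protocol is the discrete grid).
    """
    est = BraggWilliamsSLE(dataset.pair, grid_min=grid_min, grid_max=grid_max,
                           step=step, refine=refine).fit(dataset.x_a, dataset.t)
    return FitResult(zw=est.zw_, aad_bw=est.aad_, aad_ideal=est.aad_ideal_,
                     grid=est.grid_, n_points_used=est.n_points_used_)


def aad(dataset: SLEDataset, model: BWModel) -> float:
    """Average absolute deviation (K) of the model liquidus from the
    dataset's interior points, evaluated at the experimental x_a."""
    interior = dataset.interior()
    if len(interior) == 0:
        raise ValueError("dataset has no interior points")
    t_model = liquidus_temperature(model, interior.x_a)
    return float(np.mean(np.abs(np.asarray(t_model) - interior.t)))


def _branch_errs(pair, point, fn, magnitude):
    zw_a, zw_b, _ = estimate_zw_from_point(pair, point)
    if zw_a <= zw_b:
        return float(fn(pair.a, point.x_a, point.t, magnitude))
    return float(fn(pair.b, 1.0 - point.x_a, point.t, magnitude))


def zw_error_from_temperature(pair: BinaryPair, point: SLEPoint, dt: float) -> float:
    """Propagated zw error (J/mol) for a ``dt`` kelvin uncertainty on the
    point's measured temperature, on the same branch as the chosen zw."""
    if dt <= 0:
        raise ValueError("perturbation magnitude must be positive")
    return _branch_errs(pair, point, _est.zw_error_from_temperature, dt)


def zw_error_from_enthalpy(pair: BinaryPair, point: SLEPoint, dh: float) -> float:
    """Propagated zw error (J/mol) for a ``dh`` J/mol uncertainty on the
    branch compound's enthalpy of melting."""
    if dh <= 0:
        raise ValueError("perturbation magnitude must be positive")
    return _branch_errs(pair, point, _est.zw_error_from_enthalpy, dh)


def zw_error_from_tm(pair: BinaryPair, point: SLEPoint, dtm: float) -> float:
    """Propagated zw error (J/mol) for a ``dtm`` kelvin uncertainty on the
    branch compound's melting temperature."""
    if dtm <= 0:
        raise ValueError("perturbation magnitude must be positive")
    return _branch_errs(pair, point, _est.zw_error_from_tm, dtm)
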