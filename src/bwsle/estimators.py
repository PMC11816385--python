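"""Scikit-learn style estimators for the Bragg-Williams interaction parameter.

Two estimators are provided, both following the fit/predict contract so
they compose with sklearn pipelines and model selection:

``BraggWilliamsSLE``
    Grid-search fit of the single interaction parameter zw to a set of
    (x_a, T) melting points, minimising the average absolute deviation
    (AAD) between the model liquidus and the data. The default grid is
    -100 to +100 kJ/mol in steps of 0.1 kJ/mol and candidate liquidus
    temperatures are evaluated directly at the experimental compositions
    (never interpolated from a display grid).

``PointwiseZw``
    Per-point algebraic inversion of the branch equation: each melting
    point yields two zw estimates (one per branch); the numerically
    smaller is kept — the larger one would imply, for the other compound,
    a melting temperature above the measured one. Point estimates are
    combined by an inverse-variance weighted mean, with per-point
    variances from first-order error propagation of a chosen error source.

Both accept X as an (n,) or (n, 1) array of molar fractions of compound A
and y as the measured melting temperatures in kelvin. Compositions within
1e-6 of 0 or 1 are excluded from fitting (the error terms are singular
there) with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .thermo import (
    BOUNDARY_TOL,
    KJ,
    R,
    BinaryPair,
    BWModel,
    NonphysicalModelError,
    ideal_branch_temperature,
    liquidus_temperature,
)

_ERROR_SOURCES = ("temperature", "enthalpy", "tm")


def _validate_xy(X, y=None):
    X = np.asarray(X, dtype=float)
    if X.ndim == 2 and X.shape[1] == 1:
        X = X[:, 0]
    if X.ndim != 1:
        raise ValueError(f"X must be (n,) or (n, 1) molar fractions, got shape {X.shape}")
    if np.any((X < 0) | (X > 1)) or not np.all(np.isfinite(X)):
        raise ValueError("molar fractions must lie in [0, 1]")
    if y is None:
        return X
    y = np.asarray(y, dtype=float)
    if y.shape != X.shape:
        raise ValueError(f"y has shape {y.shape}, expected {X.shape}")
    if np.any(y <= 0):
        raise ValueError("melting temperatures must be positive kelvin")
    return X, y


def _interior_mask(x: np.ndarray) -> np.ndarray:
    mask = (x > BOUNDARY_TOL) & (x < 1.0 - BOUNDARY_TOL)
    if not np.all(mask):
        warnings.warn(
            f"excluding {int((~mask).sum())} boundary point(s) (x within "
            f"{BOUNDARY_TOL:g} of 0 or 1) from estimation", stacklevel=3)
    return mask


def zw_from_branch_point(compound, x, t):
    """Invert the branch equation for zw at one melting point.

    ``x`` is the molar fraction of ``compound`` and ``t`` the measured
    liquidus temperature. Returns J/mol. Vectorised.

        zw = [dHm (T/Tm - 1) - R T ln(x)] / (1 - x)^2
    """
    x = np.asarray(x, dtype=float)
    if np.any((x <= 0) | (x >= 1)):
        bad = np.atleast_1d(x)[np.atleast_1d((x <= 0) | (x >= 1))][0]
        raise ValueError(f"per-point inversion needs interior molar fractions, got {bad}")
    t = np.asarray(t, dtype=float)
    zw = (compound.dhm * (t / compound.tm - 1.0) - R * t * np.log(x)) / (1.0 - x) ** 2
    return zw if zw.ndim else float(zw)


def zw_error_from_temperature(compound, x, t, dt):
    """Propagated zw uncertainty from a temperature error ``dt`` (K).

    |d zw / dT| * dt = [dHm/Tm - R ln(x)] / (1-x)^2 * dt, in J/mol.
    Grows as (1-x)^-2 toward the pure-compound boundary; never clipped.
    """
    x = np.asarray(x, dtype=float)
    return np.abs(compound.dhm / compound.tm - R * np.log(x)) / (1.0 - x) ** 2 * dt


def zw_error_from_enthalpy(compound, x, t, dh):
    """Propagated zw uncertainty from an error ``dh`` (J/mol) in the
    compound's enthalpy of melting: |T/Tm - 1| / (1-x)^2 * dh."""
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    return np.abs(t / compound.tm - 1.0) / (1.0 - x) ** 2 * dh


def zw_error_from_tm(compound, x, t, dtm):
    """Propagated zw uncertainty from an error ``dtm`` (K) in the
    compound's melting temperature: dHm T / Tm^2 / (1-x)^2 * dtm."""
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    return compound.dhm * t / compound.tm ** 2 / (1.0 - x) ** 2 * dtm


class BraggWilliamsSLE(RegressorMixin, BaseEstimator):
    """Grid-search regressor for the Bragg-Williams liquidus.

    Parameters
    ----------
    pair : BinaryPair
        The two pure compounds; X is the molar fraction of ``pair.a``.
    grid_min, grid_max : float, default -100e3 / +100e3
        Search range for zw, J/mol.
    step : float, default 100.0
        Grid resolution, J/mol (0.1 kJ/mol).
    refine : bool, default False
        If True, polish the grid optimum by golden-section search within
        one grid step on either side. Off by default so the fit follows
        the discrete grid protocol exactly.

    Attributes
    ----------
    zw_ : float
        Best-fit interaction parameter, J/mol.
    aad_ : float
        Average absolute deviation of the fitted liquidus, K.
    aad_ideal_ : float
        AAD of the ideal (zw = 0) liquidus, K.
    n_points_used_ : int
        Interior points that entered the objective.
    model_ : BWModel
        The fitted model, ready for curve construction.
    """

    def __init__(self, pair: BinaryPair | None = None, grid_min: float = -100 * KJ,
                 grid_max: float = 100 * KJ, step: float = 100.0, refine: bool = False):
        self.pair = pair
        self.grid_min = grid_min
        self.grid_max = grid_max
        self.step = step
        self.refine = refine

    def _candidates(self) -> np.ndarray:
        if self.pair is None:
            raise ValueError("BraggWilliamsSLE requires a BinaryPair")
        if not (self.grid_min < self.grid_max) or self.step <= 0:
            raise ValueError("need grid_min < grid_max and step > 0")
        n = int(round((self.grid_max - self.grid_min) / self.step))
        return self.grid_min + self.step * np.arange(n + 1)

    def _branch_matrix(self, zw: np.ndarray, x: np.ndarray) -> np.ndarray:
        """Liquidus temperature for every (candidate, composition) pair;
        NaN where both branches are nonphysical."""
        a, b = self.pair.a, self.pair.b
        zw = zw[:, None]
        ta_num = 1.0 + (zw / a.dhm) * (1.0 - x) ** 2
        ta = np.where(ta_num > 0, ta_num / (1.0 / a.tm - (R / a.dhm) * np.log(x)), np.nan)
        xb = 1.0 - x
        tb_num = 1.0 + (zw / b.dhm) * (1.0 - xb) ** 2
        tb = np.where(tb_num > 0, tb_num / (1.0 / b.tm - (R / b.dhm) * np.log(xb)), np.nan)
        return np.fmax(ta, tb)

    def fit(self, X, y):
        x, t = _validate_xy(X, y)
        mask = _interior_mask(x)
        x, t = x[mask], t[mask]
        if x.size == 0:
            raise ValueError("no interior data points: nothing to fit")

        zw_grid = self._candidates()
        t_model = self._branch_matrix(zw_grid, x)
        bad = np.isnan(t_model).any(axis=1)
        if bad.all():
            raise NonphysicalModelError(
                "every zw candidate is nonphysical at some data composition; "
                f"grid [{self.grid_min / KJ:g}, {self.grid_max / KJ:g}] kJ/mol")
        obj = np.mean(np.abs(t_model - t), axis=1)
        obj[bad] = np.inf

        best = obj.min()
        ties = np.flatnonzero(obj == best)
        # parsimony: smallest |zw| wins; between +/-|zw|, the negative one
        order = np.lexsort((zw_grid[ties], np.abs(zw_grid[ties])))
        zw_hat = float(zw_grid[ties[order[0]]])

        if self.refine:
            from scipy.optimize import minimize_scalar
            lo = max(self.grid_min, zw_hat - self.step)
            hi = min(self.grid_max, zw_hat + self.step)
            res = minimize_scalar(
                lambda z: float(np.mean(np.abs(
                    self._branch_matrix(np.array([z]), x)[0] - t))),
                bounds=(lo, hi), method="bounded",
                options={"xatol": self.step * 1e-6})
            if np.isfinite(res.fun) and res.fun <= best:
                zw_hat, best = float(res.x), float(res.fun)

        i0 = int(np.argmin(np.abs(zw_grid)))
        aad_ideal = (float(obj[i0]) if abs(zw_grid[i0]) < 1e-9 else
                     float(np.mean(np.abs(self._branch_matrix(np.zeros(1), x)[0] - t))))

        self.zw_ = zw_hat
        self.aad_ = float(best)
        self.aad_ideal_ = aad_ideal
        self.n_points_used_ = int(x.size)
        self.grid_ = (float(self.grid_min), float(self.grid_max), float(self.step))
        self.model_ = BWModel(self.pair, zw_hat)
        return self

    def predict(self, X):
        """Liquidus temperature (K) of the fitted model at compositions X."""
        check_is_fitted(self, "zw_")
        x = _validate_xy(X)
        return np.asarray(liquidus_temperature(self.model_, x))


class PointwiseZw(RegressorMixin, BaseEstimator):
    """Per-point zw estimation with inverse-variance weighted averaging.

    Parameters
    ----------
    pair : BinaryPair
    error_source : {"temperature", "enthalpy", "tm"}, default "temperature"
        Which uncertainty drives the per-point error bars and weights.
    magnitude : float, default 5.0
        Size of that uncertainty: K for "temperature" and "tm",
        J/mol for "enthalpy". The default mirrors a 5 K temperature
        uncertainty.

    Attributes
    ----------
    zw_ : float
        Inverse-variance weighted mean of the per-point estimates, J/mol.
    zw_err_ : float
        Its standard error, 1/sqrt(sum of weights).
    zw_a_, zw_b_, zw_point_, err_point_ : ndarray
        Per-interior-point branch estimates, the chosen (smaller) value,
        and its propagated uncertainty.
    branch_point_ : ndarray of "A"/"B"
        Which branch supplied the chosen estimate.
    """

    def __init__(self, pair: BinaryPair | None = None,
                 error_source: str = "temperature", magnitude: float = 5.0):
        self.pair = pair
        self.error_source = error_source
        self.magnitude = magnitude

    def fit(self, X, y):
        if self.pair is None:
            raise ValueError("PointwiseZw requires a BinaryPair")
        if self.error_source not in _ERROR_SOURCES:
            raise ValueError(f"error_source must be one of {_ERROR_SOURCES}")
        if self.magnitude <= 0:
            raise ValueError("error magnitude must be positive")
        x, t = _validate_xy(X, y)
        mask = _interior_mask(x)
        x, t = x[mask], t[mask]
        if x.size == 0:
            raise ValueError("no interior data points: nothing to estimate")

        a, b = self.pair.a, self.pair.b
        zw_a = zw_from_branch_point(a, x, t)
        zw_b = zw_from_branch_point(b, 1.0 - x, t)
        choose_a = zw_a <= zw_b
        zw_pt = np.where(choose_a, zw_a, zw_b)

        err_fn = {"temperature": zw_error_from_temperature,
                  "enthalpy": zw_error_from_enthalpy,
                  "tm": zw_error_from_tm}[self.error_source]
        err_a = err_fn(a, x, t, self.magnitude)
        err_b = err_fn(b, 1.0 - x, t, self.magnitude)
        err_pt = np.where(choose_a, err_a, err_b)

        mean, se = weighted_mean_zw(zw_pt, err_pt)
        self.zw_ = mean
        self.zw_err_ = se
        self.x_ = x
        self.zw_a_ = np.atleast_1d(zw_a)
        self.zw_b_ = np.atleast_1d(zw_b)
        self.zw_point_ = np.atleast_1d(zw_pt)
        self.err_point_ = np.atleast_1d(err_pt)
        self.branch_point_ = np.where(np.atleast_1d(choose_a), "A", "B")
        self.model_ = BWModel(self.pair, mean)
        return self

    def predict(self, X):
        """Liquidus temperature (K) at the weighted-mean zw."""
        check_is_fitted(self, "zw_")
        x = _validate_xy(X)
        return np.asarray(liquidus_temperature(self.model_, x))


def weighted_mean_zw(zw, err):
    """Inverse-variance weighted mean and its standard error.

    ``mean = sum(zw_i / s_i^2) / sum(1 / s_i^2)``;
    ``se = 1 / sqrt(sum(1 / s_i^2))``. Estimates with infinite error get
    zero weight; all-infinite (or zero) weights raise.
    """
    zw = np.atleast_1d(np.asarray(zw, dtype=float))
    err = np.atleast_1d(np.asarray(err, dtype=float))
    if np.any(err <= 0):
        raise ValueError("propagated errors must be positive")
    w = 1.0 / err ** 2
    finite = np.isfinite(w) & (w > 0)
    if not finite.any():
        raise ValueError("all per-point weights vanish; cannot average")
    w, zw = w[finite], zw[finite]
    wsum = w.sum()
    return float((w * zw).sum() / wsum), float(1.0 / np.sqrt(wsum))


def curve_sensitivity(model: BWModel, x, dzw: float):
    """First-order liquidus temperature change for a zw perturbation.

    ``dT = (1-x)^2 / dHm * T_ideal(x) * dzw`` on the A branch; exact,
    since the explicit branch temperature is linear in zw. Bounded for
    all interior x — the curve has no singular sensitivity, unlike the
    per-point inverse problem.
    """
    x = np.asarray(x, dtype=float)
    t_id = ideal_branch_temperature(model.pair.a, x)
    s = (1.0 - x) ** 2 / model.pair.a.dhm * t_id * dzw
    return s if s.ndim else float(s)
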