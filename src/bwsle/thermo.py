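"""Closed-form liquidus equations for ideal and Bragg-Williams binary mixtures.

The model describes the solid-liquid equilibrium of a binary mixture of
immiscible solids A and B. Each liquidus branch gives the temperature at
which the pure solid of one compound is in equilibrium with the liquid
mixture of composition ``x`` (molar fraction of that compound in the
liquid). For an ideal solution melting-point depression is purely entropic:

    1/T = 1/Tm - R ln(x) / dHm

The Bragg-Williams (regular-solution) correction adds a single interaction
parameter ``zw`` — the number of contacts per molecule times the energy
change for replacing like contacts by an unlike contact — contributing a
partial molar mixing enthalpy ``(1 - x)^2 * zw``, which yields the explicit
branch temperature

    T = [1 + (zw/dHm) (1 - x)^2] / [1/Tm - (R/dHm) ln(x)].

``zw = 0`` recovers the ideal solution exactly. Negative ``zw`` deepens the
eutectic; positive ``zw`` raises the liquidus. All quantities are SI:
kelvin and J/mol; ``R = 8.31446`` J/(mol K). The heat capacity change on
melting is assumed negligible (no Delta-cp correction term).

Nonphysical branch values — the numerator above going non-positive for
extremely negative ``zw`` — are represented by NaN, never by a negative
temperature; a branch that is nonphysical at a composition simply cannot be
the liquidus there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import brentq

R = 8.31446
"""Universal gas constant, J/(mol K)."""

KJ = 1000.0
"""Joules per kilojoule; unit conversion at user-facing boundaries."""

#: Compositions within this distance of 0 or 1 are treated as boundary
#: points: the (1-x)^-2 error terms are singular there.
BOUNDARY_TOL = 1e-6


class NonphysicalModelError(ValueError):
    """Both liquidus branches are nonphysical somewhere on the grid."""


@dataclass(frozen=True)
class PureCompound:
    """A pure substance's melting data.

    Parameters
    ----------
    name : str
        Non-empty identifier.
    tm : float
        Melting temperature of the pure compound, K.
    dhm : float
        Molar enthalpy of melting (fusion), J/mol.
    """

    name: str
    tm: float
    dhm: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("compound name must be non-empty")
        if not (np.isfinite(self.tm) and self.tm > 0):
            raise ValueError(f"{self.name}: melting temperature must be > 0, got {self.tm}")
        if not (np.isfinite(self.dhm) and self.dhm > 0):
            raise ValueError(f"{self.name}: enthalpy of melting must be > 0, got {self.dhm}")


@dataclass(frozen=True)
class BinaryPair:
    """An ordered pair (A, B) of pure compounds defining a binary mixture.

    Throughout the package ``x`` denotes the molar fraction of compound
    ``a``; the fraction of ``b`` is ``1 - x``.
    """

    a: PureCompound
    b: PureCompound

    def __post_init__(self) -> None:
        if self.a.name == self.b.name:
            raise ValueError(f"pair requires two distinct compounds, got {self.a.name!r} twice")

    @property
    def label(self) -> str:
        return f"{self.a.name}/{self.b.name}"


@dataclass(frozen=True)
class BWModel:
    """A binary pair plus the Bragg-Williams interaction parameter.

    ``zw`` is in J/mol (user-facing surfaces report kJ/mol). ``zw = 0``
    reduces the model to the ideal solution exactly.
    """

    pair: BinaryPair
    zw: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.zw):
            raise ValueError(f"interaction parameter zw must be finite, got {self.zw}")


@dataclass(frozen=True)
class LiquidusCurve:
    """Both liquidus branches and their pointwise maximum on a grid.

    ``grid`` holds interior molar fractions of A; NaN entries in a branch
    mark nonphysical (negative-numerator) values. ``limiting_branch[i]``
    is ``"A"`` or ``"B"`` according to which branch attains the maximum.
    """

    grid: np.ndarray
    t_branch_a: np.ndarray
    t_branch_b: np.ndarray
    t_liquidus: np.ndarray
    limiting_branch: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class EutecticPoint:
    """Liquidus minimum: composition, temperature, and whether the two
    branches actually intersect inside (0, 1)."""

    x: float
    t: float
    branch_crossing: bool


def _check_x(x, upper_closed: bool = True) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    hi_bad = x > 1 if upper_closed else x >= 1
    bad = (x <= 0) | hi_bad
    if np.any(bad):
        offending = np.atleast_1d(x)[np.atleast_1d(bad)][0]
        rng = "(0, 1]" if upper_closed else "(0, 1)"
        raise ValueError(f"molar fraction must be in {rng}, got {offending}")
    return x


def ideal_branch_temperature(compound: PureCompound, x):
    """Ideal-solution liquidus temperature for ``compound`` at molar
    fraction ``x`` of that compound.

    Solves ``1/T = 1/Tm - R ln(x)/dHm``; returns K. Accepts scalars or
    arrays; ``x = 1`` returns ``tm`` exactly.
    """
    x = _check_x(x)
    inv_t = 1.0 / compound.tm - R * np.log(x) / compound.dhm
    t = np.where(x == 1.0, compound.tm, 1.0 / inv_t)  # exact analytic limit
    return t if t.ndim else float(t)


def bw_branch_temperature(model: BWModel, branch: Literal["A", "B"], x):
    """Bragg-Williams liquidus temperature of one branch.

    ``x`` is the molar fraction of the *branch* compound (for branch B the
    caller passes ``1 - x_a``). Nonphysical values (numerator <= 0, only
    possible for strongly negative ``zw``) come back as NaN.
    """
    comp = _branch_compound(model.pair, branch)
    x = _check_x(x)
    numer = 1.0 + (model.zw / comp.dhm) * (1.0 - x) ** 2
    denom = 1.0 / comp.tm - (R / comp.dhm) * np.log(x)
    t = np.where(numer > 0, numer / denom, np.nan)
    t = np.where(x == 1.0, comp.tm, t)  # exact analytic limit, any zw
    return t if t.ndim else float(t)


def _branch_compound(pair: BinaryPair, branch: str) -> PureCompound:
    if branch == "A":
        return pair.a
    if branch == "B":
        return pair.b
    raise ValueError(f"branch must be 'A' or 'B', got {branch!r}")


def excess_mixing_enthalpy(model: BWModel, x):
    """Partial molar mixing enthalpy of A in the liquid: ``(1-x)^2 zw``.

    Zero at ``x = 1`` (pure A); equals ``zw`` at ``x = 0``. J/mol.
    """
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("molar fraction must be in [0, 1]")
    h = (1.0 - x) ** 2 * model.zw
    return h if h.ndim else float(h)


def liquidus_temperature(model: BWModel, x_a):
    """Liquidus at overall composition ``x_a``: the higher of the two
    branch temperatures, NaN branches ignored."""
    x_a = _check_x(x_a, upper_closed=False)
    ta = bw_branch_temperature(model, "A", x_a)
    tb = bw_branch_temperature(model, "B", 1.0 - np.asarray(x_a, dtype=float))
    t = np.fmax(ta, tb)  # fmax ignores single NaNs
    return t if np.ndim(t) else float(t)


def liquidus_curve(model: BWModel, n_grid: int = 1000) -> LiquidusCurve:
    """Evaluate both branches on ``n_grid`` equally spaced interior
    compositions ``x_i = i/(n_grid + 1)`` and take the pointwise maximum.

    Endpoints are excluded: the log term is singular at x = 0 and the
    branch limits there are the pure melting temperatures, handled
    analytically by :func:`bw_branch_temperature` at x = 1.

    Raises
    ------
    NonphysicalModelError
        If both branches are nonphysical at some grid point.
    """
    if n_grid < 2:
        raise ValueError(f"n_grid must be >= 2, got {n_grid}")
    grid = np.arange(1, n_grid + 1) / (n_grid + 1)
    ta = bw_branch_temperature(model, "A", grid)
    tb = bw_branch_temperature(model, "B", 1.0 - grid)
    both_bad = np.isnan(ta) & np.isnan(tb)
    if np.any(both_bad):
        raise NonphysicalModelError(
            f"both branches nonphysical at x_a={grid[both_bad][0]:.4g} "
            f"for zw={model.zw / KJ:.3g} kJ/mol"
        )
    tl = np.fmax(ta, tb)
    limiting = np.where(np.fmax(ta, -np.inf) >= np.fmax(tb, -np.inf), "A", "B")
    limiting = np.where(np.isnan(ta), "B", np.where(np.isnan(tb), "A", limiting))
    return LiquidusCurve(grid=grid, t_branch_a=ta, t_branch_b=tb,
                         t_liquidus=tl, limiting_branch=limiting)


def eutectic_point(model: BWModel, n_grid: int = 1000, tol: float = 1e-6) -> EutecticPoint:
    """Locate the liquidus minimum.

    Finds the grid minimum of the liquidus, then refines the branch
    crossing ``T_A(x) = T_B(x)`` by bisection on their difference to
    within ``tol`` kelvin. If the branches do not cross inside (0, 1) —
    one compound's branch dominates everywhere — the boundary-adjacent
    grid minimum is returned with ``branch_crossing=False``.
    """
    curve = liquidus_curve(model, n_grid=n_grid)
    i_min = int(np.nanargmin(curve.t_liquidus))

    def diff(x: float) -> float:
        ta = bw_branch_temperature(model, "A", x)
        tb = bw_branch_temperature(model, "B", 1.0 - x)
        if np.isnan(ta) or np.isnan(tb):
            # a nonphysical branch cannot be the liquidus: push the sign
            # toward the physical branch
            return -np.inf if np.isnan(ta) else np.inf
        return ta - tb

    # bracket the sign change of T_A - T_B around the grid minimum
    lo_i, hi_i = None, None
    signs = np.sign([diff(x) for x in curve.grid[max(0, i_min - 2): i_min + 3]])
    base = max(0, i_min - 2)
    for j in range(len(signs) - 1):
        if signs[j] != signs[j + 1] and signs[j] != 0:
            lo_i, hi_i = base + j, base + j + 1
            break
    if lo_i is None:
        # fall back to a full scan (coarse grids, crossing away from minimum)
        all_signs = np.sign([diff(x) for x in curve.grid])
        flips = np.nonzero(np.diff(all_signs))[0]
        if flips.size:
            lo_i, hi_i = int(flips[0]), int(flips[0]) + 1

    if lo_i is None:
        return EutecticPoint(x=float(curve.grid[i_min]),
                             t=float(curve.t_liquidus[i_min]),
                             branch_crossing=False)

    # temperature tolerance -> composition tolerance via the local slope
    x_lo, x_hi = curve.grid[lo_i], curve.grid[hi_i]
    slope = abs(diff(x_hi) - diff(x_lo)) / (x_hi - x_lo)
    xtol = tol / slope if slope > 0 else tol
    x_star = brentq(diff, x_lo, x_hi, xtol=max(xtol, 1e-15))
    t_star = float(liquidus_temperature(model, x_star))
    return EutecticPoint(x=float(x_star), t=t_star, branch_crossing=True)
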