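"""Synthetic melting-point data with the statistical structure the
estimators assume.

Real liquidus measurements for eutectic mixtures are a handful of
(composition, temperature) points read off a DSC or visual melting
experiment. The generator emulates exactly that: compositions placed in a
sub-interval of (0, 1), temperatures on the Bragg-Williams liquidus of a
known model — the branch *maximum*, so the estimator's branch-selection
rule is genuinely exercised — plus additive Gaussian temperature noise.
Molar fractions carry no noise (they are prepared gravimetrically and
known to high accuracy). Measurement artifacts such as DSC peak
broadening, supercooling or metastability are not emulated.

Every dataset is reproducible from its spec (seed included); the
parameter-recovery harness derives per-replicate seeds deterministically
from a master seed via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .estimation import SLEDataset, SLEPoint, estimate_zw_pointwise, fit_zw_grid
from .thermo import BinaryPair, BWModel, liquidus_temperature


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic dataset.

    Parameters
    ----------
    pair : BinaryPair
    zw_true : float
        Generating interaction parameter, J/mol.
    n_points : int
    x_range : (float, float), default (0.05, 0.95)
        Compositions are placed strictly inside (0, 1).
    noise_sd : float, default 1.0
        Additive Gaussian temperature noise, K. The 1 K default reflects
        typical melting-point measurement scatter; it is a noise level,
        distinct from the larger 5 K / 5 kJ/mol *uncertainty assumptions*
        used for per-point error bars.
    seed : int, default 0
    design : {"uniform-grid", "uniform-random"}, default "uniform-grid"
    """

    pair: BinaryPair
    zw_true: float
    n_points: int
    x_range: tuple[float, float] = (0.05, 0.95)
    noise_sd: float = 1.0
    seed: int = 0
    design: str = "uniform-grid"

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.x_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError(f"x_range must lie strictly inside (0, 1), got {self.x_range}")
        if self.design not in ("uniform-grid", "uniform-random"):
            raise ValueError(f"unknown design {self.design!r}")


def generate_dataset(spec: SyntheticSpec) -> SLEDataset:
    """Sample melting points from the liquidus of ``(pair, zw_true)``.

    Compositions: an evenly spaced grid over ``x_range`` (or uniform
    draws). Temperatures: the branch-maximum liquidus plus N(0, noise_sd)
    noise; ``t_err`` is set to ``noise_sd`` when it is positive. Raises
    if the generating model is nonphysical anywhere on ``x_range``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.x_range
    if spec.design == "uniform-grid":
        x = np.linspace(lo, hi, spec.n_points)
    else:
        x = np.sort(rng.uniform(lo, hi, spec.n_points))
    model = BWModel(spec.pair, spec.zw_true)
    t_true = np.asarray(liquidus_temperature(model, x))
    if np.isnan(t_true).any():
        raise ValueError(
            f"generating model zw={spec.zw_true / 1000:.3g} kJ/mol is "
            f"nonphysical at x={x[np.isnan(t_true)][0]:.4g}")
    t = t_true + rng.normal(0.0, spec.noise_sd, spec.n_points) if spec.noise_sd > 0 else t_true
    t_err = spec.noise_sd if spec.noise_sd > 0 else None
    return SLEDataset(spec.pair, tuple(
        SLEPoint(float(xi), float(ti), t_err) for xi, ti in zip(x, t)))


@dataclass(frozen=True)
class RecoverySummary:
    """Monte-Carlo parameter-recovery summary over replicates.

    ``bias``/``rmse`` (J/mol) describe the grid-fit estimates;
    ``pointwise_bias``/``pointwise_rmse`` the per-point weighted means;
    ``coverage`` is the fraction of replicates whose weighted mean +/- its
    propagated error covers ``zw_true``.
    """

    zw_true: float
    n_replicates: int
    bias: float
    rmse: float
    pointwise_bias: float
    pointwise_rmse: float
    coverage: float
    fitted: np.ndarray
    pointwise: np.ndarray


def replicate_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-replicate seeds: the first ``n`` words of the
    ``SeedSequence(master_seed)`` state stream, folded below 2**31."""
    ss = np.random.SeedSequence(master_seed)
    return ss.generate_state(n, dtype=np.uint64) % (2 ** 31)


def recovery_experiment(spec: SyntheticSpec, n_replicates: int,
                        grid_step: float = 100.0) -> RecoverySummary:
    """Generate -> fit and generate -> pointwise-estimate, repeated.

    Each replicate re-runs :func:`generate_dataset` with its own derived
    seed, grid-fits zw, and forms the per-point inverse-variance weighted
    mean with the temperature error source set to the generating noise
    (or the 5 K default for noise-free data, where coverage is trivial).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    seeds = replicate_seeds(spec.seed, n_replicates)
    fitted = np.empty(n_replicates)
    pointwise = np.empty(n_replicates)
    covered = np.empty(n_replicates, dtype=bool)
    err_mag = spec.noise_sd if spec.noise_sd > 0 else 5.0
    for i, s in enumerate(seeds):
        ds = generate_dataset(replace(spec, seed=int(s)))
        fitted[i] = fit_zw_grid(ds, step=grid_step).zw
        pt = estimate_zw_pointwise(ds, error_source="temperature", magnitude=err_mag)
        pointwise[i] = pt.weighted_mean
        covered[i] = abs(pt.weighted_mean - spec.zw_true) <= pt.weighted_mean_err
    return RecoverySummary(
        zw_true=spec.zw_true, n_replicates=n_replicates,
        bias=float(np.mean(fitted - spec.zw_true)),
        rmse=float(np.sqrt(np.mean((fitted - spec.zw_true) ** 2))),
        pointwise_bias=float(np.mean(pointwise - spec.zw_true)),
        pointwise_rmse=float(np.sqrt(np.mean((pointwise - spec.zw_true) ** 2))),
        coverage=float(np.mean(covered)),
        fitted=fitted, pointwise=pointwise)
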