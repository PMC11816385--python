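"""CSV readers/writers and the packaged pure-compound table.

File conventions mirror how melting data are tabulated in practice:
kelvin for temperatures, kJ/mol for enthalpies, comma-separated with
``.`` decimals, ``#`` comment lines allowed. Internally everything is
J/mol; conversion happens on read/write only.

A registry of thirteen reference compounds — the menthol/thymol terpenes,
six monocarboxylic acids, trioctylphosphine oxide, camphor, sobrerol,
phenol and malonic acid — ships with the package and is the default
compound source for the command-line tools.
"""

from __future__ import annotations

import io as _stdio
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import FitResult, SLEDataset, SLEPoint, ZwPointEstimates
from .thermo import KJ, BinaryPair, LiquidusCurve, PureCompound

COMPOUND_COLUMNS = ["name", "tm_K", "dhm_kJ_per_mol"]
SLE_COLUMNS = ["x_a", "T_K"]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


@dataclass(frozen=True)
class CompoundRegistry:
    """Name -> PureCompound mapping; lookup is case-insensitive but names
    are stored as given."""

    compounds: dict[str, PureCompound]

    def __getitem__(self, name: str) -> PureCompound:
        key = name.casefold()
        for stored, comp in self.compounds.items():
            if stored.casefold() == key:
                return comp
        raise KeyError(f"unknown compound {name!r}; available: {', '.join(self.names)}")

    def __contains__(self, name: str) -> bool:
        try:
            self[name]
        except KeyError:
            return False
        return True

    def __len__(self) -> int:
        return len(self.compounds)

    @property
    def names(self) -> list[str]:
        return list(self.compounds)

    def pair(self, a: str, b: str) -> BinaryPair:
        return BinaryPair(self[a], self[b])


def _read_csv(source, required, what):
    try:
        df = pd.read_csv(source, comment="#", skip_blank_lines=True,
                         float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - surface as a parse error
        raise ParseError(f"cannot read {what} CSV from {source!r}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(
            f"{what} CSV is missing column(s) {missing}; expected header "
            f"{','.join(required)}, found {list(df.columns)}")
    return df


def read_compounds(source) -> CompoundRegistry:
    """Read a pure-compound table (``name,tm_K,dhm_kJ_per_mol``).

    Enthalpies are converted from kJ/mol to J/mol. Duplicate names,
    non-numeric fields and non-positive Tm or dHm raise :class:`ParseError`
    naming the offending row.
    """
    df = _read_csv(source, COMPOUND_COLUMNS, "compound")
    compounds: dict[str, PureCompound] = {}
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        name = str(row["name"]).strip()
        try:
            tm = float(row["tm_K"])
            dhm_kj = float(row["dhm_kJ_per_mol"])
        except (TypeError, ValueError) as exc:
            raise ParseError(f"line {line}: non-numeric value in {dict(row)}") from exc
        if name.casefold() in (n.casefold() for n in compounds):
            raise ParseError(f"line {line}: duplicate compound name {name!r}")
        try:
            compounds[name] = PureCompound(name, tm, dhm_kj * KJ)
        except ValueError as exc:
            raise ParseError(f"line {line}: {exc}") from exc
    return CompoundRegistry(compounds)


def default_registry() -> CompoundRegistry:
    """The packaged thirteen-compound reference table."""
    text = resources.files("bwsle.data").joinpath("pure_compounds.csv").read_text()
    return read_compounds(_stdio.StringIO(text))


def read_sle_dataset(source, pair: BinaryPair) -> SLEDataset:
    """Read melting points (``x_a,T_K`` with optional ``T_err_K``).

    Points are kept in file order; boundary compositions load fine but
    are excluded from estimation downstream. x_a outside [0, 1] raises.
    """
    df = _read_csv(source, SLE_COLUMNS, "SLE dataset")
    has_err = "T_err_K" in df.columns
    points = []
    for i, row in df.iterrows():
        line = i + 2
        try:
            x_a = float(row["x_a"])
            t = float(row["T_K"])
            t_err = float(row["T_err_K"]) if has_err and pd.notna(row["T_err_K"]) else None
        except (TypeError, ValueError) as exc:
            raise ParseError(f"line {line}: non-numeric value in {dict(row)}") from exc
        try:
            points.append(SLEPoint(x_a, t, t_err))
        except ValueError as exc:
            raise ParseError(f"line {line}: {exc}") from exc
    return SLEDataset(pair, tuple(points))


def write_sle_dataset(dataset: SLEDataset, dest) -> None:
    """Write a dataset back to ``x_a,T_K[,T_err_K]`` CSV (full precision)."""
    data = {"x_a": dataset.x_a, "T_K": dataset.t}
    t_err = dataset.t_err
    if np.isfinite(t_err).any():
        data["T_err_K"] = t_err
    # shortest round-trip repr so values survive write -> read bit-exactly
    pd.DataFrame(data).to_csv(dest, index=False,
                              float_format=lambda v: repr(float(v)))


def write_curve(curve: LiquidusCurve, dest) -> None:
    """Write a liquidus curve as CSV with both branches, their maximum
    and the limiting branch at each grid composition."""
    pd.DataFrame({
        "x_a": curve.grid,
        "T_branch_a_K": curve.t_branch_a,
        "T_branch_b_K": curve.t_branch_b,
        "T_liquidus_K": curve.t_liquidus,
        "limiting_branch": curve.limiting_branch,
    }).to_csv(dest, index=False)


def write_fit_report(result: FitResult, estimates: ZwPointEstimates | None,
                     curve: LiquidusCurve | None, dest) -> None:
    """Write a machine-readable fit report (JSON) plus, next to it, the
    liquidus curve CSV when a curve is given.

    Schema: ``zw_kJ_per_mol``, ``aad_bw_K``, ``aad_ideal_K``,
    ``grid_kJ_per_mol`` (min, max, step), ``n_points_used``, and an
    optional ``per_point`` table mirroring :class:`ZwPointEstimates`
    (zw values in kJ/mol, propagated errors likewise).
    """
    report: dict = {
        "zw_kJ_per_mol": result.zw / KJ,
        "aad_bw_K": result.aad_bw,
        "aad_ideal_K": result.aad_ideal,
        "grid_kJ_per_mol": [g / KJ for g in result.grid[:2]] + [result.grid[2] / KJ],
        "n_points_used": result.n_points_used,
    }
    if estimates is not None:
        report["per_point"] = {
            "error_source": estimates.error_source,
            "magnitude": estimates.magnitude / (KJ if estimates.error_source == "enthalpy" else 1.0),
            "x_a": estimates.x_a.tolist(),
            "zw_a_kJ_per_mol": (estimates.zw_a / KJ).tolist(),
            "zw_b_kJ_per_mol": (estimates.zw_b / KJ).tolist(),
            "zw_chosen_kJ_per_mol": (estimates.zw_chosen / KJ).tolist(),
            "err_kJ_per_mol": (estimates.err / KJ).tolist(),
            "branch": estimates.branch.tolist(),
            "weighted_mean_kJ_per_mol": estimates.weighted_mean / KJ,
            "weighted_mean_err_kJ_per_mol": estimates.weighted_mean_err / KJ,
        }
    dest = Path(dest)
    dest.write_text(json.dumps(report, indent=2) + "\n")
    if curve is not None:
        write_curve(curve, dest.with_suffix(".curve.csv"))


def read_fit_report(source) -> dict:
    """Load a fit report written by :func:`write_fit_report`."""
    return json.loads(Path(source).read_text())
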