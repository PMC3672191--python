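"""Titration orchestration: calibrate → fit → select → hydrodynamic shape.

:func:`run_titration` applies, per pH value: one- and two-species fits,
parsimony-based model selection, Stokes–Einstein conversion of the fast
diffusion coefficient, and — when the measured D falls below the
equal-volume sphere bound — Perrin prolate inversion at a fixed reference
volume.  The reference volume defaults to the sphere volume implied by the
largest selected D across the titration (the native, most compact state
anchors the constraint) and is overridable in the config.

Failures are isolated per pH: a row records its error and the run
continues.  Reports are byte-deterministic for a fixed config and input.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from . import __version__
from .errors import DomainError, FcsHydroError, UsageError
from .fcs import BeamGeometry, CorrelationCurve, PhysicalConditions, calibrate_beam
from .fitting import FitResult, compare_models, fit_correlation
from .hydro import NoProlateSolutionError, OutOfModelError, invert_prolate, sphere_volume, stokes_einstein_radius

__all__ = ["RunConfig", "TitrationReport", "run_titration", "write_report", "read_report"]

logger = logging.getLogger("fcs_hydroshape")

_COLUMNS = [
    "pH", "selected", "D1", "F1", "D2", "chi2_red_1sp", "chi2_red_2sp",
    "R_sph_A", "a_A", "b_A", "p", "slow_fraction", "error",
]


@dataclass(frozen=True)
class RunConfig:
    """Everything a titration run needs, JSON-serializable."""

    temperature_K: float = 298.15
    viscosity_cP: float = 0.89
    omega0_um: Optional[float] = None
    z0_um: Optional[float] = None
    photon_mode: str = "two-photon"
    d_ref_um2_s: float = 300.0
    calibration_tau_d_s: Optional[float] = None
    chi2_improvement: float = 0.10
    fraction_floor: float = 0.005
    volume_A3: Optional[float] = None
    seed: int = 0

    def beam(self) -> BeamGeometry:
        if self.omega0_um is not None:
            z0 = self.z0_um if self.z0_um is not None else 5.0 * self.omega0_um
            return BeamGeometry(self.omega0_um, z0, self.photon_mode)
        if self.calibration_tau_d_s is not None:
            return calibrate_beam(self.calibration_tau_d_s, self.d_ref_um2_s, self.photon_mode)
        raise UsageError("config must provide omega0_um or calibration_tau_d_s")

    def conditions(self) -> PhysicalConditions:
        return PhysicalConditions(self.temperature_K, self.viscosity_cP)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


@dataclass(frozen=True)
class TitrationReport:
    """Per-pH fit/shape table plus run provenance."""

    table: pd.DataFrame
    provenance: Dict

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.table.columns]
        if missing:
            raise UsageError(f"report table missing columns {missing}")


def _fit_row(ph: float, curve: CorrelationCurve, config: RunConfig, beam: BeamGeometry) -> dict:
    cond = config.conditions()
    row: dict = {"pH": ph, "error": ""}
    fit1 = fit_correlation(curve, 1, beam)
    row["chi2_red_1sp"] = fit1.chi2_red
    fit2: Optional[FitResult] = None
    try:
        fit2 = fit_correlation(curve, 2, beam)
        row["chi2_red_2sp"] = fit2.chi2_red
    except (UsageError, FcsHydroError) as exc:
        row["chi2_red_2sp"] = np.nan
        logger.info("pH %.2f: two-species fit unavailable (%s)", ph, exc)
    if fit2 is not None:
        choice = compare_models(fit1, fit2, config.chi2_improvement, config.fraction_floor)
        best = choice.best
        logger.info("pH %.2f: selected %d species (%s)", ph, choice.n_species, choice.reason)
    else:
        best = fit1
    row["selected"] = best.n_species
    row["D1"] = best.model.species[0].D_um2_s
    row["F1"] = best.model.species[0].fraction
    if best.n_species == 2:
        row["D2"] = best.model.species[1].D_um2_s
        row["slow_fraction"] = best.model.species[1].fraction
    else:
        row["D2"] = np.nan
        # the aggregate estimate still comes from the two-species fit when it exists
        row["slow_fraction"] = (
            min(sp.fraction for sp in fit2.model.species) if fit2 is not None else np.nan
        )
    row["R_sph_A"] = stokes_einstein_radius(row["D1"], cond)
    return row


def _add_shape(row: dict, volume_A3: float, cond: PhysicalConditions) -> None:
    try:
        shape = invert_prolate(row["D1"], volume_A3, cond)
        row["a_A"], row["b_A"], row["p"] = shape.a_A, shape.b_A, shape.p
    except NoProlateSolutionError:
        # faster than the equal-volume sphere: report the sphere itself
        r_eq = (3.0 * volume_A3 / (4.0 * np.pi)) ** (1.0 / 3.0)
        row["a_A"], row["b_A"], row["p"] = r_eq, r_eq, 1.0
    except OutOfModelError as exc:
        row["a_A"] = row["b_A"] = row["p"] = np.nan
        row["error"] = (row["error"] + f"; shape: {exc}").lstrip("; ")


def run_titration(config: RunConfig, curves: Mapping[float, CorrelationCurve]) -> TitrationReport:
    """Fit every curve, select models, and attach hydrodynamic shapes."""
    beam = config.beam()
    cond = config.conditions()
    logger.info(
        "titration run: %d curves, beam omega0=%.4g µm z0=%.4g µm (%s), T=%.2f K, eta=%.3g cP",
        len(curves), beam.omega0_um, beam.z0_um, beam.photon_mode.value,
        config.temperature_K, config.viscosity_cP,
    )
    if not curves:
        logger.warning("empty curve set: producing empty report")
    rows = []
    for ph in sorted(curves):
        try:
            rows.append(_fit_row(float(ph), curves[ph], config, beam))
        except FcsHydroError as exc:
            logger.warning("pH %.2f failed: %s", ph, exc)
            rows.append({"pH": float(ph), "error": str(exc)})
    d_values = [r["D1"] for r in rows if "D1" in r and np.isfinite(r.get("D1", np.nan))]
    if config.volume_A3 is not None:
        volume = config.volume_A3
    elif d_values:
        volume = sphere_volume(stokes_einstein_radius(max(d_values), cond))
        logger.info("reference volume from max D = %.4g µm²/s: %.4g Å³", max(d_values), volume)
    else:
        volume = np.nan
    for row in rows:
        if np.isfinite(row.get("D1", np.nan)) and np.isfinite(volume):
            _add_shape(row, volume, cond)
    table = pd.DataFrame(rows, columns=_COLUMNS)
    provenance = {
        "config": json.loads(config.to_json()),
        "config_sha256": config.digest(),
        "seeds": {"run": config.seed},
        "reference_volume_A3": None if not np.isfinite(volume) else float(volume),
        "package": "fcs-hydroshape",
        "version": __version__,
        "n_curves": len(curves),
    }
    return TitrationReport(table=table, provenance=provenance)


def write_report(report: TitrationReport, outdir) -> Dict[str, Path]:
    """Write report.csv + report.json under ``outdir``; returns the paths.

    Writing is deterministic (sorted keys, repr floats) so identical runs
    produce byte-identical artifacts.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / "report.csv"
    json_path = out / "report.json"
    report.table.to_csv(csv_path, index=False)
    payload = {
        "provenance": report.provenance,
        "table": json.loads(report.table.to_json(orient="split", index=False)),
    }
    json_path.write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")
    logger.info("report written to %s", out)
    return {"csv": csv_path, "json": json_path}


def read_report(outdir) -> TitrationReport:
    out = Path(outdir)
    payload = json.loads((out / "report.json").read_text())
    tbl = payload["table"]
    table = pd.DataFrame(tbl["data"], columns=tbl["columns"])
    table["error"] = table["error"].fillna("")
    return TitrationReport(table=table, provenance=payload["provenance"])
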