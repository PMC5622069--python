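"""End-to-end orchestration: peaks -> mass -> composition -> topology -> CCS.

The pipeline reproduces the native-MS inference chain for an unknown
complex: centroid the spectrum, assign a charge envelope and neutral mass,
enumerate integer subunit compositions within the mass-width tolerance,
rank candidate subunit arrangements against the observed dissociation
fragments, and (when a calibrant table is supplied) fit a drift-time
calibration.  Configuration is a flat TOML key map; every number in the
report traces back to a config key or an input file, and the report is
byte-identical across reruns on identical inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from . import ccs as ccs_mod
from .deconvolution import assign_charges, neutral_mass
from .peaks import pick_peaks, read_peaklist
from .stoichiometry import SubunitCatalog, solve_compositions
from .topology import ObservationSet, parse_label, rank_topologies

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "render_report"]

logger = logging.getLogger(__name__)

EXIT_MISSING_FILE = 2
EXIT_NO_COMPOSITION = 3


class PipelineError(RuntimeError):
    def __init__(self, message: str, exit_code: int = 1):
        super().__init__(message)
        self.exit_code = exit_code


@dataclass
class PipelineConfig:
    """Flat configuration; unknown keys are rejected on load."""

    # inputs
    peaks: str | None = None
    peaks_dialect: str = "tsv"
    catalog_csv: str | None = None
    adducts_csv: str | None = None
    observations: str | None = None
    calibrants: str | None = None
    # direct mass input (skips the spectrum stages when no peaks file given)
    mass: float | None = None
    # peak picking
    min_rel_intensity: float = 0.05
    min_prominence: float = 0.01
    # charge assignment
    zmin: int = 10
    zmax: int = 50
    tol_ppm: float = 100.0
    # composition solving
    mass_tol: float | None = None
    # topology
    topology_composition: str | None = None
    family: str = "ring"
    pendant: str | None = None
    secondary_dissociation: bool = False
    # CCS
    edc_coefficient: float = 1.57
    gas_mass: float = 28.0134
    # misc
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise PipelineError(f"config file not found: {path}", EXIT_MISSING_FILE)
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _require(path_str: str | None, what: str) -> Path:
    if path_str is None:
        raise PipelineError(f"config is missing the {what} path")
    path = Path(path_str)
    if not path.exists():
        raise PipelineError(f"{what} file not found: {path}", EXIT_MISSING_FILE)
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the report document.

    Raises :class:`PipelineError` with a stage-specific exit code on
    failure (2 for missing files, 3 when no composition fits the mass
    tolerance).
    """
    report: dict = {"parameters": config.to_dict()}

    # --- mass determination -------------------------------------------------
    fwhm_mass = 0.0
    if config.peaks is not None:
        path = _require(config.peaks, "peak list")
        logger.info("stage peaks: reading %s", path)
        spectrum = read_peaklist(path, config.peaks_dialect)
        peaklist = pick_peaks(
            spectrum, config.min_rel_intensity, config.min_prominence
        )
        if len(peaklist) < 2:
            raise PipelineError("fewer than 2 peaks found; cannot deconvolve")
        logger.info("stage deconvolve: %d peaks", len(peaklist))
        envelopes = assign_charges(peaklist, config.zmin, config.zmax, config.tol_ppm)
        if not envelopes:
            raise PipelineError("no consistent charge envelope found")
        estimates = [neutral_mass(e) for e in envelopes]
        # envelope with most members, then most intensity, wins
        best_i = max(
            range(len(envelopes)),
            key=lambda i: (len(envelopes[i]), sum(p.intensity for p, _ in envelopes[i].members)),
        )
        best = estimates[best_i]
        fwhm_mass = best.fwhm_mass
        observed_mass = best.mass
        report["mass_estimate"] = {
            "mass": best.mass,
            "sd": best.sd,
            "fwhm_mass": best.fwhm_mass,
            "n_peaks": best.n_peaks,
            "charges": [z for _, z in envelopes[best_i].members],
            "n_envelopes": len(envelopes),
        }
    elif config.mass is not None:
        observed_mass = config.mass
        report["mass_estimate"] = {"mass": config.mass, "source": "config"}
    else:
        raise PipelineError("config must provide either a peaks file or a mass")

    # --- composition solving ------------------------------------------------
    catalog_path = _require(config.catalog_csv, "subunit catalog")
    adducts = None
    if config.adducts_csv is not None:
        adducts = _require(config.adducts_csv, "adduct catalog")
    catalog = SubunitCatalog.from_csv(catalog_path, adducts)
    tol = config.mass_tol
    if tol is None:
        if fwhm_mass > 0:
            tol = fwhm_mass
        elif observed_mass < 10_000:
            tol = 2.0
        else:
            raise PipelineError(
                "mass_tol not set and no peak width available to derive it"
            )
    logger.info("stage assign: mass %.1f Da, tol %.1f Da", observed_mass, tol)
    compositions = solve_compositions(observed_mass, tol, catalog)
    if not compositions:
        nearest = _nearest_miss(observed_mass, catalog)
        raise PipelineError(
            f"no composition within {tol:.1f} Da of {observed_mass:.1f} Da "
            f"(nearest miss {nearest:+.1f} Da)",
            EXIT_NO_COMPOSITION,
        )
    report["compositions"] = [
        {
            "label": c.label(catalog),
            "counts": c.counts,
            "adduct_counts": c.adduct_counts,
            "theoretical_mass": c.theoretical_mass,
            "mass_error": c.mass_error,
        }
        for c in compositions[:50]
    ]

    # --- topology ranking ---------------------------------------------------
    if config.observations is not None:
        obs_path = _require(config.observations, "observations")
        try:
            observed = ObservationSet.from_csv(obs_path)
        except ValueError as exc:
            raise PipelineError(str(exc)) from None
        if config.topology_composition is not None:
            counts = parse_label(config.topology_composition)
        else:
            counts = compositions[0].symbol_counts(catalog)
            if config.pendant is not None:
                counts.pop(config.pendant, None)
        logger.info("stage topology: composition %s, family %s", counts, config.family)
        ranking = rank_topologies(
            counts,
            config.family,
            observed,
            secondary_dissociation=config.secondary_dissociation,
            pendant=config.pendant if config.family == "ring_plus_pendant" else None,
        )
        report["topology"] = {
            "composition": counts,
            "family": config.family,
            "ranking": [
                {
                    "canonical": topo.canonical or topo.label(),
                    "total": score.total,
                    "rank": score.rank,
                    "per_composition": score.per_composition,
                }
                for topo, score in ranking
            ],
        }

    # --- CCS calibration ----------------------------------------------------
    if config.calibrants is not None:
        cal_path = _require(config.calibrants, "calibrant table")
        records = _read_calibrants(cal_path)
        calibration = ccs_mod.fit_calibration(
            records, config.edc_coefficient, config.gas_mass
        )
        logger.info("stage ccs: fit over %d calibrants, r2=%.6f", len(records), calibration.r_squared)
        report["ccs_calibration"] = {
            "ln_a": calibration.ln_a,
            "b": calibration.b,
            "edc_coefficient": calibration.edc_coefficient,
            "gas_mass": calibration.gas_mass,
            "r_squared": calibration.r_squared,
            "n_calibrants": len(records),
        }

    return report


def _nearest_miss(mass: float, catalog: SubunitCatalog) -> float:
    """Signed mass error of the closest composition outside tolerance."""
    wide = solve_compositions(mass, max(abs(mass), 1e6), catalog)
    return wide[0].mass_error if wide else float("nan")


def _read_calibrants(path: Path) -> list[ccs_mod.CalibrantRecord]:
    import csv as _csv

    records = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(_csv.DictReader(fh), start=2):
            try:
                records.append(
                    ccs_mod.CalibrantRecord(
                        name=row["name"].strip(),
                        mass=float(row["mass"]),
                        z=int(row["z"]),
                        drift_time=float(row["drift_time_ms"]),
                        ccs_lit=float(row["ccs_A2"]),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise PipelineError(f"{path}: line {lineno}: {exc}") from None
    return records


def render_report(report: dict) -> str:
    """Deterministic JSON rendering (sorted keys, fixed layout)."""
    return json.dumps(report, indent=2, sort_keys=True) + "\n"
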