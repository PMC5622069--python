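"""Traveling-wave ion mobility CCS calibration.

TWIMS drift times have no closed-form relation to collision cross section,
so CCS is obtained by calibration: for calibrant ions of known literature
CCS, the EDC-corrected drift time t' = t_d - edc*sqrt(m/z)/1000 is related
to the charge- and reduced-mass-normalised cross section
CCS' = CCS_lit * sqrt(mu) / z (mu the ion/drift-gas reduced mass) by a
power law CCS' = a * t'^b, fit by ordinary least squares in log-log space.
Unknown ions are then converted with the inverse relation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .deconvolution import PROTON_MASS

__all__ = [
    "NITROGEN_MASS",
    "CalibrantRecord",
    "CCSCalibration",
    "fit_calibration",
    "ccs_of",
]

#: Average mass of N2 drift gas in Da.
NITROGEN_MASS = 28.0134


@dataclass(frozen=True)
class CalibrantRecord:
    name: str
    mass: float  # Da
    z: int
    drift_time: float  # ms
    ccs_lit: float  # Angstrom^2, literature value in the stated drift gas

    def __post_init__(self) -> None:
        if min(self.mass, self.z, self.drift_time, self.ccs_lit) <= 0:
            raise ValueError(f"calibrant {self.name}: all fields must be positive")


@dataclass
class CCSCalibration:
    ln_a: float
    b: float
    edc_coefficient: float
    gas_mass: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("calibration exponent b must be positive")
        if not (0 <= self.r_squared <= 1 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")


def _corrected_drift(drift_time: float, mass: float, z: int, edc: float) -> float:
    mz = (mass + z * PROTON_MASS) / z
    return drift_time - edc * np.sqrt(mz) / 1000.0


def _reduced_mass(mass: float, gas_mass: float) -> float:
    return mass * gas_mass / (mass + gas_mass)


def fit_calibration(
    calibrants: list[CalibrantRecord],
    edc_coefficient: float = 1.57,
    gas_mass: float = NITROGEN_MASS,
) -> CCSCalibration:
    """Least-squares power-law fit of normalised CCS against corrected drift time.

    Needs at least two calibrants with distinct corrected drift times.
    Raises a domain error naming any record whose corrected drift time is
    non-positive.
    """
    if len(calibrants) < 2:
        raise ValueError("need at least 2 calibrants")
    ln_t = []
    ln_ccs = []
    for rec in calibrants:
        t = _corrected_drift(rec.drift_time, rec.mass, rec.z, edc_coefficient)
        if t <= 0:
            raise ValueError(
                f"calibrant {rec.name}: corrected drift time {t:.4g} ms is not positive"
            )
        mu = _reduced_mass(rec.mass, gas_mass)
        ln_t.append(np.log(t))
        ln_ccs.append(np.log(rec.ccs_lit * np.sqrt(mu) / rec.z))
    ln_t = np.asarray(ln_t)
    ln_ccs = np.asarray(ln_ccs)
    if np.ptp(ln_t) < 1e-12:
        raise ValueError("calibrants have identical drift times; cannot fit")
    b, ln_a = np.polyfit(ln_t, ln_ccs, 1)
    fitted = ln_a + b * ln_t
    ss_res = float(np.sum((ln_ccs - fitted) ** 2))
    ss_tot = float(np.sum((ln_ccs - ln_ccs.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return CCSCalibration(
        ln_a=float(ln_a),
        b=float(b),
        edc_coefficient=edc_coefficient,
        gas_mass=gas_mass,
        r_squared=r2,
    )


def ccs_of(
    calibration: CCSCalibration, drift_time: float, mass: float, z: int
) -> float:
    """Convert one ion's drift time to CCS with a fitted calibration."""
    if min(drift_time, mass, z) <= 0:
        raise ValueError("drift_time, mass and z must be positive")
    t = _corrected_drift(drift_time, mass, z, calibration.edc_coefficient)
    if t <= 0:
        raise ValueError(f"corrected drift time {t:.4g} ms is not positive")
    mu = _reduced_mass(mass, calibration.gas_mass)
    ccs_prime = np.exp(calibration.ln_a + calibration.b * np.log(t))
    return float(ccs_prime * z / np.sqrt(mu))
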