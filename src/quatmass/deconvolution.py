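"""Charge-state assignment, neutral-mass estimation, and adduct-series detection.

Electrospray of a folded complex produces a short run of consecutive charge
states z, each observed at m/z = (M + z*m_p)/z with m_p the proton mass.
Adjacent peaks in such a run fix z without prior knowledge of M: for the
pair (p1 at higher m/z, p2 just below), z(p1) = (p2 - m_p)/(p1 - p2).
Maximal runs whose implied neutral masses agree within a ppm tolerance form
a :class:`ChargeEnvelope`; the envelope's intensity-weighted mass and width
form a :class:`MassEstimate`.

For an isotope-unresolved complex the mass uncertainty is set by the peak
width: a FWHM of w Th at charge z maps to w*z Da in the mass domain
(:func:`mass_width_from_peak_width`).

Metal/modification occupancy is read from satellite series: bound adducts
shift a monomer peak by delta/z per copy, so matching satellite intensities
at +k*delta/z yields an :class:`OccupancyDistribution` over adduct counts
(:func:`detect_adduct_series`).
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field

import numpy as np

from .peaks import Peak, PeakList

__all__ = [
    "PROTON_MASS",
    "CU_MASS",
    "ChargeEnvelope",
    "MassEstimate",
    "OccupancyDistribution",
    "assign_charges",
    "neutral_mass",
    "mass_width_from_peak_width",
    "detect_adduct_series",
    "copper_adduct_delta",
]

logger = logging.getLogger(__name__)

#: Proton mass in Da; the charging species in ammonium-acetate electrospray.
PROTON_MASS = 1.007276
#: Average atomic mass of copper in Da.
CU_MASS = 63.546


def copper_adduct_delta(displaced_protons: int = 0) -> float:
    """Mass shift per bound Cu, optionally charge-compensated.

    A Cu(II) ion bound with displacement of ``d`` protons shifts the neutral
    mass by 63.546 - d*1.008 Da.  The convention is genuinely ambiguous at
    low resolution, so it is exposed as configuration (d in {0, 1, 2}).
    """
    if displaced_protons not in (0, 1, 2):
        raise ValueError("displaced_protons must be 0, 1 or 2")
    return CU_MASS - displaced_protons * 1.008


@dataclass
class ChargeEnvelope:
    """Peaks with assigned consecutive charges, z decreasing as m/z increases."""

    members: list[tuple[Peak, int]]
    proton_mass: float = PROTON_MASS

    def __post_init__(self) -> None:
        if any(z < 1 for _, z in self.members):
            raise ValueError("all charges must be >= 1")
        mzs = [p.mz for p, _ in self.members]
        zs = [z for _, z in self.members]
        order = np.argsort(mzs)
        self.members = [self.members[i] for i in order]
        zs_sorted = [self.members[i][1] for i in range(len(self.members))]
        if any(a <= b for a, b in zip(zs_sorted, zs_sorted[1:])):
            raise ValueError("charge must strictly decrease with increasing m/z")

    def __len__(self) -> int:
        return len(self.members)

    def member_masses(self) -> np.ndarray:
        return np.array([z * (p.mz - self.proton_mass) for p, z in self.members])


@dataclass
class MassEstimate:
    """Neutral mass with spread (sd over charge states) and mass-domain FWHM."""

    mass: float
    sd: float
    fwhm_mass: float
    n_peaks: int
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        if self.sd < 0 or self.fwhm_mass < 0:
            raise ValueError("sd and fwhm_mass must be >= 0")


@dataclass
class OccupancyDistribution:
    """Normalized distribution over adduct counts, keys contiguous from 0."""

    probs: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.probs:
            keys = sorted(self.probs)
            if keys != list(range(keys[-1] + 1)):
                raise ValueError("occupancy keys must be contiguous from 0")
            total = sum(self.probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("occupancy fractions must sum to 1")

    @property
    def mode(self) -> int:
        return max(self.probs, key=lambda k: (self.probs[k], -k))

    @property
    def mean(self) -> float:
        return sum(k * p for k, p in self.probs.items())


def mass_width_from_peak_width(fwhm_mz: float, z: int) -> float:
    """Convert an m/z-domain FWHM to the mass domain: width_Da = fwhm_mz * z."""
    if fwhm_mz < 0:
        raise ValueError("fwhm_mz must be >= 0")
    if z < 1:
        raise ValueError("charge must be >= 1")
    return fwhm_mz * z


def _pair_mass(peak: Peak, z: int, proton_mass: float) -> float:
    return z * (peak.mz - proton_mass)


def assign_charges(
    peaks: PeakList,
    z_min: int,
    z_max: int,
    tol_ppm: float = 50.0,
    proton_mass: float = PROTON_MASS,
) -> list[ChargeEnvelope]:
    """Group peaks into charge envelopes of consecutive z.

    Walks the peak list from high to low m/z.  For each adjacent pair the
    candidate charge of the higher-m/z peak is z = (mz_low - m_p) /
    (mz_high - mz_low); the pair joins the current envelope when a rounded
    integer z in [z_min, z_max] makes both implied neutral masses agree
    within ``tol_ppm``.  When two integer charges both fit, the one with
    lower RMS mass disagreement wins, then the lower charge.  Envelopes
    need at least two members.
    """
    if not (1 <= z_min <= z_max <= 100):
        raise ValueError("require 1 <= z_min <= z_max <= 100")
    if len(peaks) < 2:
        if len(peaks) == 1:
            logger.warning("single peak: charge assignment is ambiguous")
        return []

    ordered = sorted(peaks, key=lambda p: p.mz, reverse=True)
    envelopes: list[ChargeEnvelope] = []
    current: list[tuple[Peak, int]] = []  # built high-m/z-first, z ascending

    def flush() -> None:
        if len(current) >= 2:
            envelopes.append(ChargeEnvelope(list(current), proton_mass))
        current.clear()

    i = 0
    while i < len(ordered) - 1:
        p_hi, p_lo = ordered[i], ordered[i + 1]
        spacing = p_hi.mz - p_lo.mz
        if spacing <= 0:
            flush()
            i += 1
            continue
        z_float = (p_lo.mz - proton_mass) / spacing
        candidates = []
        for z in {int(np.floor(z_float)), int(np.ceil(z_float))}:
            if not (z_min <= z <= z_max):
                continue
            m_hi = _pair_mass(p_hi, z, proton_mass)
            m_lo = _pair_mass(p_lo, z + 1, proton_mass)
            mean = 0.5 * (m_hi + m_lo)
            if abs(m_hi - m_lo) <= tol_ppm * 1e-6 * mean:
                rms = abs(m_hi - m_lo)
                candidates.append((rms, z))
        candidates.sort()
        chosen = None
        for _, z in candidates:
            if current:
                # p_hi already carries a charge from the previous pair
                if current[-1][1] != z:
                    continue
                # consistency of the newly implied mass with the run so far
                masses = [m for m in (_pair_mass(p, q, proton_mass) for p, q in current)]
                m_lo = _pair_mass(p_lo, z + 1, proton_mass)
                mean = statistics.fmean(masses + [m_lo])
                if abs(m_lo - mean) > tol_ppm * 1e-6 * mean:
                    continue
            chosen = z
            break
        if chosen is None:
            flush()
            i += 1
            continue
        if not current:
            current.append((p_hi, chosen))
        current.append((p_lo, chosen + 1))
        i += 1
    flush()
    return envelopes


def neutral_mass(envelope: ChargeEnvelope) -> MassEstimate:
    """Intensity-weighted neutral mass of an envelope.

    mass = weighted mean of z*(mz - m_p); sd = weighted standard deviation
    of the per-member masses; fwhm_mass = median of fwhm_mz * z over
    members.  A single-member envelope is flagged low-confidence.
    """
    if len(envelope) == 0:
        raise ValueError("empty envelope")
    masses = envelope.member_masses()
    weights = np.array([p.intensity for p, _ in envelope.members])
    if weights.sum() <= 0:
        weights = np.ones_like(weights)
    mean = float(np.average(masses, weights=weights))
    var = float(np.average((masses - mean) ** 2, weights=weights))
    fwhm_mass = float(np.median([p.fwhm_mz * z for p, z in envelope.members]))
    return MassEstimate(
        mass=mean,
        sd=var**0.5,
        fwhm_mass=fwhm_mass,
        n_peaks=len(envelope),
        low_confidence=len(envelope) < 2,
    )


def detect_adduct_series(
    peaks: PeakList,
    z: int,
    adduct_delta: float,
    max_adducts: int,
    tol_ppm: float = 100.0,
) -> OccupancyDistribution:
    """Read adduct occupancy from a satellite series at one charge state.

    The lowest-m/z member is taken as the apo (occupancy-0) anchor;
    satellites are expected at +k*adduct_delta/z for k = 1..max_adducts.
    Matched peak intensities, normalised, give the occupancy fractions;
    expected positions with no matching peak contribute 0.  Trailing
    all-zero occupancies beyond the last match are dropped so keys run
    contiguously from 0 to the maximum observed count.
    """
    if adduct_delta <= 0:
        raise ValueError("adduct_delta must be positive")
    if z < 1:
        raise ValueError("charge must be >= 1")
    if len(peaks) == 0:
        raise ValueError("no anchor peak: peak list is empty")
    anchor = peaks[0]
    spacing = adduct_delta / z
    raw: dict[int, float] = {}
    for k in range(max_adducts + 1):
        expected = anchor.mz + k * spacing
        tol = max(expected * tol_ppm * 1e-6, 1e-9)
        best = None
        for p in peaks:
            err = abs(p.mz - expected)
            if err <= tol and (best is None or err < abs(best.mz - expected)):
                best = p
        raw[k] = best.intensity if best is not None else 0.0
    last = max((k for k, v in raw.items() if v > 0), default=0)
    raw = {k: raw[k] for k in range(last + 1)}
    total = sum(raw.values())
    if total <= 0:
        raise ValueError("no anchor peak intensity: cannot form a distribution")
    return OccupancyDistribution({k: v / total for k, v in raw.items()})
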