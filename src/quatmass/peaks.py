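"""Peak-list and spectrum I/O plus centroiding.

A :class:`Spectrum` is the raw observable of a native-MS experiment: an
ordered set of (m/z, intensity) points, either profile (a sampled trace)
or centroided (one point per resolved ion species).  :func:`pick_peaks`
reduces a profile spectrum to a :class:`PeakList`, estimating each peak's
full width at half maximum (FWHM) — the width that, multiplied by the
charge state, sets the mass-domain uncertainty of a large complex whose
isotope structure is unresolved.

Intensities are never renormalised on read; downstream abundance classes
depend on raw ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Peak",
    "PeakList",
    "Spectrum",
    "PeakParseError",
    "read_peaklist",
    "write_peaklist",
    "pick_peaks",
    "is_centroided",
]

#: Threshold spacing (Th) below which adjacent points look like a profile trace.
_PROFILE_SPACING_TH = 0.05
#: A spectrum is centroided when fewer than this fraction of spacings are tight.
_PROFILE_FRACTION = 0.05


class PeakParseError(ValueError):
    """A peak-list file contained a row that could not be parsed."""


@dataclass(frozen=True)
class Peak:
    """A centroided peak: position, height, and full width at half maximum."""

    mz: float
    intensity: float
    fwhm_mz: float = 0.0

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.fwhm_mz < 0:
            raise ValueError(f"peak FWHM must be >= 0, got {self.fwhm_mz}")


@dataclass
class PeakList:
    """Peaks sorted ascending by m/z with no duplicates within 1e-6 Th."""

    peaks: list[Peak]

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)
        for a, b in zip(self.peaks, self.peaks[1:]):
            if abs(b.mz - a.mz) < 1e-6:
                raise ValueError(f"duplicate m/z within 1e-6 Th at {a.mz}")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def __getitem__(self, i):
        return self.peaks[i]

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])

    def base_peak(self) -> Peak:
        return max(self.peaks, key=lambda p: p.intensity)


@dataclass
class Spectrum:
    """An m/z-ordered intensity trace plus free-text metadata.

    Invariants: m/z strictly increasing, intensities non-negative, non-empty.
    """

    mz: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.size == 0:
            raise ValueError("spectrum must be non-empty")
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")

    def __len__(self) -> int:
        return self.mz.size


def _parse_rows(lines: Iterable[str], source: str) -> tuple[list[float], list[float]]:
    mzs: list[float] = []
    intens: list[float] = []
    header_allowed = True
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.replace(",", " ").split()
        try:
            values = [float(t) for t in tokens[:2]]
            if len(values) < 2:
                raise ValueError
        except ValueError:
            # one leading header line (non-numeric first token) is tolerated
            if header_allowed:
                header_allowed = False
                continue
            raise PeakParseError(
                f"{source}: non-numeric row at line {lineno}: {line!r}"
            ) from None
        header_allowed = False
        mzs.append(values[0])
        intens.append(values[1])
    return mzs, intens


def read_peaklist(path: str | Path, dialect: str = "tsv") -> Spectrum:
    """Read a two-column peak list (TSV/CSV) or an mzML file into a Spectrum.

    The text dialect accepts whitespace- or comma-separated numeric columns
    and auto-skips a single leading header line whose first token is
    non-numeric.  Points are returned sorted ascending by m/z; metadata
    records the source path and dialect.
    """
    path = Path(path)
    if dialect not in {"tsv", "csv", "mzml"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    if not path.exists():
        raise FileNotFoundError(f"peak list not found: {path}")
    if dialect == "mzml":
        from pyteomics import mzml as _mzml

        with _mzml.read(str(path)) as reader:
            try:
                scan = next(iter(reader))
            except StopIteration:
                raise ValueError(f"{path}: mzML file contains no spectra") from None
        mzs = np.asarray(scan["m/z array"], dtype=float)
        intens = np.asarray(scan["intensity array"], dtype=float)
    else:
        mzs, intens = _parse_rows(path.read_text().splitlines(), str(path))
    if len(mzs) == 0:
        raise ValueError(f"{path}: empty peak list")
    return Spectrum(
        np.asarray(mzs), np.asarray(intens), metadata={"source": str(path), "dialect": dialect}
    )


def write_peaklist(peaks: PeakList | Spectrum, path: str | Path) -> None:
    """Write peaks as TSV (mz, intensity[, fwhm_mz]) with a header line."""
    path = Path(path)
    lines = []
    if isinstance(peaks, PeakList):
        lines.append("mz\tintensity\tfwhm_mz")
        for p in peaks:
            lines.append(f"{p.mz:.10g}\t{p.intensity:.10g}\t{p.fwhm_mz:.10g}")
    else:
        lines.append("mz\tintensity")
        for mz, inten in zip(peaks.mz, peaks.intensity):
            lines.append(f"{mz:.10g}\t{inten:.10g}")
    path.write_text("\n".join(lines) + "\n")


def is_centroided(spectrum: Spectrum) -> bool:
    """Heuristic profile/centroid detection.

    A spectrum is profile (not centroided) when at least 5% of adjacent
    spacings are below 0.05 Th (finely sampled traces), or when the
    spacing is nearly uniform over many points (a sampling grid at any
    step, as for isotope-unresolved complexes sampled coarsely).
    """
    if len(spectrum) < 3:
        return True
    spacings = np.diff(spectrum.mz)
    if float(np.mean(spacings < _PROFILE_SPACING_TH)) >= _PROFILE_FRACTION:
        return False
    if len(spectrum) >= 50:
        cv = float(np.std(spacings) / np.mean(spacings))
        if cv < 0.05:
            return False
    return True


def _half_max_crossing(
    mz: np.ndarray, inten: np.ndarray, apex: int, half: float, direction: int
) -> float | None:
    """m/z where intensity crosses `half` walking from apex; None if truncated."""
    i = apex
    while 0 <= i + direction < len(mz):
        j = i + direction
        if inten[j] <= half:
            # linear interpolation between points i and j
            if inten[i] == inten[j]:
                return float(mz[j])
            frac = (inten[i] - half) / (inten[i] - inten[j])
            return float(mz[i] + frac * (mz[j] - mz[i]))
        i = j
    return None


def pick_peaks(
    spectrum: Spectrum,
    min_rel_intensity: float = 0.01,
    min_prominence: float = 0.0,
    profile: bool | None = None,
) -> PeakList:
    """Centroid a spectrum into a PeakList.

    Each returned peak is a local maximum whose height exceeds
    ``min_rel_intensity`` of the base peak and whose prominence exceeds
    ``min_prominence`` of the base peak.  The FWHM is estimated by linear
    interpolation to half maximum on both flanks; a flank that runs off the
    spectrum leaves FWHM at 0.  An all-zero spectrum yields an empty list.

    ``profile`` overrides the automatic profile/centroid detection.
    """
    if not (0 <= min_rel_intensity < 1 and 0 <= min_prominence < 1):
        raise ValueError("thresholds must lie in [0, 1)")
    base = float(spectrum.intensity.max())
    if base <= 0:
        return PeakList([])
    if profile is None:
        profile = not is_centroided(spectrum)
    if not profile:
        keep = [
            Peak(float(m), float(i))
            for m, i in zip(spectrum.mz, spectrum.intensity)
            if i >= min_rel_intensity * base and i > 0
        ]
        return PeakList(keep)

    from scipy.signal import find_peaks

    height = max(min_rel_intensity * base, np.finfo(float).tiny)
    kwargs: dict = {"height": height}
    if min_prominence > 0:
        kwargs["prominence"] = min_prominence * base
    idx, _ = find_peaks(spectrum.intensity, **kwargs)
    out: list[Peak] = []
    for apex in idx:
        half = spectrum.intensity[apex] / 2.0
        left = _half_max_crossing(spectrum.mz, spectrum.intensity, apex, half, -1)
        right = _half_max_crossing(spectrum.mz, spectrum.intensity, apex, half, +1)
        fwhm = (right - left) if (left is not None and right is not None) else 0.0
        out.append(
            Peak(
                _refine_apex(spectrum.mz, spectrum.intensity, apex, left, right),
                float(spectrum.intensity[apex]),
                fwhm,
            )
        )
    return PeakList(out)


def _refine_apex(
    mz: np.ndarray,
    inten: np.ndarray,
    apex: int,
    left: float | None,
    right: float | None,
) -> float:
    """Refine a sampled apex to sub-grid accuracy.

    Uses the intensity-weighted centroid of the points above half maximum
    (baseline-subtracted at the half level), which is exact for symmetric
    peaks and robust to additive noise; falls back to a 3-point parabola
    when the half-max region is too narrow, and to the grid point at the
    spectrum edges.
    """
    if left is not None and right is not None:
        sel = (mz >= left) & (mz <= right)
        if int(sel.sum()) >= 5:
            w = inten[sel] - inten[apex] / 2.0
            w = np.clip(w, 0.0, None)
            if w.sum() > 0:
                return float(np.average(mz[sel], weights=w))
    if apex == 0 or apex == len(mz) - 1:
        return float(mz[apex])
    y0, y1, y2 = inten[apex - 1], inten[apex], inten[apex + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:  # flat or non-concave: keep the grid point
        return float(mz[apex])
    dl = mz[apex] - mz[apex - 1]
    dr = mz[apex + 1] - mz[apex]
    if not math.isclose(dl, dr, rel_tol=1e-6):
        return float(mz[apex])
    shift = 0.5 * (y0 - y2) / denom
    return float(mz[apex] + shift * dl)
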