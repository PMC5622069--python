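"""Integer subunit/adduct composition solving against a neutral mass.

Given a catalog of subunit masses with copy-number bounds (plus optional
adducts such as bound Cu or covalent modifications), :func:`solve_compositions`
enumerates every integer composition whose theoretical mass falls within a
tolerance of an observed neutral mass, ranked by mass error then parsimony.
Near-degenerate alternatives (e.g. swapping two subunits of almost equal
mass) are deliberately kept in the ranked list rather than silently
resolved — at 211 kDa with a ~1.6 kDa peak width that degeneracy is real.

:func:`complement_check` verifies that two dissociation products sum to the
precursor mass, the arithmetic behind pairing a released subcomplex with
the residual species.
"""

from __future__ import annotations

import csv
import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "SubunitEntry",
    "AdductEntry",
    "SubunitCatalog",
    "Composition",
    "ComplementVerdict",
    "composition_mass",
    "solve_compositions",
    "complement_check",
    "mnx_catalog",
]

#: Refuse exhaustive searches larger than this many candidate compositions.
MAX_SEARCH_SPACE = 10**8


@dataclass(frozen=True)
class SubunitEntry:
    name: str
    mass: float
    min_copies: int = 0
    max_copies: int = 1
    #: one-letter display symbol used in composition labels (e.g. "E" for MnxE)
    symbol: str | None = None

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"subunit {self.name}: mass must be positive")
        if not (0 <= self.min_copies <= self.max_copies):
            raise ValueError(f"subunit {self.name}: require 0 <= min <= max copies")

    @property
    def display(self) -> str:
        return self.symbol or self.name


@dataclass(frozen=True)
class AdductEntry:
    name: str
    delta: float
    max_count: int = 0

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError(f"adduct {self.name}: delta must be positive")
        if self.max_count < 0:
            raise ValueError(f"adduct {self.name}: max_count must be >= 0")


@dataclass
class SubunitCatalog:
    """Subunit and adduct masses with copy-number bounds; names unique."""

    entries: list[SubunitEntry]
    adducts: list[AdductEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries] + [a.name for a in self.adducts]
        if len(set(names)) != len(names):
            raise ValueError("catalog names must be unique")

    def subunit(self, name: str) -> SubunitEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(f"unknown subunit {name!r}")

    def adduct(self, name: str) -> AdductEntry:
        for a in self.adducts:
            if a.name == name:
                return a
        raise KeyError(f"unknown adduct {name!r}")

    @classmethod
    def from_csv(cls, path: str | Path, adduct_path: str | Path | None = None) -> "SubunitCatalog":
        """Read a catalog from CSV (name, mass, min, max[, symbol]); adducts
        optionally from a second CSV (name, delta, max_count)."""
        entries = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                entries.append(
                    SubunitEntry(
                        name=row["name"].strip(),
                        mass=float(row["mass"]),
                        min_copies=int(row.get("min", 0) or 0),
                        max_copies=int(row.get("max", 1) or 1),
                        symbol=(row.get("symbol") or "").strip() or None,
                    )
                )
        adducts = []
        if adduct_path is not None:
            with open(adduct_path, newline="") as fh:
                for row in csv.DictReader(fh):
                    adducts.append(
                        AdductEntry(
                            name=row["name"].strip(),
                            delta=float(row["delta"]),
                            max_count=int(row.get("max_count", 0) or 0),
                        )
                    )
        return cls(entries, adducts)


@dataclass
class Composition:
    """Integer subunit counts plus adduct counts, with theoretical mass."""

    counts: dict[str, int]
    adduct_counts: dict[str, int] = field(default_factory=dict)
    theoretical_mass: float = 0.0
    mass_error: float = 0.0  # observed - theoretical

    @property
    def total_copies(self) -> int:
        return sum(self.counts.values())

    def label(self, catalog: "SubunitCatalog | None" = None) -> str:
        """Compact composition label, e.g. ``E3F3`` or ``G1E3F3``."""
        def disp(name: str) -> str:
            if catalog is not None:
                try:
                    return catalog.subunit(name).display
                except KeyError:
                    return name
            return name

        parts = sorted((disp(n), c) for n, c in self.counts.items() if c > 0)
        return "".join(f"{d}{c}" for d, c in parts)

    def symbol_counts(self, catalog: "SubunitCatalog | None" = None) -> dict[str, int]:
        out: dict[str, int] = {}
        for name, c in self.counts.items():
            if c <= 0:
                continue
            d = name
            if catalog is not None:
                try:
                    d = catalog.subunit(name).display
                except KeyError:
                    pass
            out[d] = out.get(d, 0) + c
        return out


def composition_mass(composition: Composition, catalog: SubunitCatalog) -> float:
    """Theoretical mass: sum of counts*subunit mass + adduct_counts*delta."""
    total = 0.0
    for name, count in composition.counts.items():
        total += count * catalog.subunit(name).mass
    for name, count in composition.adduct_counts.items():
        total += count * catalog.adduct(name).delta
    return total


def solve_compositions(
    mass: float,
    tol: float,
    catalog: SubunitCatalog,
    max_adducts: dict[str, int] | None = None,
) -> list[Composition]:
    """Exhaustively enumerate compositions with |observed - theoretical| <= tol.

    Results are ranked by |mass_error| ascending, then fewer total subunit
    copies, then fewer adducts, then lexicographic label — so the ordering
    is deterministic and invariant to catalog entry order.  An empty list
    means no composition fits within tolerance (not an error).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    entries = sorted(catalog.entries, key=lambda e: e.name)
    adducts = sorted(catalog.adducts, key=lambda a: a.name)
    adduct_caps = []
    for a in adducts:
        cap = a.max_count
        if max_adducts is not None and a.name in max_adducts:
            cap = max_adducts[a.name]
        adduct_caps.append(cap)

    space = math.prod(e.max_copies - e.min_copies + 1 for e in entries)
    space *= math.prod(c + 1 for c in adduct_caps)
    if space > MAX_SEARCH_SPACE:
        raise ValueError(
            f"search space {space:.3g} exceeds {MAX_SEARCH_SPACE:.0e}; "
            "tighten copy-number bounds or adduct caps"
        )

    results: list[Composition] = []
    subunit_ranges = [range(e.min_copies, e.max_copies + 1) for e in entries]
    adduct_ranges = [range(c + 1) for c in adduct_caps]
    for combo in itertools.product(*subunit_ranges):
        base = sum(c * e.mass for c, e in zip(combo, entries))
        for acombo in itertools.product(*adduct_ranges):
            theo = base + sum(c * a.delta for c, a in zip(acombo, adducts))
            err = mass - theo
            if abs(err) <= tol:
                results.append(
                    Composition(
                        counts={e.name: c for e, c in zip(entries, combo)},
                        adduct_counts={a.name: c for a, c in zip(adducts, acombo)},
                        theoretical_mass=theo,
                        mass_error=err,
                    )
                )
    results.sort(
        key=lambda c: (
            abs(c.mass_error),
            c.total_copies,
            sum(c.adduct_counts.values()),
            sorted(c.counts.items()),
            sorted(c.adduct_counts.items()),
        )
    )
    return results


@dataclass(frozen=True)
class ComplementVerdict:
    consistent: bool
    residual: float  # precursor - (f1 + f2), signed


def complement_check(
    precursor_mass: float, fragment_masses: tuple[float, float], tol: float
) -> ComplementVerdict:
    """Do two dissociation products account for the precursor mass?

    residual = precursor - (f1 + f2); consistent when |residual| <= tol.
    A positive residual is mass unaccounted for (e.g. retained metals or
    modifications lost with neither fragment).
    """
    f1, f2 = fragment_masses
    if precursor_mass <= 0 or f1 <= 0 or f2 <= 0:
        raise ValueError("masses must be positive")
    residual = precursor_mass - (f1 + f2)
    return ComplementVerdict(consistent=abs(residual) <= tol, residual=residual)


def mnx_catalog(
    mnxg_mass: float = 139783.0,
    mnxe_mass: float = 12112.0,
    mnxf_mass: float = 11699.0,
    max_cu: int = 15,
) -> SubunitCatalog:
    """Default catalog for the Mnx Mn-oxidase complex (MnxG + MnxE/MnxF).

    Masses are average masses consistent with the published approximate
    values (MnxG ~139 kDa plus the ~1 kDa excess it shows experimentally,
    MnxE/MnxF both ~12 kDa, intact complex 211,216 Da); exact per-subunit
    masses should be supplied from sequence-level measurements when known.
    """
    return SubunitCatalog(
        entries=[
            SubunitEntry("MnxG", mnxg_mass, 0, 1, symbol="G"),
            SubunitEntry("MnxE", mnxe_mass, 0, 8, symbol="E"),
            SubunitEntry("MnxF", mnxf_mass, 0, 8, symbol="F"),
        ],
        adducts=[
            AdductEntry("Cu", 63.546, max_count=max_cu),
            AdductEntry("gluconoyl", 176.0, max_count=1),
            AdductEntry("AEBSF", 183.0, max_count=1),
        ],
    )
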