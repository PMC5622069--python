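"""Synthetic ground truth and instrument-free forward models.

Everything downstream of the instrument can be exercised without data
files: a :class:`GroundTruth` fixes a subunit catalog, composition,
connectivity graph, and per-subunit metal-occupancy distributions, and the
generators here produce (deterministically per seed)

* native mass spectra — charge-state envelopes of every metal-occupancy
  mass variant with Gaussian peak shapes and optional uniform noise
  (:func:`simulate_spectrum`);
* dissociation fragment tables — low-energy SID releases the pendant
  subunit and the intact ring, high-energy SID samples contiguous ring
  arcs, CID ejects single unfolded monomers; SID retains bound metals with
  high probability, CID strips them (:func:`simulate_dissociation`);
* IM calibrant tables drawn from a known power-law calibration
  (:func:`simulate_calibrants`).

The default ground truth emulates a Mn-oxidase-like heterocomplex: one
~140 kDa catalytic subunit riding on an alternating ring of three ~12.1
and three ~11.7 kDa accessory subunits (total 211,216 Da), with the E-type
subunit binding one Cu tightly and the F-type 0-2 Cu loosely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .ccs import CalibrantRecord
from .deconvolution import CU_MASS, PROTON_MASS
from .peaks import Spectrum, write_peaklist
from .stoichiometry import Composition, SubunitCatalog, composition_mass, mnx_catalog
from .topology import (
    ObservationSet,
    TopologyGraph,
    classify_abundances,
    enumerate_arrangements,
    format_label,
    primary_cleavage,
)

__all__ = [
    "GroundTruth",
    "mnx_ground_truth",
    "simulate_spectrum",
    "simulate_dissociation",
    "simulate_calibrants",
    "write_simulation",
]


@dataclass
class GroundTruth:
    """A complete synthetic complex: catalog, composition, topology, metals."""

    catalog: SubunitCatalog
    composition: Composition
    topology: TopologyGraph
    metal_occupancy: dict[str, dict[int, float]] = field(default_factory=dict)
    metal_delta: float = CU_MASS
    seed: int = 0

    def __post_init__(self) -> None:
        topo_counts = self.topology.composition()
        comp_counts = self.composition.symbol_counts(self.catalog)
        if topo_counts != comp_counts:
            raise ValueError(
                f"topology composition {topo_counts} does not match "
                f"declared composition {comp_counts}"
            )
        for name, dist in self.metal_occupancy.items():
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"occupancy for {name} must sum to 1")

    @property
    def neutral_mass(self) -> float:
        return composition_mass(self.composition, self.catalog)

    def apo(self) -> "GroundTruth":
        """The same complex with all metal occupancies forced to zero
        (the EDTA-stripped preparation used for unambiguous assignment)."""
        return replace(
            self,
            metal_occupancy={k: {0: 1.0} for k in self.metal_occupancy},
        )

    def node_occupancy(self, symbol: str) -> dict[int, float]:
        """Occupancy distribution for a subunit, looked up by symbol or name."""
        if symbol in self.metal_occupancy:
            return self.metal_occupancy[symbol]
        for entry in self.catalog.entries:
            if entry.display == symbol and entry.name in self.metal_occupancy:
                return self.metal_occupancy[entry.name]
        return {0: 1.0}

    def total_metal_distribution(self) -> dict[int, float]:
        """Distribution of the total bound-metal count over the whole complex
        (independent convolution across subunit copies)."""
        dist = np.array([1.0])
        for sym, copies in sorted(self.topology.composition().items()):
            occ = self.node_occupancy(sym)
            vec = np.zeros(max(occ) + 1)
            for k, p in occ.items():
                vec[k] = p
            for _ in range(copies):
                dist = np.convolve(dist, vec)
        return {k: float(p) for k, p in enumerate(dist) if p > 1e-12}

    def ring_nodes(self) -> list[int]:
        """Ring node ids in cyclic order (pendant excluded if present)."""
        g = self.topology.graph
        if self.topology.family == "ring_plus_pendant":
            for v in g.nodes:
                rest = g.subgraph([u for u in g.nodes if u != v])
                if rest.number_of_nodes() >= 3 and all(d == 2 for _, d in rest.degree()):
                    return _walk_cycle(rest)
            raise ValueError("no pendant node found in ring_plus_pendant topology")
        if self.topology.family == "ring":
            if g.number_of_nodes() <= 2:
                return list(g.nodes)
            return _walk_cycle(g)
        raise ValueError(f"ring order undefined for family {self.topology.family!r}")


def _walk_cycle(g: nx.Graph) -> list[int]:
    """Node ids of a 2-regular graph in cyclic traversal order."""
    start = min(g.nodes)
    order = [start]
    prev = None
    current = start
    while True:
        nxt = [u for u in g.neighbors(current) if u != prev]
        nxt = min(nxt) if prev is None else nxt[0]
        if nxt == start:
            return order
        order.append(nxt)
        prev, current = current, nxt


def mnx_ground_truth(seed: int = 0) -> GroundTruth:
    """Default truth: G1E3F3, alternating EFEFEF ring with pendant G.

    Subunit masses sum to 211,216 Da; E carries one tightly bound Cu with
    small spill to 0/2, F carries 0-2 Cu triangularly.
    """
    catalog = mnx_catalog()
    composition = Composition(counts={"MnxG": 1, "MnxE": 3, "MnxF": 3})
    composition.theoretical_mass = composition_mass(composition, catalog)
    arrangements = enumerate_arrangements(
        {"E": 3, "F": 3, "G": 1}, "ring_plus_pendant", pendant="G"
    )
    alternating = next(t for t in arrangements if t.canonical == "EFEFEF")
    return GroundTruth(
        catalog=catalog,
        composition=composition,
        topology=alternating,
        metal_occupancy={
            "MnxE": {0: 0.05, 1: 0.90, 2: 0.05},
            "MnxF": {0: 0.25, 1: 0.50, 2: 0.25},
        },
        seed=seed,
    )


def simulate_spectrum(
    truth: GroundTruth,
    z_center: int = 29,
    z_spread: int = 5,
    peak_fwhm_mz: float = 55.0,
    noise_rel: float = 0.0,
    seed: int = 0,
    mz_step: float | None = None,
) -> Spectrum:
    """Forward-model a profile native mass spectrum of the complex.

    ``z_spread`` counts the charge states in the envelope (1 means the
    single state ``z_center``; 9 around z_center=29 spans 25..33).
    Gaussian peaks appear at (M_k + z*m_p)/z for every charge state
    (envelope weights from a discretised Gaussian over z) and every
    total-metal variant mass M_k = M + k*metal_delta (weights from the
    occupancy convolution).  Uniform additive noise at ``noise_rel`` of
    the base peak; identical seeds give bit-identical spectra.
    """
    if z_spread < 1:
        raise ValueError("z_spread must be >= 1")
    if peak_fwhm_mz <= 0:
        raise ValueError("peak_fwhm_mz must be positive")
    rng = np.random.default_rng(seed)
    base_mass = truth.neutral_mass
    variants = truth.total_metal_distribution()
    charges = np.arange(
        z_center - (z_spread - 1) // 2, z_center + z_spread // 2 + 1
    )
    charges = charges[charges >= 1]
    z_sigma = max(z_spread / 3.0, 0.75)
    z_weights = np.exp(-0.5 * ((charges - z_center) / z_sigma) ** 2)
    z_weights /= z_weights.max()

    positions = []
    amplitudes = []
    for k, pk in variants.items():
        m_var = base_mass + k * truth.metal_delta
        for z, wz in zip(charges, z_weights):
            positions.append((m_var + z * PROTON_MASS) / z)
            amplitudes.append(pk * wz)
    positions = np.asarray(positions)
    amplitudes = np.asarray(amplitudes)

    sigma = peak_fwhm_mz / 2.3548200450309493
    step = peak_fwhm_mz / 50.0 if mz_step is None else mz_step
    lo = positions.min() - 5 * peak_fwhm_mz
    hi = positions.max() + 5 * peak_fwhm_mz
    grid = np.arange(lo, hi + step, step)
    inten = np.zeros_like(grid)
    for pos, amp in zip(positions, amplitudes):
        inten += amp * np.exp(-0.5 * ((grid - pos) / sigma) ** 2)
    if noise_rel > 0:
        inten += noise_rel * inten.max() * rng.uniform(0.0, 1.0, size=grid.size)
    return Spectrum(
        grid,
        inten,
        metadata={
            "source": "synthetic",
            "truth_mass": base_mass,
            "z_center": z_center,
            "seed": seed,
        },
    )


def _arc_labels(sequence: list[str], start: int, k: int) -> list[str]:
    m = len(sequence)
    return [sequence[(start + i) % m] for i in range(k)]


def simulate_dissociation(
    truth: GroundTruth,
    mode: str = "SID",
    n_events: int = 1000,
    energy: str = "high",
    seed: int = 0,
    p_retain_sid: float = 0.9,
    p_retain_cid: float = 0.1,
    tau: float = 1.5,
    thresholds: dict[str, float] | None = None,
) -> tuple[ObservationSet, pd.DataFrame]:
    """Simulate gas-phase dissociation fragment tables.

    * ``SID``/``low``  — pendant cleavage: every event releases the pendant
      subunit and the intact ring.
    * ``SID``/``high`` — samples contiguous ring arcs with size bias
      P(k) ~ exp(-|k - m/2|/tau), so every size from monomer to full ring
      appears; each bound metal is retained with ``p_retain_sid``.
    * ``CID`` — ejects a single unfolded monomer (uniform over ring nodes)
      plus the stripped residual complex; the monomer retains each bound
      metal only with ``p_retain_cid``.

    Returns the abundance-classed ObservationSet over fragment labels and
    the per-event fragment table (label, size, metals bound/retained, mass).
    """
    if mode not in {"SID", "CID"}:
        raise ValueError(f"unknown dissociation mode {mode!r}")
    if energy not in {"low", "high"}:
        raise ValueError(f"unknown energy level {energy!r}")
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    subunit = nx.get_node_attributes(truth.topology.graph, "subunit")
    mass_of_symbol = {e.display: e.mass for e in truth.catalog.entries}
    ring = truth.ring_nodes()
    sequence = [subunit[v] for v in ring]
    m = len(sequence)

    rows: list[dict] = []

    def draw_fragment(symbols: list[str], p_retain: float, event: int) -> None:
        bound = 0
        retained = 0
        for sym in symbols:
            occ = truth.node_occupancy(sym)
            ks = np.array(sorted(occ))
            ps = np.array([occ[k] for k in ks])
            k = int(rng.choice(ks, p=ps / ps.sum()))
            bound += k
            retained += int(rng.binomial(k, p_retain))
        label = format_label(dict(_count(symbols)))
        mass = sum(mass_of_symbol[s] for s in symbols) + retained * truth.metal_delta
        rows.append(
            {
                "event": event,
                "label": label,
                "size": len(symbols),
                "metals_bound": bound,
                "metals_retained": retained,
                "mass": mass,
            }
        )

    if mode == "SID" and energy == "low":
        products = primary_cleavage(truth.topology)
        pendant_sym = None
        if truth.topology.family == "ring_plus_pendant" and len(products) == 2:
            pendant_sym = products[0].rstrip("0123456789")
        for event in range(n_events):
            if pendant_sym is not None:
                draw_fragment([pendant_sym], p_retain_sid, event)
                draw_fragment(sequence, p_retain_sid, event)
            else:
                draw_fragment(sequence, p_retain_sid, event)
    elif mode == "SID":
        sizes = np.arange(1, m + 1)
        probs = np.exp(-np.abs(sizes - m / 2.0) / tau)
        probs /= probs.sum()
        for event in range(n_events):
            k = int(rng.choice(sizes, p=probs))
            start = int(rng.integers(0, m)) if k < m else 0
            draw_fragment(_arc_labels(sequence, start, k), p_retain_sid, event)
    else:  # CID
        for event in range(n_events):
            idx = int(rng.integers(0, m))
            draw_fragment([sequence[idx]], p_retain_cid, event)
            stripped = sequence[:idx] + sequence[idx + 1 :]
            if truth.topology.family == "ring_plus_pendant":
                pend = [s for s in primary_cleavage(truth.topology)[0] if s.isalpha()]
                stripped = stripped + ["".join(pend)]
            draw_fragment(stripped, 1.0, event)

    table = pd.DataFrame(rows)
    counts = table["label"].value_counts().to_dict()
    observed = classify_abundances(counts, thresholds)
    return observed, table


def _count(symbols: list[str]) -> dict[str, int]:
    out: dict[str, int] = {}
    for s in symbols:
        out[s] = out.get(s, 0) + 1
    return out


def simulate_calibrants(
    ln_a: float,
    b: float,
    edc: float = 1.57,
    gas_mass: float = 28.0134,
    n: int = 8,
    noise_rel: float = 0.0,
    seed: int = 0,
) -> list[CalibrantRecord]:
    """Draw calibrant records from a known power-law mobility calibration.

    Masses are log-uniform over 10-500 kDa with native-like charges; the
    corrected drift time is drawn uniformly in 2-14 ms and inverted
    through the forward model; ``noise_rel`` applies multiplicative
    Gaussian noise to the drift times.
    """
    if n < 2:
        raise ValueError("need n >= 2 calibrants")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        mass = float(10 ** rng.uniform(4.0, 5.7))
        z = max(1, int(round(0.078 * np.sqrt(mass))))
        t_prime = float(rng.uniform(2.0, 14.0))
        mu = mass * gas_mass / (mass + gas_mass)
        ccs = float(np.exp(ln_a) * t_prime**b * z / np.sqrt(mu))
        mz = (mass + z * PROTON_MASS) / z
        drift = t_prime + edc * np.sqrt(mz) / 1000.0
        if noise_rel > 0:
            drift *= 1.0 + noise_rel * float(rng.standard_normal())
        records.append(
            CalibrantRecord(
                name=f"cal_{i+1}", mass=mass, z=z, drift_time=float(drift), ccs_lit=ccs
            )
        )
    return records


def write_simulation(
    truth: GroundTruth,
    out_dir: str | Path,
    seed: int = 42,
    n_events: int = 2000,
    noise_rel: float = 0.005,
) -> dict[str, Path]:
    """Write a full synthetic data set (peaks, observations, fragments,
    calibrants, truth) for pipeline round-trips.

    The intact spectrum is written for the metal-stripped (apo) complex,
    mirroring the EDTA-treated preparation used for unambiguous
    stoichiometry assignment; the dissociation table carries the metals.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "peaks": out / "peaks.tsv",
        "observations": out / "observations.csv",
        "fragments": out / "fragments.csv",
        "calibrants": out / "calibrants.csv",
        "truth": out / "truth.json",
    }
    spectrum = simulate_spectrum(truth.apo(), noise_rel=noise_rel, seed=seed)
    write_peaklist(spectrum, paths["peaks"])

    observed, fragments = simulate_dissociation(
        truth, mode="SID", energy="high", n_events=n_events, seed=seed + 1
    )
    with open(paths["observations"], "w") as fh:
        fh.write("composition,class\n")
        for label, klass in sorted(observed.records.items()):
            fh.write(f"{label},{klass}\n")
    fragments.to_csv(paths["fragments"], index=False)

    calibrants = simulate_calibrants(
        ln_a=float(np.log(250.0)), b=0.55, n=8, noise_rel=0.0, seed=seed + 2
    )
    with open(paths["calibrants"], "w") as fh:
        fh.write("name,mass,z,drift_time_ms,ccs_A2\n")
        for rec in calibrants:
            fh.write(
                f"{rec.name},{rec.mass:.4f},{rec.z},{rec.drift_time:.6f},{rec.ccs_lit:.4f}\n"
            )

    truth_doc = {
        "seed": seed,
        "neutral_mass": truth.neutral_mass,
        "composition": truth.composition.counts,
        "composition_label": truth.composition.label(truth.catalog),
        "topology_family": truth.topology.family,
        "topology_canonical": truth.topology.canonical,
        "metal_occupancy": {
            k: {str(i): p for i, p in v.items()} for k, v in truth.metal_occupancy.items()
        },
        "catalog": {
            "subunits": [
                {
                    "name": e.name,
                    "mass": e.mass,
                    "min": e.min_copies,
                    "max": e.max_copies,
                    "symbol": e.display,
                }
                for e in truth.catalog.entries
            ],
            "adducts": [
                {"name": a.name, "delta": a.delta, "max_count": a.max_count}
                for a in truth.catalog.adducts
            ],
        },
    }
    paths["truth"].write_text(json.dumps(truth_doc, indent=2, sort_keys=True) + "\n")
    return paths
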