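"""Subunit-connectivity enumeration and SID fragment scoring.

Surface-induced dissociation (SID) cleaves a native complex at its weakest
inter-subunit interfaces, so the subcomplexes it releases are connected
pieces of the underlying connectivity graph.  This module enumerates
candidate arrangements of a given subunit composition (rings up to
bracelet symmetry, rings with a pendant subunit, trees, or arbitrary
connected graphs), predicts the multiset of connected induced subgraphs
each arrangement can release, and scores arrangements against an observed
fragment table classed by abundance.  Arrangements whose predicted pieces
include species that are conspicuously absent (e.g. homodimers from a
blocked ring) are penalised and fall in the ranking — the elimination
logic that identifies an alternating hexamer.

Composition labels are compact strings over subunit symbols, e.g.
``E2F1`` for a trimer of two E and one F; a missing count means 1.
"""

from __future__ import annotations

import csv
import itertools
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

__all__ = [
    "ABUNDANCE_CLASSES",
    "DEFAULT_WEIGHTS",
    "DEFAULT_CLASS_THRESHOLDS",
    "TopologyGraph",
    "FragmentPrediction",
    "ObservationSet",
    "TopologyScore",
    "parse_label",
    "format_label",
    "enumerate_arrangements",
    "predict_subcomplexes",
    "primary_cleavage",
    "score_topology",
    "rank_topologies",
    "classify_abundances",
]

ABUNDANCE_CLASSES = ("major", "minor", "trace", "absent")

#: Scoring matrix w(predicted?, class).  Predicted-but-absent species are
#: disqualifying evidence; unpredicted trace species are excusable as
#: secondary dissociation products.
DEFAULT_WEIGHTS: dict[tuple[bool, str], float] = {
    (True, "major"): 2.0,
    (True, "minor"): 1.0,
    (True, "trace"): 0.0,
    (True, "absent"): -2.0,
    (False, "major"): -3.0,
    (False, "minor"): -1.0,
    (False, "trace"): 0.0,
    (False, "absent"): 0.0,
}

#: Intensity fractions of the most abundant fragment defining each class.
DEFAULT_CLASS_THRESHOLDS = {"major": 0.20, "minor": 0.02, "trace": 0.005}

_FAMILY_BOUNDS = {"ring": 10, "ring_plus_pendant": 10, "tree": 7, "connected": 6}

_LABEL_RE = re.compile(r"([A-Z][a-z]*)(\d*)")


def parse_label(label: str) -> dict[str, int]:
    """Parse ``E2F1`` / ``G`` into subunit counts (symbols are an uppercase
    letter plus optional lowercase tail, chemical-formula style)."""
    label = label.strip()
    if not label:
        raise ValueError("empty composition label")
    counts: dict[str, int] = {}
    pos = 0
    for m in _LABEL_RE.finditer(label):
        if m.start() != pos:
            raise ValueError(f"malformed composition label {label!r}")
        name, digits = m.group(1), m.group(2)
        counts[name] = counts.get(name, 0) + (int(digits) if digits else 1)
        pos = m.end()
    if pos != len(label):
        raise ValueError(f"malformed composition label {label!r}")
    return counts


def format_label(counts: dict[str, int] | Counter) -> str:
    """Canonical label: symbols sorted, counts explicit (``G1E3F3`` -> ``E3F3G1``)."""
    return "".join(f"{s}{c}" for s, c in sorted(counts.items()) if c > 0)


@dataclass
class TopologyGraph:
    """A labeled connectivity graph; nodes carry a ``subunit`` attribute."""

    graph: nx.Graph
    family: str
    canonical: str = ""  # bracelet-canonical ring string where applicable

    def __post_init__(self) -> None:
        if self.graph.number_of_nodes() == 0:
            raise ValueError("topology must be non-empty")
        if self.graph.number_of_nodes() > 1 and not nx.is_connected(self.graph):
            raise ValueError("topology must be connected")
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("topology must be simple (no self-loops)")

    @property
    def n(self) -> int:
        return self.graph.number_of_nodes()

    def composition(self) -> dict[str, int]:
        return dict(Counter(nx.get_node_attributes(self.graph, "subunit").values()))

    def label(self) -> str:
        return format_label(self.composition())


@dataclass
class FragmentPrediction:
    """Multiset of connected-subcomplex compositions a topology can release."""

    multiset: dict[str, int]
    by_size: dict[int, dict[str, int]]

    @property
    def labels(self) -> set[str]:
        return set(self.multiset)


@dataclass
class ObservationSet:
    """Observed fragment compositions, each with an abundance class."""

    records: dict[str, str]

    def __post_init__(self) -> None:
        canonical: dict[str, str] = {}
        for label, cls in self.records.items():
            if cls not in ABUNDANCE_CLASSES:
                raise ValueError(f"unknown abundance class {cls!r} for {label!r}")
            canonical[format_label(parse_label(label))] = cls
        self.records = canonical

    @classmethod
    def from_csv(cls, path: str | Path) -> "ObservationSet":
        records: dict[str, str] = {}
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            for lineno, row in enumerate(reader, start=1):
                if not row or row[0].strip().startswith("#"):
                    continue
                if lineno == 1 and row[0].strip().lower() in {"composition", "label"}:
                    continue
                if len(row) < 2:
                    raise ValueError(f"{path}: line {lineno}: expected 'composition,class'")
                label, klass = row[0].strip(), row[1].strip().lower()
                if klass not in ABUNDANCE_CLASSES:
                    raise ValueError(
                        f"{path}: line {lineno}: unknown abundance class {klass!r}"
                    )
                try:
                    parse_label(label)
                except ValueError as exc:
                    raise ValueError(f"{path}: line {lineno}: {exc}") from None
                records[label] = klass
        return cls(records)

    def klass(self, label: str) -> str:
        return self.records.get(label, "absent")


@dataclass
class TopologyScore:
    total: float
    per_composition: dict[str, float]
    rank: int = 0


def classify_abundances(
    intensities: dict[str, float],
    thresholds: dict[str, float] | None = None,
) -> ObservationSet:
    """Turn raw fragment intensities (or counts) into abundance classes.

    Classes are relative to the most intense fragment: major >= 20%,
    minor >= 2%, trace >= 0.5%, else absent (defaults; configurable).
    """
    th = dict(DEFAULT_CLASS_THRESHOLDS if thresholds is None else thresholds)
    if not intensities:
        return ObservationSet({})
    top = max(intensities.values())
    if top <= 0:
        return ObservationSet({})
    records = {}
    for label, inten in intensities.items():
        f = inten / top
        if f >= th["major"]:
            records[label] = "major"
        elif f >= th["minor"]:
            records[label] = "minor"
        elif f >= th["trace"]:
            records[label] = "trace"
        else:
            records[label] = "absent"
    return ObservationSet(records)


# ---------------------------------------------------------------------------
# Arrangement enumeration


def _bracelet_canonical(seq: tuple[str, ...]) -> tuple[str, ...]:
    """Lexicographically smallest string over all rotations and reflections."""
    n = len(seq)
    best = None
    for s in (seq, seq[::-1]):
        for r in range(n):
            cand = s[r:] + s[:r]
            if best is None or cand < best:
                best = cand
    return best


def _ring_graph(seq: tuple[str, ...]) -> nx.Graph:
    n = len(seq)
    if n == 1:
        g = nx.Graph()
        g.add_node(0, subunit=seq[0])
        return g
    if n == 2:
        g = nx.Graph()
        g.add_node(0, subunit=seq[0])
        g.add_node(1, subunit=seq[1])
        g.add_edge(0, 1)
        return g
    g = nx.cycle_graph(n)
    for i, s in enumerate(seq):
        g.nodes[i]["subunit"] = s
    return g


def _enumerate_bracelets(counts: dict[str, int]) -> list[tuple[str, ...]]:
    beads: list[str] = []
    for s, c in sorted(counts.items()):
        beads.extend([s] * c)
    seen: set[tuple[str, ...]] = set()
    for perm in set(itertools.permutations(beads)):
        seen.add(_bracelet_canonical(perm))
    return sorted(seen)


def _iso_dedupe(graphs: list[nx.Graph]) -> list[nx.Graph]:
    """Deduplicate by label-respecting graph isomorphism (deterministic order)."""
    nm = nx.algorithms.isomorphism.categorical_node_match("subunit", None)
    kept: list[nx.Graph] = []
    for g in graphs:
        if not any(nx.is_isomorphic(g, h, node_match=nm) for h in kept):
            kept.append(g)
    return kept


def enumerate_arrangements(
    counts: dict[str, int],
    family: str = "ring",
    pendant: str | None = None,
    pendant_degree: int | None = None,
) -> list[TopologyGraph]:
    """One representative per label-respecting isomorphism class.

    ``counts`` maps subunit symbols to copy numbers.  For rings the
    equivalence is bracelet equivalence (rotation + reflection) and the
    representative carries the lexicographically smallest ring string.
    For ``ring_plus_pendant`` the subunit named ``pendant`` (count 1) is
    attached to ``pendant_degree`` contiguous ring positions (default:
    all of them, a single super-interface).  ``tree`` and ``connected``
    enumerate via Pruefer sequences / edge subsets with isomorphism
    deduplication.
    """
    counts = {s: c for s, c in counts.items() if c > 0}
    n = sum(counts.values())
    if n == 0:
        raise ValueError("empty composition")
    if family not in _FAMILY_BOUNDS:
        raise ValueError(f"unsupported family {family!r}")
    bound = _FAMILY_BOUNDS[family]
    if n > bound:
        raise ValueError(f"family {family!r} supports at most {bound} subunits, got {n}")

    if n == 1:
        g = nx.Graph()
        g.add_node(0, subunit=next(iter(counts)))
        return [TopologyGraph(g, family, canonical=format_label(counts))]

    if family == "ring":
        return [
            TopologyGraph(_ring_graph(seq), "ring", canonical="".join(seq))
            for seq in _enumerate_bracelets(counts)
        ]

    if family == "ring_plus_pendant":
        if pendant is None or counts.get(pendant) != 1:
            raise ValueError("ring_plus_pendant requires a pendant subunit with count 1")
        ring_counts = {s: c for s, c in counts.items() if s != pendant}
        m = sum(ring_counts.values())
        if m == 0:
            raise ValueError("pendant requires at least one ring subunit")
        k = m if pendant_degree is None else pendant_degree
        if not (1 <= k <= m):
            raise ValueError("pendant_degree must be in [1, ring size]")
        candidates: list[tuple[nx.Graph, str]] = []
        for seq in _enumerate_bracelets(ring_counts):
            for start in range(m if k < m else 1):
                g = _ring_graph(seq)
                g.add_node(m, subunit=pendant)
                for off in range(k):
                    g.add_edge(m, (start + off) % m)
                candidates.append((g, "".join(seq)))
        graphs = _iso_dedupe([g for g, _ in candidates])
        out = []
        for g in graphs:
            canon = next(c for h, c in candidates if h is g)
            out.append(TopologyGraph(g, "ring_plus_pendant", canonical=canon))
        return out

    # general families: build labeled node list deterministically
    labels: list[str] = []
    for s, c in sorted(counts.items()):
        labels.extend([s] * c)

    if family == "tree":
        graphs = []
        for pruefer in itertools.product(range(n), repeat=n - 2):
            g = nx.from_prufer_sequence(list(pruefer))
            for i, s in enumerate(labels):
                g.nodes[i]["subunit"] = s
            graphs.append(g)
        kept = _iso_dedupe(graphs)
        return [TopologyGraph(g, "tree") for g in kept]

    # connected: all simple connected graphs on the labeled nodes
    all_edges = list(itertools.combinations(range(n), 2))
    graphs = []
    for r in range(n - 1, len(all_edges) + 1):
        for subset in itertools.combinations(all_edges, r):
            g = nx.Graph(subset)
            if g.number_of_nodes() != n or not nx.is_connected(g):
                continue
            for i, s in enumerate(labels):
                g.nodes[i]["subunit"] = s
            graphs.append(g)
    kept = _iso_dedupe(graphs)
    return [TopologyGraph(g, "connected") for g in kept]


# ---------------------------------------------------------------------------
# Fragment prediction and scoring


def predict_subcomplexes(topology: TopologyGraph) -> FragmentPrediction:
    """All connected induced subgraphs, as a composition multiset.

    For a ring these are exactly the contiguous arcs: n pieces of every
    size 1 <= k < n plus the full ring once.
    """
    g = topology.graph
    nodes = list(g.nodes)
    subunit = nx.get_node_attributes(g, "subunit")
    multiset: Counter = Counter()
    by_size: dict[int, Counter] = {}
    for k in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, k):
            sub = g.subgraph(subset)
            if k > 1 and not nx.is_connected(sub):
                continue
            label = format_label(Counter(subunit[v] for v in subset))
            multiset[label] += 1
            by_size.setdefault(k, Counter())[label] += 1
    return FragmentPrediction(
        multiset=dict(multiset), by_size={k: dict(v) for k, v in by_size.items()}
    )


def primary_cleavage(topology: TopologyGraph) -> list[str]:
    """Products of cleaving the weakest interface first.

    For a ring-plus-pendant arrangement the pendant's super-interface is
    assumed weakest, so low-energy SID releases the pendant and the intact
    ring: labels [pendant, ring].  Other families return the full complex.
    """
    if topology.family != "ring_plus_pendant":
        return [topology.label()]
    subunit = nx.get_node_attributes(topology.graph, "subunit")
    # the pendant is the unique node whose removal leaves a 2-regular ring
    for v in topology.graph.nodes:
        rest = topology.graph.subgraph([u for u in topology.graph.nodes if u != v])
        if rest.number_of_nodes() >= 3 and all(d == 2 for _, d in rest.degree()):
            pend = format_label({subunit[v]: 1})
            ring = format_label(Counter(subunit[u] for u in rest.nodes))
            return [pend, ring]
    return [topology.label()]


def _sub_composition(inner: dict[str, int], outer: dict[str, int]) -> bool:
    return all(outer.get(s, 0) >= c for s, c in inner.items())


def score_topology(
    prediction: FragmentPrediction,
    observed: ObservationSet,
    weights: dict[tuple[bool, str], float] | None = None,
    secondary_dissociation: bool = False,
) -> TopologyScore:
    """Score a predicted fragment set against classed observations.

    total = sum over the union of predicted and observed labels of
    w(predicted?, class); labels predicted but not observed count as class
    "absent".  With ``secondary_dissociation`` on, unpredicted trace
    species that are sub-compositions of a predicted fragment contribute
    exactly 0 (they are plausibly second-generation pieces).
    """
    w = DEFAULT_WEIGHTS if weights is None else weights
    labels = set(prediction.labels) | set(observed.records)
    per: dict[str, float] = {}
    for label in sorted(labels):
        predicted = label in prediction.labels
        klass = observed.klass(label)
        if (
            secondary_dissociation
            and not predicted
            and klass == "trace"
            and any(
                _sub_composition(parse_label(label), parse_label(p))
                for p in prediction.labels
            )
        ):
            per[label] = 0.0
            continue
        try:
            per[label] = w[(predicted, klass)]
        except KeyError:
            raise ValueError(
                f"weights undefined for (predicted={predicted}, {klass!r})"
            ) from None
    return TopologyScore(total=sum(per.values()), per_composition=per)


def rank_topologies(
    counts: dict[str, int],
    family: str,
    observed: ObservationSet,
    weights: dict[tuple[bool, str], float] | None = None,
    secondary_dissociation: bool = False,
    pendant: str | None = None,
    pendant_degree: int | None = None,
) -> list[tuple[TopologyGraph, TopologyScore]]:
    """Enumerate, predict, score, and sort descending by score.

    Ties break on the canonical arrangement string so the ranking is
    deterministic.
    """
    arrangements = enumerate_arrangements(
        counts, family, pendant=pendant, pendant_degree=pendant_degree
    )
    scored = []
    for topo in arrangements:
        pred = predict_subcomplexes(topo)
        score = score_topology(pred, observed, weights, secondary_dissociation)
        scored.append((topo, score))
    scored.sort(key=lambda ts: (-ts[1].total, ts[0].canonical, ts[0].label()))
    for rank, (_, score) in enumerate(scored, start=1):
        score.rank = rank
    return scored
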