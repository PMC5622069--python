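import itertools
from collections import Counter

import networkx as nx
import pytest

from quatmass.topology import (
    DEFAULT_WEIGHTS,
    ObservationSet,
    TopologyGraph,
    classify_abundances,
    enumerate_arrangements,
    format_label,
    parse_label,
    predict_subcomplexes,
    primary_cleavage,
    rank_topologies,
    score_topology,
)


def bracelet_orbit_count(counts: dict[str, int]) -> int:
    """Independent oracle: count orbits of labeled ring strings under the
    dihedral group, by grouping every string into its full orbit set."""
    beads = []
    for s, c in sorted(counts.items()):
        beads.extend([s] * c)
    orbits = set()
    for perm in set(itertools.permutations(beads)):
        orbit = set()
        for s in (perm, perm[::-1]):
            for r in range(len(s)):
                orbit.add(s[r:] + s[:r])
        orbits.add(frozenset(orbit))
    return len(orbits)


class TestLabels:
    @pytest.mark.parametrize(
        "label,expected",
        [
            ("E1F1", {"E": 1, "F": 1}),
            ("G", {"G": 1}),
            ("E2F3", {"E": 2, "F": 3}),
            ("Cu2E1", {"Cu": 2, "E": 1}),
        ],
    )
    def test_parse(self, label, expected):
        assert parse_label(label) == expected

    def test_parse_rejects_garbage(self):
        with pytest.raises(ValueError):
            parse_label("3E")
        with pytest.raises(ValueError):
            parse_label("")

    def test_format_canonical(self):
        assert format_label({"G": 1, "E": 3, "F": 3}) == "E3F3G1"


class TestEnumerateArrangements:
    def test_hexamer_bracelets(self):
        arrs = enumerate_arrangements({"E": 3, "F": 3}, "ring")
        assert [a.canonical for a in arrs] == ["EEEFFF", "EEFEFF", "EFEFEF"]

    def test_tetramer_bracelets(self):
        arrs = enumerate_arrangements({"E": 2, "F": 2}, "ring")
        assert [a.canonical for a in arrs] == ["EEFF", "EFEF"]

    def test_single_subunit(self):
        arrs = enumerate_arrangements({"G": 1}, "ring")
        assert len(arrs) == 1
        assert arrs[0].n == 1

    def test_bracelet_counts_match_orbit_oracle(self):
        for n in range(2, 9):
            for k in range(0, n + 1):
                counts = {"E": k, "F": n - k}
                got = len(enumerate_arrangements(counts, "ring"))
                assert got == bracelet_orbit_count(counts), (n, k)

    def test_size_bound_refused(self):
        with pytest.raises(ValueError, match="at most"):
            enumerate_arrangements({"E": 6, "F": 6}, "ring")

    def test_pendant_requires_unique_pendant(self):
        with pytest.raises(ValueError):
            enumerate_arrangements({"E": 3, "F": 3, "G": 2}, "ring_plus_pendant", pendant="G")

    def test_pendant_hexamer(self):
        arrs = enumerate_arrangements(
            {"E": 3, "F": 3, "G": 1}, "ring_plus_pendant", pendant="G"
        )
        assert sorted(a.canonical for a in arrs) == ["EEEFFF", "EEFEFF", "EFEFEF"]
        for a in arrs:
            assert a.composition() == {"E": 3, "F": 3, "G": 1}

    def test_tree_family_distinct_from_ring(self):
        # 4 nodes: trees are paths and stars, never cycles
        arrs = enumerate_arrangements({"A": 4}, "tree")
        assert len(arrs) == 2  # path and star on 4 identical nodes
        for a in arrs:
            assert a.graph.number_of_edges() == 3

    def test_connected_family_triangle(self):
        arrs = enumerate_arrangements({"A": 3}, "connected")
        # path and triangle
        assert len(arrs) == 2


class TestPredictSubcomplexes:
    def test_alternating_ring_arcs(self):
        alt = next(
            a
            for a in enumerate_arrangements({"E": 3, "F": 3}, "ring")
            if a.canonical == "EFEFEF"
        )
        pred = predict_subcomplexes(alt)
        assert pred.by_size == {
            1: {"E1": 3, "F1": 3},
            2: {"E1F1": 6},
            3: {"E2F1": 3, "E1F2": 3},
            4: {"E2F2": 6},
            5: {"E3F2": 3, "E2F3": 3},
            6: {"E3F3": 1},
        }

    def test_blocked_ring_dimers(self):
        blocked = next(
            a
            for a in enumerate_arrangements({"E": 3, "F": 3}, "ring")
            if a.canonical == "EEEFFF"
        )
        pred = predict_subcomplexes(blocked)
        assert pred.by_size[2] == {"E2": 2, "E1F1": 2, "F2": 2}

    def test_single_node(self):
        g = nx.Graph()
        g.add_node(0, subunit="G")
        pred = predict_subcomplexes(TopologyGraph(g, "ring"))
        assert pred.multiset == {"G1": 1}

    def test_ring_arc_count_identity(self):
        # an n-ring has exactly n connected pieces of every size k < n, and 1 of size n
        for arrangement in enumerate_arrangements({"E": 2, "F": 3}, "ring"):
            pred = predict_subcomplexes(arrangement)
            n = arrangement.n
            for k in range(1, n):
                assert sum(pred.by_size[k].values()) == n
            assert sum(pred.by_size[n].values()) == 1

    def test_invariance_under_ring_relabeling(self):
        seq = ("E", "F", "E", "F", "E", "F")
        def ring_of(order):
            g = nx.cycle_graph(6)
            for i, s in enumerate(order):
                g.nodes[i]["subunit"] = s
            return TopologyGraph(g, "ring")

        base = predict_subcomplexes(ring_of(seq))
        rotated = predict_subcomplexes(ring_of(seq[2:] + seq[:2]))
        reflected = predict_subcomplexes(ring_of(seq[::-1]))
        assert base.multiset == rotated.multiset == reflected.multiset

    def test_complement_closure_on_rings(self):
        for arrangement in enumerate_arrangements({"E": 3, "F": 3}, "ring"):
            pred = predict_subcomplexes(arrangement)
            full = Counter(parse_label(arrangement.label()))
            for label in pred.labels:
                comp = Counter(full) - Counter(parse_label(label))
                comp_label = format_label(dict(comp))
                if sum(comp.values()) > 0:
                    assert comp_label in pred.labels, (arrangement.canonical, label)


class TestScoring:
    def test_perfect_agreement_is_maximal(self):
        alt = next(
            a
            for a in enumerate_arrangements({"E": 3, "F": 3}, "ring")
            if a.canonical == "EFEFEF"
        )
        pred = predict_subcomplexes(alt)
        perfect = ObservationSet({label: "major" for label in pred.labels})
        best = score_topology(pred, perfect).total
        assert best == len(pred.labels) * DEFAULT_WEIGHTS[(True, "major")]
        # any degraded observation scores no higher
        for label in pred.labels:
            worse = dict(perfect.records)
            worse[label] = "absent"
            assert score_topology(pred, ObservationSet(worse)).total < best

    def test_alternating_ring_wins_on_sid_observations(self, sid_observations):
        ranking = rank_topologies({"E": 3, "F": 3}, "ring", sid_observations)
        assert ranking[0][0].canonical == "EFEFEF"
        assert ranking[0][1].total > ranking[1][1].total  # strictly highest

    def test_blocked_ring_penalised_for_absent_homodimers(self, sid_observations):
        blocked = next(
            a
            for a in enumerate_arrangements({"E": 3, "F": 3}, "ring")
            if a.canonical == "EEEFFF"
        )
        score = score_topology(predict_subcomplexes(blocked), sid_observations)
        assert score.per_composition["E2"] == DEFAULT_WEIGHTS[(True, "absent")]
        assert score.per_composition["E3"] == DEFAULT_WEIGHTS[(True, "absent")]
        assert score.total < 0

    def test_score_additivity(self, sid_observations):
        alt = next(
            a
            for a in enumerate_arrangements({"E": 3, "F": 3}, "ring")
            if a.canonical == "EFEFEF"
        )
        pred = predict_subcomplexes(alt)
        full = score_topology(pred, sid_observations)
        assert full.total == pytest.approx(sum(full.per_composition.values()))
        # removing one observed-only label changes the total by its contribution
        reduced = dict(sid_observations.records)
        removed = reduced.pop("E3F1")
        partial = score_topology(pred, ObservationSet(reduced))
        delta = full.total - partial.total
        assert delta == pytest.approx(full.per_composition["E3F1"])

    def test_secondary_dissociation_neutralises_trace_subpieces(self):
        alt = next(
            a
            for a in enumerate_arrangements({"E": 3, "F": 3}, "ring")
            if a.canonical == "EFEFEF"
        )
        pred = predict_subcomplexes(alt)
        obs = ObservationSet({"E3F3": "major", "F2": "trace"})
        harsh = {**DEFAULT_WEIGHTS, (False, "trace"): -5.0}
        with_flag = score_topology(pred, obs, harsh, secondary_dissociation=True)
        without = score_topology(pred, obs, harsh, secondary_dissociation=False)
        assert with_flag.per_composition["F2"] == 0.0
        assert without.per_composition["F2"] == -5.0

    def test_self_consistency_rank(self):
        blocked = next(
            a
            for a in enumerate_arrangements({"E": 3, "F": 3}, "ring")
            if a.canonical == "EEEFFF"
        )
        obs = ObservationSet(
            {label: "major" for label in predict_subcomplexes(blocked).labels}
        )
        ranking = rank_topologies({"E": 3, "F": 3}, "ring", obs)
        assert ranking[0][0].canonical == "EEEFFF"


class TestPrimaryCleavage:
    def test_pendant_cleaves_first(self):
        arrs = enumerate_arrangements(
            {"E": 3, "F": 3, "G": 1}, "ring_plus_pendant", pendant="G"
        )
        alt = next(a for a in arrs if a.canonical == "EFEFEF")
        assert primary_cleavage(alt) == ["G1", "E3F3"]

    def test_plain_ring_has_no_pendant(self):
        alt = enumerate_arrangements({"E": 3, "F": 3}, "ring")[2]
        assert primary_cleavage(alt) == ["E3F3"]


class TestObservationSet:
    def test_from_csv_with_header(self, tmp_path):
        f = tmp_path / "obs.csv"
        f.write_text("composition,class\nE1F1,major\nE2,absent\n")
        obs = ObservationSet.from_csv(f)
        assert obs.records == {"E1F1": "major", "E2": "absent"}

    def test_bad_class_names_line(self, tmp_path):
        f = tmp_path / "obs.csv"
        f.write_text("composition,class\nE1F1,huge\n")
        with pytest.raises(ValueError, match="line 2"):
            ObservationSet.from_csv(f)

    def test_classify_thresholds(self):
        obs = classify_abundances({"A1": 100.0, "B1": 30.0, "C1": 5.0, "D1": 1.0, "E1": 0.1})
        assert obs.records == {
            "A1": "major",
            "B1": "major",
            "C1": "minor",
            "D1": "trace",
            "E1": "absent",
        }
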