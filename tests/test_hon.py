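"""Higher-order rule extraction, wiring, and port collapse."""

from __future__ import annotations

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from sfhon.core import Trajectory, Visit
from sfhon.hon import (
    Rule, collapse_to_ports, extract_rules, node_label, path_risk, port_of,
    read_rules, wire_network, write_rules,
)
from sfhon.networks import build_fon


def traj(ship, ports):
    return Trajectory(ship_id=ship, visits=[Visit(p, None, None) for p in ports])


class TestPathRisk:
    def test_single_edge_path(self):
        assert path_risk(["C", "A"], {("C", "A"): 0.1}) == pytest.approx(0.1, rel=1e-12)

    def test_two_edge_union(self):
        risks = {("C", "A"): 0.1, ("A", "E"): 0.2}
        assert path_risk(["C", "A", "E"], risks) == pytest.approx(0.28, rel=1e-12)

    def test_certain_edge_absorbs(self):
        risks = {("A", "B"): 1.0, ("B", "C"): 0.1}
        assert path_risk(["A", "B", "C"], risks) == 1.0

    def test_short_path_rejected(self):
        with pytest.raises(ValueError):
            path_risk(["A"], {})

    @given(st.lists(st.floats(0, 0.99), min_size=1, max_size=8))
    @settings(max_examples=200, deadline=None)
    def test_matches_inclusion_exclusion_oracle(self, edge_probs):
        ports = [f"P{i}" for i in range(len(edge_probs) + 1)]
        risks = {(a, b): p for (a, b), p in
                 zip(zip(ports, ports[1:]), edge_probs)}
        # inclusion-exclusion over nonempty subsets of edges
        oracle = 0.0
        for k in range(1, len(edge_probs) + 1):
            for sub in itertools.combinations(edge_probs, k):
                term = 1.0
                for p in sub:
                    term *= p
                oracle += (-1) ** (k + 1) * term
        assert path_risk(ports, risks) == pytest.approx(oracle, abs=1e-12)

    @given(st.lists(st.floats(0, 0.99), min_size=2, max_size=8))
    @settings(max_examples=200, deadline=None)
    def test_extension_never_decreases_risk(self, edge_probs):
        ports = [f"P{i}" for i in range(len(edge_probs) + 1)]
        risks = {(a, b): p for (a, b), p in
                 zip(zip(ports, ports[1:]), edge_probs)}
        assert path_risk(ports, risks) >= path_risk(ports[1:], risks) - 1e-15


class TestExtractRules:
    def test_support_gate(self):
        # a second-order pattern occurring min_support - 1 times is absent
        risks = {("C", "A"): 0.3, ("A", "E"): 0.3, ("B", "A"): 0.3}
        trajs = [traj(f"s{i}", ["C", "A", "E"]) for i in range(4)]
        rules = extract_rules(trajs, risks, min_support=5)
        assert all(r.order == 1 for r in rules) and not rules
        rules = extract_rules(trajs * 2, risks, min_support=5)
        assert any(r.order == 2 for r in rules)

    def test_planted_dependency_recovered(self):
        # ships from C via A continue to E; the (C,A) edge carries risk
        risks = {("C", "A"): 0.2, ("A", "E"): 0.2, ("B", "A"): 0.0, ("A", "F"): 0.2}
        trajs = [traj(f"c{i}", ["C", "A", "E"]) for i in range(20)]
        trajs += [traj(f"b{i}", ["B", "A", "F"]) for i in range(20)]
        rules = extract_rules(trajs, risks, min_support=5, threshold=0.1)
        assert (("C", "A"), "E") in {(r.context, r.next) for r in rules if r.order == 2}
        # the (B,A) context carries no risk, so it is never extended
        assert (("B", "A"), "F") not in {(r.context, r.next) for r in rules}

    def test_rule_probability_is_pathway_union(self):
        risks = {("C", "A"): 0.1, ("A", "E"): 0.2}
        trajs = [traj(f"s{i}", ["C", "A", "E"]) for i in range(10)]
        rules = {(r.context, r.next): r for r in extract_rules(trajs, risks)}
        assert rules[(("C", "A"), "E")].probability == pytest.approx(0.28, rel=1e-12)
        assert rules[(("C", "A"), "E")].support == 10

    def test_suffix_monotonicity(self):
        import numpy as np
        rng = np.random.default_rng(7)
        ports = [f"P{i}" for i in range(6)]
        risks = {(a, b): float(rng.uniform(0, 0.4))
                 for a in ports for b in ports if a != b}
        seqs = [list(rng.choice(ports, size=6)) for _ in range(60)]
        trajs = [traj(f"s{i}", s) for i, s in enumerate(seqs)]
        rules = extract_rules(trajs, risks, min_support=2, threshold=0.01)
        by_key = {(r.context, r.next): r.probability for r in rules}
        for (ctx, nxt), p in by_key.items():
            if len(ctx) > 1 and (ctx[1:], nxt) in by_key:
                assert p >= by_key[(ctx[1:], nxt)] - 1e-15

    def test_infinite_threshold_keeps_only_first_order(self):
        risks = {("C", "A"): 0.5, ("A", "E"): 0.5}
        trajs = [traj(f"s{i}", ["C", "A", "E"]) for i in range(10)]
        rules = extract_rules(trajs, risks, threshold=1e18)
        assert rules and all(r.order == 1 for r in rules)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            extract_rules([], {}, threshold=-0.1)
        with pytest.raises(ValueError):
            extract_rules([], {}, criterion="kl")

    def test_absolute_criterion_extends_zero_risk_contexts(self):
        # under the absolute criterion a risky preceding edge can extend a
        # context whose own pathway carries no risk
        risks = {("C", "A"): 0.2, ("A", "E"): 0.0}
        trajs = [traj(f"s{i}", ["C", "A", "E"]) for i in range(10)]
        rel = extract_rules(trajs, risks, criterion="relative")
        ab = extract_rules(trajs, risks, criterion="absolute", threshold=0.05)
        assert all(r.order == 1 for r in rel)
        assert (("C", "A"), "E") in {(r.context, r.next) for r in ab}

    def test_deterministic_across_input_order(self):
        risks = {("C", "A"): 0.2, ("A", "E"): 0.2, ("X", "Y"): 0.1}
        trajs = [traj(f"s{i}", ["C", "A", "E"]) for i in range(10)] \
            + [traj(f"t{i}", ["X", "Y"]) for i in range(6)]
        r1 = extract_rules(trajs, risks)
        r2 = extract_rules(list(reversed(trajs)), risks)
        assert r1 == r2


class TestWireNetwork:
    def test_worked_example_third_order_rule(self):
        # P({p0,p1,p2 -> p3}) = 0.5 becomes edge p2|p0,p1 -> p3, weight 0.5
        rules = [Rule(context=("p0", "p1", "p2"), next="p3", probability=0.5, support=9)]
        g = wire_network(rules)
        assert g.has_edge("p2|p0,p1", "p3")
        assert g["p2|p0,p1"]["p3"]["weight"] == 0.5
        assert port_of(g, "p2|p0,p1") == "p2"

    def test_first_order_rules_reproduce_fon(self):
        import pandas as pd
        risks = [("A", "B", 0.1), ("B", "C", 0.2)]
        rules = [Rule(context=(s,), next=d, probability=w, support=5)
                 for s, d, w in risks]
        g = wire_network(rules)
        fon = build_fon(pd.DataFrame(risks, columns=["source", "dest", "p_spread"]))
        assert set(g.edges) == set(fon.edges)
        for e in g.edges:
            assert g.edges[e]["weight"] == fon.edges[e]["weight"]

    def test_target_is_highest_order_suffix_node(self):
        # after the edge (A|C) -> E, the walker knows history (A, E); if the
        # context (A, E) exists as a rule context, the edge must land on E|A
        rules = [
            Rule(context=("C", "A"), next="E", probability=0.3, support=5),
            Rule(context=("A", "E"), next="F", probability=0.4, support=5),
            Rule(context=("A",), next="E", probability=0.2, support=9),
        ]
        g = wire_network(rules)
        assert g.has_edge("A|C", "E|A")
        assert g.has_edge("A", "E|A")

    def test_wiring_deterministic_under_rule_order(self):
        rules = [
            Rule(context=("C", "A"), next="E", probability=0.3, support=5),
            Rule(context=("A",), next="E", probability=0.2, support=9),
            Rule(context=("B",), next="A", probability=0.1, support=7),
        ]
        g1 = wire_network(rules)
        g2 = wire_network(list(reversed(rules)))
        assert sorted(g1.edges(data="weight")) == sorted(g2.edges(data="weight"))
        assert sorted(g1.nodes) == sorted(g2.nodes)


class TestCollapse:
    def test_single_node_per_port_is_identity(self):
        rules = [Rule(context=("A",), next="B", probability=0.25, support=5)]
        pairs, in_risk = collapse_to_ports(wire_network(rules))
        assert pairs == {("A", "B"): 0.25}
        assert in_risk["B"] == 0.25

    def test_parallel_edges_union(self):
        # X and X|A are the same physical port, so their edges to B combine
        rules = [
            Rule(context=("X",), next="B", probability=0.5, support=5),
            Rule(context=("A", "X"), next="B", probability=0.5, support=5),
        ]
        pairs, _ = collapse_to_ports(wire_network(rules))
        assert pairs[("X", "B")] == pytest.approx(0.75, rel=1e-12)

    def test_union_matches_exhaustive_enumeration(self):
        import numpy as np
        rng = np.random.default_rng(3)
        ws = [float(w) for w in rng.uniform(0, 0.9, size=6)]
        rules = [Rule(context=("A", f"X{i}"), next="B", probability=w, support=5)
                 for i, w in enumerate(ws)]
        hon = wire_network(rules)
        _, in_risk = collapse_to_ports(hon)
        # brute force: enumerate all 2^6 outcomes
        oracle = 0.0
        for mask in range(1, 2 ** 6):
            prob = 1.0
            for i, w in enumerate(ws):
                prob *= w if (mask >> i) & 1 else (1.0 - w)
            oracle += prob
        assert in_risk["B"] == pytest.approx(oracle, abs=1e-12)

    def test_mean_and_sum_modes(self):
        rules = [
            Rule(context=("A",), next="B", probability=0.2, support=5),
            Rule(context=("A", "X"), next="B", probability=0.4, support=5),
        ]
        hon = wire_network(rules)
        _, mean_risk = collapse_to_ports(hon, mode="mean")
        _, sum_risk = collapse_to_ports(hon, mode="sum")
        assert mean_risk["B"] == pytest.approx(0.3)
        assert sum_risk["B"] == pytest.approx(0.6)
        with pytest.raises(ValueError):
            collapse_to_ports(hon, mode="median")


class TestRuleSerialization:
    def test_roundtrip(self, tmp_path):
        rules = [
            Rule(context=("A",), next="B", probability=0.125, support=7),
            Rule(context=("C", "A"), next="B", probability=0.25, support=5),
        ]
        f = tmp_path / "rules.csv"
        write_rules(rules, f)
        assert read_rules(f) == rules

    def test_node_label_grammar(self):
        assert node_label(("A",)) == "A"
        assert node_label(("p0", "p1", "p2")) == "p2|p0,p1"
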