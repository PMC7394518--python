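"""Higher-order network construction from risk-weighted ship trajectories.

A *rule* is a dependency ``context -> next``: the spread risk of the pathway
ending at the context's current port and continuing to ``next``, where the
context records the ports visited beforehand. Rules are extracted from the
trajectory corpus bottom-up: every observed first-order transition with
enough support is a rule; a rule's context is extended one port further back
whenever the extended pathway (a) recurs at least ``min_support`` times in
the corpus and (b) raises the pathway spread risk by more than a relative
``threshold`` — so only recurring, risk-significant histories survive.

Extracted rules are wired into a higher-order network whose nodes are ports
annotated with visiting history (``p2|p0,p1`` = port p2 for ships that came
via p0 then p1); several such nodes can map to one physical port.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .core import Trajectory

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Rule:
    """An extracted dependency: ``context`` (oldest -> current) to ``next``."""

    context: tuple[str, ...]
    next: str
    probability: float  # spread risk of the context-plus-next pathway
    support: int        # corpus traversals matching context then next

    @property
    def order(self) -> int:
        return len(self.context)

    @property
    def current(self) -> str:
        return self.context[-1]


def path_risk(path, edge_risk: dict[tuple[str, str], float]) -> float:
    """Union spread probability over the consecutive edges of a port path.

    Edges absent from the lookup count as zero risk. A two-port path reduces
    to the edge risk itself.
    """
    path = list(path)
    if len(path) < 2:
        raise ValueError("path needs at least two ports")
    total = 0.0
    for a, b in zip(path, path[1:]):
        r = edge_risk.get((a, b), 0.0)
        if r >= 1.0:
            return 1.0
        total += math.log1p(-r)
    return -math.expm1(total)


def _ngram_counts(trajectories, max_len: int):
    """Counts of all port n-grams (2 <= n <= max_len) across trajectories."""
    counts: dict[tuple[str, ...], int] = {}
    for traj in trajectories:
        seq = traj.ports if isinstance(traj, Trajectory) else list(traj)
        n = len(seq)
        for length in range(2, max_len + 1):
            for i in range(n - length + 1):
                g = tuple(seq[i:i + length])
                counts[g] = counts.get(g, 0) + 1
    return counts


def extract_rules(
    trajectories,
    edge_risk: dict[tuple[str, str], float],
    max_order: int = 5,
    min_support: int = 5,
    threshold: float = 0.10,
    criterion: str = "relative",
) -> list[Rule]:
    """Extract significant higher-order dependency rules from a corpus.

    All first-order transitions with support >= ``min_support`` become rules.
    A rule with context ``S`` and pathway risk ``P_S`` is extended with a
    preceding port ``x`` iff the extended pathway recurs at least
    ``min_support`` times and the risk change is significant — by default
    ``(P_new - P_S) / P_S > threshold`` (``criterion="relative"``), or
    ``P_new - P_S > threshold`` (``"absolute"``); extension recurses up to
    ``max_order``. Under the relative criterion, contexts whose own pathway
    risk is zero are never extended (there is no baseline risk to amplify).
    Deterministic: output sorted by (order, context, next).
    """
    if max_order < 1 or min_support < 1:
        raise ValueError("max_order and min_support must be >= 1")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if criterion not in ("relative", "absolute"):
        raise ValueError(f"unknown significance criterion {criterion!r}")

    counts = _ngram_counts(trajectories, max_order + 2)

    rules: list[Rule] = []
    # first-order rules
    frontier: list[tuple[tuple[str, ...], str, float, int]] = []
    for gram, c in counts.items():
        if len(gram) == 2 and c >= min_support:
            prob = path_risk(gram, edge_risk)
            rule = Rule(context=(gram[0],), next=gram[1], probability=prob, support=c)
            rules.append(rule)
            frontier.append((rule.context, rule.next, prob, c))

    # index: for a pathway g, which ports precede it (with counts)?
    preceders: dict[tuple[str, ...], list[tuple[str, int]]] = {}
    for gram, c in counts.items():
        if len(gram) >= 3:
            preceders.setdefault(gram[1:], []).append((gram[0], c))

    while frontier:
        context, nxt, p_s, _ = frontier.pop()
        if len(context) + 1 > max_order:
            continue
        if criterion == "relative" and p_s <= 0.0:
            continue
        pathway = context + (nxt,)
        for x, c_new in preceders.get(pathway, ()):
            if c_new < min_support:
                continue
            r_pre = edge_risk.get((x, context[0]), 0.0)
            p_new = 1.0 - (1.0 - r_pre) * (1.0 - p_s)
            significant = ((p_new - p_s) / p_s > threshold
                           if criterion == "relative"
                           else p_new - p_s > threshold)
            if significant:
                rule = Rule(context=(x,) + context, next=nxt,
                            probability=p_new, support=c_new)
                rules.append(rule)
                frontier.append((rule.context, rule.next, p_new, c_new))

    rules.sort(key=lambda r: (r.order, r.context, r.next))
    return rules


def node_label(context: tuple[str, ...]) -> str:
    """``current|oldest,...,newest``; plain port id for first-order contexts."""
    if len(context) == 1:
        return context[0]
    return f"{context[-1]}|{','.join(context[:-1])}"


def wire_network(rules: list[Rule], vector: str | None = None) -> nx.DiGraph:
    """Convert extracted rules into a higher-order network.

    Each rule creates a source node labeled by its context and an edge of
    weight = the rule's pathway probability. The edge target is the
    highest-order node representing ``next`` whose context is a suffix of the
    rule's history extended by ``next`` — so walks through the network stay
    history-consistent — falling back to the first-order node. Zero-weight
    edges are dropped from the risk outputs (the nodes remain).
    """
    g = nx.DiGraph(kind="HON", vector=vector)
    contexts = {r.context for r in rules}
    ports = {p for r in rules for p in r.context} | {r.next for r in rules}

    def add_node(context: tuple[str, ...]) -> str:
        label = node_label(context)
        if label not in g:
            g.add_node(label, port=context[-1], order=len(context))
        return label

    for p in sorted(ports):
        add_node((p,))
    for r in rules:
        add_node(r.context)

    max_ctx_len = max((len(c) for c in contexts), default=1)
    for r in rules:
        src = node_label(r.context)
        history = r.context + (r.next,)
        target_ctx = (r.next,)
        for m in range(min(len(history), max_ctx_len), 1, -1):
            cand = history[-m:]
            if cand in contexts:
                target_ctx = cand
                break
        dst = add_node(target_ctx)
        if r.probability > 0.0:
            g.add_edge(src, dst, weight=r.probability, order=r.order, support=r.support)
    return g


def port_of(g: nx.DiGraph, node: str) -> str:
    """Physical port behind a node; plain port-level graphs map identically."""
    return g.nodes[node].get("port", node)


def collapse_to_ports(hon: nx.DiGraph, mode: str = "union"):
    """Collapse a higher-order network onto physical ports.

    Returns ``(pair_risk, port_in_risk)``: for each ordered physical pair the
    combination of all edges whose endpoints map to it, and for each port the
    combination of all incoming edge weights of its nodes. ``mode`` is
    ``union`` (1 - prod(1 - w), the default — parallel pathways are
    independent opportunities), ``sum`` or ``mean``.
    """
    if mode not in ("union", "sum", "mean"):
        raise ValueError(f"unknown collapse mode {mode!r}")
    pair_w: dict[tuple[str, str], list[float]] = {}
    in_w: dict[str, list[float]] = {port_of(hon, n): [] for n in hon.nodes}
    for u, v, d in hon.edges(data=True):
        pu, pv = port_of(hon, u), port_of(hon, v)
        w = float(d["weight"])
        pair_w.setdefault((pu, pv), []).append(w)
        in_w[pv].append(w)

    def combine(ws):
        if not ws:
            return 0.0
        if len(ws) == 1:
            return min(ws[0], 1.0)
        if mode == "sum":
            return float(sum(ws))
        if mode == "mean":
            return float(sum(ws) / len(ws))
        return -math.expm1(sum(math.log1p(-min(w, 1.0)) for w in ws)) \
            if all(w < 1.0 for w in ws) else 1.0

    pairs = {pair: combine(ws) for pair, ws in pair_w.items()}
    in_risk = {p: combine(ws) for p, ws in in_w.items()}
    return pairs, in_risk


def rules_to_frame(rules: list[Rule]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"context": "|".join(r.context), "next": r.next, "order": r.order,
          "support": r.support, "probability": r.probability} for r in rules]
    )


def write_rules(rules: list[Rule], path) -> None:
    df = rules_to_frame(rules)
    if not df.empty:
        df["probability"] = df["probability"].map(lambda x: f"{x:.12g}")
    df.to_csv(path, index=False)


def read_rules(path) -> list[Rule]:
    df = pd.read_csv(path, dtype={"context": str, "next": str})
    return [
        Rule(context=tuple(row.context.split("|")), next=row.next,
             probability=float(row.probability), support=int(row.support))
        for row in df.itertuples()
    ]


def write_hon_edges(g: nx.DiGraph, path) -> None:
    rows = sorted(
        (u, v, g.nodes[u]["port"], g.nodes[v]["port"], d.get("order", 1), d["weight"])
        for u, v, d in g.edges(data=True)
    )
    df = pd.DataFrame(rows, columns=["source_node", "target_node", "source_port",
                                     "target_port", "order", "weight"])
    df["weight"] = df["weight"].map(lambda x: f"{x:.12g}")
    df.to_csv(path, index=False)
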