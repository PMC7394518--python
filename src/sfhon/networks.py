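"""First-order (SF-FON) and All-Paths baseline networks.

Both are weighted digraphs over physical ports. The first-order network has
one edge per ordered port pair with positive aggregated spread risk. The
All-Paths baseline additionally connects every ordered pair of ports that
appear (in order) anywhere along a ship trajectory, scoring each subpath by
the union of its consecutive edge risks — the "no significance filtering"
extreme that tends to over-estimate overall spread risk.
"""

from __future__ import annotations

import logging
import math

import networkx as nx
import pandas as pd

from .core import Trajectory

log = logging.getLogger(__name__)


def build_fon(pair_risks: pd.DataFrame, vector: str | None = None,
              drop_zero: bool = True) -> nx.DiGraph:
    """First-order species-flow network from a pair-risk table.

    One node per port with at least one incident pair; edge weight is the
    aggregated ``p_spread``. Zero-weight edges are dropped by default.
    """
    g = nx.DiGraph(kind="FON", vector=vector)
    for row in pair_risks.itertuples():
        if row.source == row.dest:
            continue
        w = float(row.p_spread)
        g.add_node(row.source)
        g.add_node(row.dest)
        if drop_zero and w <= 0.0:
            continue
        g.add_edge(row.source, row.dest, weight=w)
    return g


def path_union(risks) -> float:
    """Union of independent per-edge Bernoulli risks along a path."""
    total = 0.0
    for r in risks:
        if r >= 1.0:
            return 1.0
        total += math.log1p(-r)
    return -math.expm1(total)


def build_all_paths(
    trajectories: dict[str, Trajectory] | list[Trajectory],
    edge_risk: dict[tuple[str, str], float],
    max_span: int | None = None,
    vector: str | None = None,
    drop_zero: bool = True,
) -> nx.DiGraph:
    """All-Paths baseline network.

    For every trajectory and every ordered index pair a < b (with
    ``b - a <= max_span`` when bounded), the subpath risk (union over the
    consecutive edge risks) contributes one Bernoulli term to the ordered
    port pair (visit a, visit b); contributions across trajectories combine
    by the same union. Consecutive pairs missing from ``edge_risk`` count as
    zero risk and are tallied in the returned graph's ``n_missing_edge_risk``
    attribute.
    """
    if isinstance(trajectories, dict):
        trajectories = list(trajectories.values())
    # accumulate log(1 - contribution) per ordered pair
    acc: dict[tuple[str, str], float] = {}
    certain: set[tuple[str, str]] = set()
    nodes: set[str] = set()
    n_missing = 0

    for traj in trajectories:
        seq = traj.ports
        nodes.update(seq)
        n = len(seq)
        # log(1 - r) for each consecutive leg
        leg_logs = []
        for a, b in zip(seq, seq[1:]):
            r = edge_risk.get((a, b))
            if r is None:
                n_missing += 1
                r = 0.0
            leg_logs.append(-math.inf if r >= 1.0 else math.log1p(-r))
        # prefix sums: subpath (a..b) risk = 1 - exp(sum of leg logs a..b-1)
        prefix = [0.0]
        for ll in leg_logs:
            prefix.append(prefix[-1] + ll)
        for a in range(n - 1):
            b_max = n if max_span is None else min(n, a + max_span + 1)
            for b in range(a + 1, b_max):
                pair = (seq[a], seq[b])
                if pair[0] == pair[1] or pair in certain:
                    continue
                sub_log = prefix[b] - prefix[a]
                if math.isinf(sub_log):
                    certain.add(pair)
                    continue
                # union with previous contributions: multiply survival
                # terms, i.e. add log(1 - subpath risk) = sub_log
                acc[pair] = acc.get(pair, 0.0) + sub_log

    g = nx.DiGraph(kind="ALLPATHS", vector=vector, n_missing_edge_risk=n_missing)
    g.add_nodes_from(nodes)
    for pair in certain:
        g.add_edge(*pair, weight=1.0)
    for pair, logsurv in acc.items():
        if pair in certain:
            continue
        w = -math.expm1(logsurv)
        if drop_zero and w <= 0.0:
            continue
        g.add_edge(*pair, weight=w)
    return g


def write_edges(g: nx.DiGraph, path) -> None:
    """Serialize edges as source_port,dest_port,weight (12 significant digits)."""
    rows = sorted((u, v, d["weight"]) for u, v, d in g.edges(data=True))
    df = pd.DataFrame(rows, columns=["source_port", "dest_port", "weight"])
    df["weight"] = df["weight"].map(lambda x: f"{x:.12g}")
    df.to_csv(path, index=False)


def read_edges(path, kind: str | None = None, vector: str | None = None) -> nx.DiGraph:
    df = pd.read_csv(path, dtype={"source_port": str, "dest_port": str})
    g = nx.DiGraph(kind=kind, vector=vector)
    for row in df.itertuples():
        g.add_edge(row.source_port, row.dest_port, weight=float(row.weight))
    return g
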