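"""Network statistics and comparative summaries for species-flow networks.

The definitions follow the network-characteristics conventions used for
comparing first-order and higher-order species-flow networks: a directed
clustering coefficient over the union in/out neighborhood, a density variant
normalized by |V|^2/2, betweenness on shortest paths with inverted-risk edge
lengths, Freeman-style graph centralization, and weak/strong component
counts. Also realm-level flow matrices, ship-type risk summaries and
temporal summaries of higher-order structure versus mean risk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class GraphStats:
    n_nodes: int
    n_edges: int
    avg_degree: float       # |E| / |V|
    avg_cc: float
    density: float
    betweenness: dict       # node -> normalized C'_B
    centralization: float
    n_weak_cc: int
    n_strong_cc: int

    @property
    def avg_betweenness(self) -> float:
        if not self.betweenness:
            return 0.0
        return sum(self.betweenness.values()) / len(self.betweenness)

    def to_dict(self):
        d = asdict(self)
        d["avg_betweenness"] = self.avg_betweenness
        return d


def local_cc(g: nx.DiGraph, node) -> float:
    """Directed clustering coefficient of one node.

    Neighborhood = union of in- and out-neighbors; the coefficient is the
    number of directed edges among neighbors divided by k(k-1). Nodes with
    fewer than two neighbors score 0.
    """
    nbrs = (set(g.successors(node)) | set(g.predecessors(node))) - {node}
    k = len(nbrs)
    if k < 2:
        return 0.0
    links = sum(1 for u in nbrs for v in nbrs if u != v and g.has_edge(u, v))
    return links / (k * (k - 1))


def avg_cc(g: nx.DiGraph) -> float:
    if g.number_of_nodes() == 0:
        return 0.0
    return sum(local_cc(g, n) for n in g.nodes) / g.number_of_nodes()


def density(g: nx.DiGraph, variant: str = "as_printed") -> float:
    """Edge density.

    ``as_printed``: |E| / (|V|^2 / 2) — the convention used in the network
    comparison tables this package mirrors. ``directed_standard``:
    |E| / (|V| (|V|-1)).
    """
    n, m = g.number_of_nodes(), g.number_of_edges()
    if n <= 1:
        return 0.0
    if variant == "as_printed":
        return m / (n * n / 2.0)
    if variant == "directed_standard":
        return m / (n * (n - 1))
    raise ValueError(f"unknown density variant {variant!r}")


def betweenness(g: nx.DiGraph, length: str = "inverse") -> dict:
    """Normalized betweenness centrality with risk-derived edge lengths.

    Shortest paths are computed on lengths 1/weight (``inverse``) or
    -log(weight) (``neglog``); zero-weight edges are untraversable. Raw
    counts (fraction of shortest s-t paths through v, endpoints excluded, all
    ordered pairs) are normalized by (n-1)(n-2)/2.
    """
    n = g.number_of_nodes()
    if n < 3:
        return {v: 0.0 for v in g.nodes}
    h = nx.DiGraph()
    h.add_nodes_from(g.nodes)
    for u, v, d in g.edges(data=True):
        w = float(d.get("weight", 1.0))
        if w <= 0.0:
            continue
        h.add_edge(u, v, length=(1.0 / w) if length == "inverse" else -np.log(w))
    raw = nx.betweenness_centrality(h, weight="length", normalized=False)
    scale = (n - 1) * (n - 2) / 2.0
    return {v: raw[v] / scale for v in h.nodes}


def centralization(g: nx.DiGraph, btw: dict | None = None) -> float:
    """Freeman graph centralization of the normalized betweenness scores:
    ``2 * sum(C'_max - C'_i) / (n - 1)``."""
    if btw is None:
        btw = betweenness(g)
    n = len(btw)
    if n < 2:
        return 0.0
    cmax = max(btw.values())
    return 2.0 * sum(cmax - c for c in btw.values()) / (n - 1)


def components(g: nx.DiGraph) -> tuple[int, int]:
    """(number of weakly connected, number of strongly connected) components."""
    if g.number_of_nodes() == 0:
        return (0, 0)
    return (nx.number_weakly_connected_components(g),
            nx.number_strongly_connected_components(g))


def graph_stats(g: nx.DiGraph, density_variant: str = "as_printed") -> GraphStats:
    n, m = g.number_of_nodes(), g.number_of_edges()
    btw = betweenness(g)
    weak, strong = components(g)
    return GraphStats(
        n_nodes=n,
        n_edges=m,
        avg_degree=(m / n) if n else 0.0,
        avg_cc=avg_cc(g),
        density=density(g, density_variant),
        betweenness=btw,
        centralization=centralization(g, btw),
        n_weak_cc=weak,
        n_strong_cc=strong,
    )


def minmax_normalize_matrix(values: np.ndarray) -> np.ndarray:
    lo, hi = np.nanmin(values), np.nanmax(values)
    if hi == lo:
        log.info("degenerate min-max normalization (max == min); returning zeros")
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def realm_flow(pair_risks: dict[tuple[str, str], float], ports) -> pd.DataFrame:
    """Mean inter-port risk between realms, min-max normalized to [0, 1].

    ``pair_risks`` maps ordered physical port pairs to risk (e.g. the
    collapsed higher-order network); ``ports`` maps port_id -> Port. Rows are
    target realms, columns source realms. Realm pairs with no scored port
    pair average over zero contributions.
    """
    realm_of = {pid: p.realm_id for pid, p in ports.items()}
    realms = sorted(set(realm_of.values()))
    idx = {r: i for i, r in enumerate(realms)}
    ports_by_realm: dict[str, list[str]] = {r: [] for r in realms}
    for pid, r in realm_of.items():
        ports_by_realm[r].append(pid)

    sums = np.zeros((len(realms), len(realms)))
    for (src, dst), w in pair_risks.items():
        if src in realm_of and dst in realm_of:
            sums[idx[realm_of[dst]], idx[realm_of[src]]] += w
    counts = np.array(
        [[len(ports_by_realm[rs]) * len(ports_by_realm[rt])
          for rs in realms] for rt in realms], dtype=float)
    counts[counts == 0] = 1.0
    means = sums / counts
    return pd.DataFrame(minmax_normalize_matrix(means), index=realms, columns=realms)


def ship_type_summary(voyage_probs: pd.DataFrame) -> pd.DataFrame:
    """Per-ship-type record share and five-number summary of voyage risks.

    Expects a frame with ``ship_type`` and ``p_voyage`` columns (see
    :func:`sfhon.risk.voyage_prob_table`). Shares are percentages of all
    records and sum to 100.
    """
    total = len(voyage_probs)
    rows = []
    for stype, grp in voyage_probs.groupby("ship_type"):
        p = grp["p_voyage"].to_numpy(dtype=float)
        q0, q1, q2, q3, q4 = np.percentile(p, [0, 25, 50, 75, 100])
        rows.append({
            "ship_type": stype, "share_pct": 100.0 * len(grp) / total,
            "mean": float(p.mean()), "min": q0, "q1": q1, "median": q2,
            "q3": q3, "max": q4, "n": len(grp),
        })
    return pd.DataFrame(rows).sort_values("ship_type", ignore_index=True)


def count_higher_order_nodes(hon: nx.DiGraph) -> int:
    return sum(1 for _, d in hon.nodes(data=True) if d.get("order", 1) >= 2)


def temporal_summary(snapshots) -> dict:
    """Series of (higher-order node count, mean edge risk) plus their Pearson r.

    ``snapshots`` is a sequence of (hon_graph, collapsed_pair_risks) pairs,
    one per time slice. Correlation is reported as None when either series is
    constant (undefined) or fewer than 3 snapshots are given.
    """
    n_ho, mean_risk = [], []
    for hon, pair_risks in snapshots:
        n_ho.append(count_higher_order_nodes(hon))
        vals = list(pair_risks.values())
        mean_risk.append(float(np.mean(vals)) if vals else 0.0)
    result = {"n_higher_order_nodes": n_ho, "mean_risk": mean_risk,
              "pearson_r": None, "p_value": None}
    if len(n_ho) >= 3 and np.std(n_ho) > 0 and np.std(mean_risk) > 0:
        r, p = stats.pearsonr(n_ho, mean_risk)
        result["pearson_r"] = float(r)
        result["p_value"] = float(p)
    return result
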