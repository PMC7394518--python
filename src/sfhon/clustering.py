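"""Flow-based community detection on species-flow networks.

Communities are found by minimizing the two-level map equation over hard
partitions of the nodes: the expected per-step description length of a
random walk that uses one index codebook for between-module moves and one
codebook per module for within-module moves. Groups of nodes among which
flow (here: species spread risk) circulates quickly and persistently are
compressed into modules.

The walk follows out-edge weights normalized per node, with uniform
teleportation (and uniform redistribution from dangling nodes), giving a
well-defined stationary visit rate per node. The built-in optimizer is a
seeded greedy local-moving search with restarts; a port belongs to every
cluster that any of its history-annotated nodes falls in, so ports can be
multi-cluster members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

log = logging.getLogger(__name__)


@dataclass
class FlowField:
    nodes: list
    visit: np.ndarray          # stationary visit rate per node
    trans: np.ndarray          # full transition matrix (incl. teleport), row-stochastic
    flow: np.ndarray           # visit[:, None] * trans
    adjacency: np.ndarray      # boolean, raw positive-weight links

    @property
    def n(self) -> int:
        return len(self.nodes)


@dataclass
class Partition:
    assignment: dict           # node -> cluster id (0-based ints)
    objective: float           # description length, bits

    def port_membership(self, hon: nx.DiGraph) -> dict:
        members: dict[str, set[int]] = {}
        for node, cid in self.assignment.items():
            port = hon.nodes[node].get("port", node)
            members.setdefault(port, set()).add(cid)
        return members


def stationary_flow(
    g: nx.DiGraph,
    teleport: float = 0.15,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> FlowField:
    """Stationary visit rates and edge flows of the teleporting random walk.

    Transition: with probability 1 - teleport follow an out-edge proportional
    to weight (dangling nodes teleport uniformly); with probability teleport
    jump uniformly. Power iteration to ``tol`` in L1; raises on
    non-convergence.
    """
    if not 0.0 < teleport < 1.0:
        raise ValueError("teleport must lie in (0, 1)")
    nodes = list(g.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("empty graph")
    idx = {v: i for i, v in enumerate(nodes)}
    w = np.zeros((n, n))
    for u, v, d in g.edges(data=True):
        w[idx[u], idx[v]] = max(0.0, float(d.get("weight", 1.0)))
    out = w.sum(axis=1)
    dangling = out <= 0.0
    link = np.where(dangling[:, None], 0.0, w / np.where(out[:, None] > 0, out[:, None], 1.0))
    # full transition incl. teleport and dangling redistribution
    tele_rate = teleport + (1.0 - teleport) * dangling  # per-node uniform-jump mass
    trans = (1.0 - tele_rate)[:, None] * link + tele_rate[:, None] / n

    p = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        p_next = p @ trans
        if np.abs(p_next - p).sum() < tol:
            p = p_next
            break
        p = p_next
    else:
        raise RuntimeError(
            f"stationary flow did not converge within {max_iter} iterations "
            f"(residual {np.abs(p @ trans - p).sum():.3e})"
        )
    p = p / p.sum()
    return FlowField(nodes=nodes, visit=p, trans=trans, flow=p[:, None] * trans,
                     adjacency=w > 0.0)


def _plogp(x: np.ndarray | float) -> np.ndarray | float:
    return np.where(x > 0, x * np.log2(np.maximum(x, 1e-300)), 0.0)


def map_equation(assignment: np.ndarray, field: FlowField) -> float:
    """Two-level map equation value (bits per step) of a partition.

    ``assignment`` is an int array over ``field.nodes``. With all nodes in
    one module the index codebook vanishes and the value reduces to the
    entropy of the visit rates.
    """
    modules = np.unique(assignment)
    if modules.size == 0:
        raise ValueError("empty partition")
    p = field.visit
    flow = field.flow

    q = np.empty(modules.size)          # exit flow per module
    p_mod = np.empty(modules.size)      # total visit rate per module
    for k, m in enumerate(modules):
        mask = assignment == m
        if not mask.any():
            raise ValueError(f"empty module {m}")
        q[k] = flow[np.ix_(mask, ~mask)].sum()
        p_mod[k] = p[mask].sum()

    q_tot = q.sum()
    # index codebook: H over normalized exit flows, used q_tot of the time
    index_term = 0.0
    if q_tot > 0:
        index_term = -float(_plogp(q / q_tot).sum()) * q_tot
    # module codebooks: entries are exit flow + member visit rates
    module_term = 0.0
    for k, m in enumerate(modules):
        mask = assignment == m
        tot = q[k] + p_mod[k]
        if tot <= 0:
            continue
        entries = np.concatenate(([q[k]], p[mask])) / tot
        module_term += -float(_plogp(entries).sum()) * tot
    return index_term + module_term


def _local_moving(assignment: np.ndarray, field: FlowField, rng: np.random.Generator,
                  max_sweeps: int = 100) -> tuple[np.ndarray, float]:
    n = field.n
    # candidate moves: modules of in/out neighbors in the raw link graph
    neighbors = [set() for _ in range(n)]
    for i, j in zip(*np.nonzero(field.adjacency)):
        if i != j:
            neighbors[i].add(j)
            neighbors[j].add(i)

    best = map_equation(assignment, field)
    for _ in range(max_sweeps):
        improved = False
        order = rng.permutation(n)
        for i in order:
            current = assignment[i]
            cand_modules = {assignment[j] for j in neighbors[i]} - {current}
            for m in cand_modules:
                old = assignment[i]
                assignment[i] = m
                val = map_equation(assignment, field)
                if val < best - 1e-13:
                    best = val
                    improved = True
                else:
                    assignment[i] = old
        if not improved:
            break
    return assignment, best


def _merge_modules(assignment: np.ndarray, field: FlowField) -> tuple[np.ndarray, float]:
    best = map_equation(assignment, field)
    improved = True
    while improved:
        improved = False
        modules = list(np.unique(assignment))
        for a_i in range(len(modules)):
            for b_i in range(a_i + 1, len(modules)):
                a, b = modules[a_i], modules[b_i]
                trial = assignment.copy()
                trial[trial == b] = a
                val = map_equation(trial, field)
                if val < best - 1e-13:
                    assignment, best = trial, val
                    improved = True
                    break
            if improved:
                break
    return assignment, best


def infomap_cluster(
    g: nx.DiGraph,
    seed: int = 0,
    n_restarts: int = 10,
    teleport: float = 0.15,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> Partition:
    """Greedy map-equation minimization; best partition over seeded restarts.

    Starts from singleton modules, alternates local node moves and module
    merges until no improvement. Reproducible for a fixed seed.
    """
    field = stationary_flow(g, teleport=teleport, tol=tol, max_iter=max_iter)
    n = field.n
    if n == 1:
        return Partition(assignment={field.nodes[0]: 0}, objective=0.0)

    rng = np.random.default_rng(seed)
    best_assign, best_val = None, np.inf
    for _ in range(max(1, n_restarts)):
        assignment = np.arange(n)
        assignment, val = _local_moving(assignment, field, rng)
        assignment, val = _merge_modules(assignment, field)
        assignment, val = _local_moving(assignment, field, rng)
        if val < best_val - 1e-13:
            best_val, best_assign = val, assignment.copy()

    # relabel clusters densely in first-appearance order for determinism
    relabel: dict[int, int] = {}
    for m in best_assign:
        if m not in relabel:
            relabel[m] = len(relabel)
    mapping = {field.nodes[i]: relabel[best_assign[i]] for i in range(n)}
    return Partition(assignment=mapping, objective=float(best_val))


def membership_report(partition: Partition, hon: nx.DiGraph, top_k: int = 5) -> dict:
    """Per-port cluster membership and the share of multi-cluster ports.

    A port belongs to the clusters of all its history-annotated nodes. Also
    reports the fraction of ports covered by the ``top_k`` largest clusters
    (by port count).
    """
    members = partition.port_membership(hon)
    n_ports = len(members)
    multi = sum(1 for cids in members.values() if len(cids) >= 2)
    cluster_ports: dict[int, set] = {}
    for port, cids in members.items():
        for c in cids:
            cluster_ports.setdefault(c, set()).add(port)
    top = sorted(cluster_ports.values(), key=len, reverse=True)[:top_k]
    covered = set().union(*top) if top else set()
    return {
        "port_clusters": {p: sorted(c) for p, c in members.items()},
        "multi_cluster_share": multi / n_ports if n_ports else 0.0,
        "top_k_coverage": len(covered) / n_ports if n_ports else 0.0,
        "n_clusters": len(cluster_ports),
    }
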