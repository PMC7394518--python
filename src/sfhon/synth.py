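"""Synthetic shipping-world generator.

Produces ports embedded in ecoregions and realms with latitude-driven
environmental gradients, a typed fleet, ship trajectories drawn from a
first-order base chain with optional *planted* higher-order dependencies
(when a ship's recent history matches a planted context, its next port is
overridden with a configured boost probability), and region-level
introduction counts generated from a true risk surface plus truncated
Gaussian noise. Every draw comes from one seeded generator, so a config
reproduces its corpus byte-for-byte.

The generator targets correctness testing of the risk/network pipeline, not
realism: traffic has no power-law port-call structure, and environmental
fields are smooth functions of latitude plus noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np

from .core import EcoregionGraph, Port, Ship, Voyage, haversine_km
from .hon import Rule, path_risk

EPOCH = date(2012, 5, 1)

DEFAULT_TYPE_MIX = {
    "Container": 0.30, "Bulk": 0.22, "General": 0.19, "Tanker": 0.12,
    "Auto": 0.07, "Passenger": 0.04, "Chemical": 0.03, "Fishing": 0.01,
    "Research": 0.01, "Yacht": 0.01,
}

# rough GWT scale (tonnes) per type for the lognormal size draw
GWT_SCALE = {
    "Container": 30_000, "Bulk": 45_000, "General": 12_000, "Tanker": 40_000,
    "Auto": 35_000, "Passenger": 30_000, "Chemical": 20_000, "Fishing": 1_500,
    "Research": 3_000, "Yacht": 500,
}


@dataclass
class SynthConfig:
    """Study conditions for one synthetic corpus."""

    n_ports: int = 50
    n_ecoregions: int = 10
    n_realms: int = 5
    n_ships: int = 500
    n_voyages: int = 5000
    #: list of (context tuple of port_ids, next port_id, boost probability)
    planted_rules: list = field(default_factory=list)
    #: first-order transition matrix (n_ports x n_ports, rows sum to 1) or
    #: None for uniform over all other ports
    base_chain: np.ndarray | None = None
    temp_range: tuple = (2.0, 29.0)     # deg C, poles -> equator
    salinity_range: tuple = (28.0, 36.0)  # ppt
    env_noise_sd: float = 1.0           # jitter on temperature/salinity
    stay_days: tuple = (1, 14)          # uniform integer stay at port
    speed_range: tuple = (250.0, 550.0)  # km/day
    noise_sd: float = 0.05              # observation noise for introductions
    seed: int = 0

    def __post_init__(self):
        if not (self.n_ports >= self.n_ecoregions >= self.n_realms >= 1):
            raise ValueError("need n_ports >= n_ecoregions >= n_realms >= 1")


def gen_ports(config: SynthConfig, rng: np.random.Generator | None = None):
    """Generate the port table and ecoregion neighbor graph.

    Ports sit on a latitude sweep from 60S to 60N; ecoregions are contiguous
    blocks of consecutive ports, nested in contiguous realms, with a chain
    neighbor relation between adjacent ecoregions. Temperature decreases with
    |latitude|; salinity follows a mild longitude gradient. One evaluation
    region per ecoregion.
    """
    rng = rng or np.random.default_rng(config.seed)
    n, ne, nr = config.n_ports, config.n_ecoregions, config.n_realms
    eco_of = np.minimum((np.arange(n) * ne) // n, ne - 1)
    realm_of_eco = np.minimum((np.arange(ne) * nr) // ne, nr - 1)

    # quasi-uniform scatter so each ecoregion block mixes climates; the
    # temperature field still decreases with |latitude|
    golden = 2.399963229728653
    lats = 60.0 * np.sin(golden * np.arange(n))
    lons = ((np.degrees(golden) * np.arange(n) + 180.0) % 360.0) - 180.0
    t_lo, t_hi = config.temp_range
    temps = t_hi - (t_hi - t_lo) * (np.abs(lats) / 60.0) \
        + rng.normal(0.0, config.env_noise_sd, n)
    s_lo, s_hi = config.salinity_range
    sals = s_lo + (s_hi - s_lo) * ((lons + 180.0) / 360.0) \
        + rng.normal(0.0, config.env_noise_sd, n)
    sals = np.maximum(0.0, sals)

    ports: dict[str, Port] = {}
    for i in range(n):
        pid = f"P{i:03d}"
        eco = f"E{eco_of[i]:02d}"
        ports[pid] = Port(
            port_id=pid, name=f"Port {i}", latitude=float(lats[i]),
            longitude=float(lons[i]), temperature=float(temps[i]),
            salinity=float(sals[i]), ecoregion_id=eco,
            realm_id=f"RL{realm_of_eco[eco_of[i]]:02d}", region_id=f"R{eco_of[i]:02d}",
        )
    eco_ids = [f"E{k:02d}" for k in range(ne)]
    eco_graph = EcoregionGraph(eco_ids)
    for a, b in zip(eco_ids, eco_ids[1:]):
        eco_graph.add_neighbors(a, b)
    return ports, eco_graph


def gen_fleet(config: SynthConfig, rng: np.random.Generator | None = None) -> dict[str, Ship]:
    rng = rng or np.random.default_rng(config.seed + 1)
    types = list(DEFAULT_TYPE_MIX)
    probs = np.array([DEFAULT_TYPE_MIX[t] for t in types])
    probs = probs / probs.sum()
    ships: dict[str, Ship] = {}
    drawn = rng.choice(len(types), size=config.n_ships, p=probs)
    sizes = rng.lognormal(mean=0.0, sigma=0.4, size=config.n_ships)
    for i in range(config.n_ships):
        stype = types[drawn[i]]
        ships[f"S{i:05d}"] = Ship(
            ship_id=f"S{i:05d}", ship_type=stype,
            gwt=float(max(100.0, GWT_SCALE[stype] * sizes[i])),
        )
    return ships


def _distance_matrix(ports: dict[str, Port], port_ids: list[str]) -> np.ndarray:
    n = len(port_ids)
    d = np.zeros((n, n))
    coords = [(ports[p].latitude, ports[p].longitude) for p in port_ids]
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = haversine_km(*coords[i], *coords[j])
    return d


def gen_trajectories(
    config: SynthConfig,
    ports: dict[str, Port],
    fleet: dict[str, Ship],
    rng: np.random.Generator | None = None,
) -> list[Voyage]:
    """Walk each ship through the port chain and emit dated voyages.

    Voyages are split as evenly as possible across the fleet. At each step
    the most recent history is matched against the planted contexts (longest
    match wins, exact consecutive ports, no gaps); on a match the planted
    next port is emitted with the boost probability, otherwise the base
    chain draws the next port. Stays and speeds come from the configured
    uniform ranges; dates are whole days.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    port_ids = sorted(ports)
    n = len(port_ids)
    idx = {p: i for i, p in enumerate(port_ids)}
    dist = _distance_matrix(ports, port_ids)

    chain = config.base_chain
    if chain is not None:
        chain = np.asarray(chain, dtype=float)
        if chain.shape != (n, n):
            raise ValueError("base_chain shape must be (n_ports, n_ports)")
        if not np.allclose(chain.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("base_chain rows must sum to 1")
        cum = np.cumsum(chain, axis=1)

    planted = sorted(
        ((tuple(ctx), nxt, float(boost)) for ctx, nxt, boost in config.planted_rules),
        key=lambda t: -len(t[0]),
    )
    max_ctx = max((len(c) for c, _, _ in planted), default=0)

    ship_ids = sorted(fleet)
    per_ship = np.full(len(ship_ids), config.n_voyages // len(ship_ids))
    per_ship[: config.n_voyages % len(ship_ids)] += 1

    stay_lo, stay_hi = config.stay_days
    voyages: list[Voyage] = []
    for s_i, ship_id in enumerate(ship_ids):
        k = int(per_ship[s_i])
        if k == 0:
            continue
        speed = rng.uniform(*config.speed_range)
        u_next = rng.random(k)
        u_boost = rng.random(k)
        stays = rng.integers(stay_lo, stay_hi + 1, size=k)
        here = int(rng.integers(n))
        history = [port_ids[here]]
        day = 0
        for step in range(k):
            nxt = None
            for ctx, target, boost in planted:
                if len(history) >= len(ctx) and tuple(history[-len(ctx):]) == ctx:
                    if u_boost[step] < boost:
                        nxt = idx[target]
                    break
            if nxt is None:
                if chain is None:
                    j = int(u_next[step] * (n - 1))
                    nxt = j if j < here else j + 1
                else:
                    nxt = int(np.searchsorted(cum[here], u_next[step], side="right"))
                    nxt = min(nxt, n - 1)
            sail = day + int(stays[step])
            dur = max(1, int(round(dist[here, nxt] / speed)))
            arrive = sail + dur
            voyages.append(Voyage(
                ship_id=ship_id, source=port_ids[here], dest=port_ids[nxt],
                sail_date=EPOCH + timedelta(days=sail),
                arrival_date=EPOCH + timedelta(days=arrive),
            ))
            here = nxt
            history.append(port_ids[here])
            if max_ctx and len(history) > max_ctx + 1:
                history = history[-(max_ctx + 1):]
            day = arrive
    return voyages


def gen_introductions(
    true_region_risk: dict[str, float],
    noise_sd: float = 0.0,
    seed: int = 0,
    count_scale: int = 1000,
):
    """Region introduction counts from a true risk surface.

    Counts are ``round(max(0, count_scale * (minmax(risk) + N(0, noise_sd))))``
    — proportional to normalized risk, noisy, truncated at zero and rounded.
    Returns (DataFrame[region_id, n_first_introductions], metadata dict).
    """
    import pandas as pd

    from .evaluation import minmax_scale

    rng = np.random.default_rng(seed)
    regions = sorted(true_region_risk)
    scaled = minmax_scale([true_region_risk[r] for r in regions])
    noisy = scaled + rng.normal(0.0, noise_sd, len(regions))
    counts = np.round(np.maximum(0.0, noisy) * count_scale).astype(int)
    df = pd.DataFrame({"region_id": regions, "n_first_introductions": counts})
    meta = {"transform": "minmax(risk) + N(0, noise_sd), truncated, rounded",
            "noise_sd": noise_sd, "count_scale": count_scale, "seed": seed}
    return df, meta


def true_rules(
    planted_rules,
    edge_risk: dict[tuple[str, str], float],
) -> list[Rule]:
    """The generating process's own rule set, scored with exact path risks.

    Planted dependencies are where multi-leg carryover truly occurs, so the
    true higher-order rules are exactly the planted (context -> next) pairs
    with the union risk of their pathways.
    """
    rules = []
    for ctx, nxt, _boost in planted_rules:
        ctx = tuple(ctx)
        rules.append(Rule(context=ctx, next=nxt,
                          probability=path_risk(ctx + (nxt,), edge_risk), support=1))
    return rules


def expected_recovery_set(planted_rules) -> set[tuple[tuple[str, ...], str]]:
    """(context, next) pairs a correct extractor should report.

    Includes each planted rule and, for planted rules of order 3 and above,
    the suffix rules they induce (extraction builds contexts stepwise, and a
    long planted dependency makes its suffix contexts genuinely predictive).
    """
    expected: set[tuple[tuple[str, ...], str]] = set()
    for ctx, nxt, _ in planted_rules:
        ctx = tuple(ctx)
        expected.add((ctx, nxt))
        while len(ctx) > 2:
            ctx = ctx[1:]
            expected.add((ctx, nxt))
    return expected


def select_planted_rules(
    ports: dict[str, Port],
    eco: EcoregionGraph,
    n_second: int = 5,
    n_third: int = 2,
    boost: float = 0.9,
    rng: np.random.Generator | None = None,
    max_temp_gap: float = 3.0,
    max_sal_gap: float = 8.0,
):
    """Sample planted dependencies whose pathways carry comparable risk.

    Context ports are drawn so that every port pair in a rule has similar
    temperature and salinity (their risks stay within a bounded ratio of
    each other) and every consecutive pair lies in distinct non-neighboring
    ecoregions — i.e. the planted pathway is risky end to end, so the
    dependency is recoverable in principle from the risk-weighted corpus.
    Each third-order rule comes with a second-order helper rule that makes
    its context recur (the helper counts toward ``n_second``). Ports are not
    reused across rules.
    """
    if n_third * 2 > n_second:
        raise ValueError("each third-order rule consumes one second-order helper")
    rng = rng or np.random.default_rng(0)
    port_ids = sorted(ports)
    used: set[str] = set()

    def env_close(a: str, b: str) -> bool:
        pa, pb = ports[a], ports[b]
        return (abs(pa.temperature - pb.temperature) <= max_temp_gap
                and abs(pa.salinity - pb.salinity) <= max_sal_gap)

    def cross_eco(a: str, b: str) -> bool:
        ea, eb = ports[a].ecoregion_id, ports[b].ecoregion_id
        return ea != eb and not eco.are_neighbors(ea, eb)

    def sample_tuple(k: int):
        for _ in range(20_000):
            cand = [port_ids[i] for i in rng.choice(len(port_ids), size=k, replace=False)]
            if used.intersection(cand):
                continue
            ok = (all(env_close(a, b) for a in cand for b in cand if a != b)
                  and all(cross_eco(a, b) for a, b in zip(cand, cand[1:])))
            if ok:
                used.update(cand)
                return cand
        raise RuntimeError("could not find a compatible planted context; "
                           "loosen the environment gaps or add ports")

    rules = []
    for _ in range(n_third):
        b_, c_, a_, e_ = sample_tuple(4)
        rules.append(((b_, c_), a_, boost))          # helper: makes (b,c,a) recur
        rules.append(((b_, c_, a_), e_, boost))      # the third-order dependency
    n_plain = n_second - n_third
    for _ in range(n_plain):
        c_, a_, e_ = sample_tuple(3)
        rules.append(((c_, a_), e_, boost))
    return rules
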