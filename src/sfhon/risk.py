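"""Per-voyage and per-port-pair nonindigenous-species spread probabilities.

The spread risk between ports i and j is the product of three independent
probabilities::

    P(spread)_ij = P(nonindigenous)_ij * P(establish)_ij * P(intro)_ij

* ``P(nonindigenous)`` is a 0/1 indicator from marine biogeography: ports in
  the same or neighboring ecoregions are assumed to share native species, so
  transfers between them are not counted as introductions.
* ``P(establish)`` is a Gaussian environmental-similarity kernel on the
  temperature and salinity differences between the ports.
* ``P(intro)`` is vector-specific (ballast water or hull biofouling),
  aggregated over all voyages between the pair as the probability that at
  least one voyage introduces (a union of independent Bernoulli events).

Biofouling per-voyage risk = antifouling factor (share of ships of the type
with no working antifouling system) x accumulation (a latitude-zone cubic in
the days spent at the source port) x en-route survival (exponential decay in
voyage velocity). Ballast per-voyage risk = management efficacy x discharge
saturation (1 - e^(-lambda*D)) x in-tank mortality decay e^(-mu*dt).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import Port, Ship, Voyage, EcoregionGraph, climate_zone

log = logging.getLogger(__name__)

#: share of ships without an operational antifouling system, by type
#: (survey of commercial ships in California)
DEFAULT_ANTIFOULING = {
    "Container": 0.19,
    "Auto": 0.20,
    "Tanker": 0.30,
    "Passenger": 0.31,
    "Bulk": 0.42,
    "General": 0.53,
    "other": 0.60,
}

#: case-folded aliases mapping raw ship-type strings onto the seven
#: antifouling categories
DEFAULT_TYPE_ALIASES = {
    "container": "Container",
    "auto": "Auto",
    "automobile": "Auto",
    "bulk": "Bulk",
    "general": "General",
    "tanker": "Tanker",
    "tanker/oil": "Tanker",
    "oil": "Tanker",
    "chemical": "Tanker",
    "gas": "Tanker",
    "passenger": "Passenger",
}

#: nominal ballast discharge per tonne of GWT (m3/tonne), by antifouling
#: category; a configurable stand-in for fleet-survey discharge/size fits
DEFAULT_DISCHARGE_COEFF = {
    "Container": 0.10,
    "Auto": 0.20,
    "Bulk": 0.35,
    "General": 0.15,
    "Tanker": 0.30,
    "Passenger": 0.20,
    "other": 0.15,
}


@dataclass
class RiskParams:
    """Every fitted constant of the spread-risk model, with shipped defaults.

    Attributes
    ----------
    alpha : peak establishment probability at perfect environmental match.
    delta_t, delta_s : kernel widths for temperature (deg C) and salinity (ppt).
    gamma : biofouling survival decay rate per (km/day) of voyage velocity.
    beta_tropical, beta_temperate : cubic accumulation coefficients
        (b1, b2, b3) for ``b1*d^3 - b2*d^2 + b3*d`` with d = days in port.
    mu : daily ballast in-tank mortality rate.
    lam : species introduction potential per m3 of discharge.
    rho_default : ballast-water management efficacy factor (kept at 1; no
        management practices are modeled).
    clamp_accumulation : clamp the cubic into [0, 1]; the fitted curve
        exceeds 1 for tropical stays beyond roughly 430 days while the
        quantity is a proportion of maximum species richness.
    """

    alpha: float = 0.00015
    delta_t: float = 2.0
    delta_s: float = 10.0
    gamma: float = 0.008
    beta_tropical: tuple = (1.29e-7, 8.316e-5, 0.0149)
    beta_temperate: tuple = (1.4e-9, 1.6566e-5, 5.193e-3)
    mu: float = 0.02
    lam: float = 3.22e-6
    rho_default: float = 1.0
    antifouling: dict = field(default_factory=lambda: dict(DEFAULT_ANTIFOULING))
    discharge_coeff: dict = field(default_factory=lambda: dict(DEFAULT_DISCHARGE_COEFF))
    type_aliases: dict = field(default_factory=lambda: dict(DEFAULT_TYPE_ALIASES))
    clamp_accumulation: bool = True

    def canonical_type(self, ship_type: str) -> str:
        """Map a raw ship-type string onto an antifouling category."""
        key = str(ship_type).strip().casefold()
        canon = self.type_aliases.get(key)
        if canon is None:
            if key.capitalize() in self.antifouling:
                return key.capitalize()
            log.debug("ship type %r not in alias table; using 'other'", ship_type)
            return "other"
        return canon

    def antifouling_for(self, ship_type: str) -> float:
        return self.antifouling[self.canonical_type(ship_type)]

    def discharge_coeff_for(self, ship_type: str) -> float:
        canon = self.canonical_type(ship_type)
        if canon not in self.discharge_coeff:
            raise KeyError(f"no discharge coefficient for ship type {canon!r}")
        return self.discharge_coeff[canon]

    @classmethod
    def from_file(cls, path) -> "RiskParams":
        """Load parameters from a YAML or JSON config file."""
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        if "beta_tropical" in data:
            data["beta_tropical"] = tuple(data["beta_tropical"])
        if "beta_temperate" in data:
            data["beta_temperate"] = tuple(data["beta_temperate"])
        return cls(**data)

    def to_file(self, path) -> None:
        data = asdict(self)
        data["beta_tropical"] = list(data["beta_tropical"])
        data["beta_temperate"] = list(data["beta_temperate"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass
class PairRisk:
    """Aggregated spread risk for one ordered port pair and one vector."""

    source: str
    dest: str
    vector: str  # "ballast" | "biofouling"
    p_nonindigenous: float
    p_establish: float
    p_intro: float
    p_spread: float
    n_voyages: int


def prob_nonindigenous(port_i: Port, port_j: Port, eco: EcoregionGraph) -> float:
    """0/1 indicator: can a transfer between these ports be an introduction?

    0 when the ports lie in the same or neighboring ecoregions (shared native
    species pool), 1 otherwise. Symmetric.
    """
    a, b = port_i.ecoregion_id, port_j.ecoregion_id
    if a == b:
        if a not in eco.ecoregions:
            raise KeyError(f"unknown ecoregion id: {a}")
        return 0.0
    return 0.0 if eco.are_neighbors(a, b) else 1.0


def prob_establish(port_i: Port, port_j: Port, params: RiskParams | None = None) -> float:
    """Gaussian environmental-similarity establishment probability.

    ``alpha * exp(-0.5 * ((dT/delta_t)^2 + (dS/delta_s)^2))``; peaks at
    ``alpha`` for an identical environment and decays with temperature and
    salinity mismatch. Symmetric in the two ports.
    """
    p = params or RiskParams()
    dt = (port_i.temperature - port_j.temperature) / p.delta_t
    ds = (port_i.salinity - port_j.salinity) / p.delta_s
    return p.alpha * math.exp(-0.5 * (dt * dt + ds * ds))


def biofouling_accumulation(stay: float, zone: str, params: RiskParams | None = None) -> float:
    """Proportion of maximum fouling species richness after ``stay`` days in port.

    Zone-specific cubic ``b1*d^3 - b2*d^2 + b3*d`` (no constant term: a zero
    stay accumulates nothing), clamped into [0, 1] by default.
    """
    if stay < 0:
        raise ValueError("stay must be non-negative")
    p = params or RiskParams()
    if zone == "tropical":
        b1, b2, b3 = p.beta_tropical
    elif zone == "temperate":
        b1, b2, b3 = p.beta_temperate
    else:
        raise ValueError(f"unknown climate zone {zone!r}")
    raw = b1 * stay**3 - b2 * stay**2 + b3 * stay
    if not p.clamp_accumulation:
        return raw
    return min(1.0, max(0.0, raw))


def biofouling_survival(velocity: float, params: RiskParams | None = None) -> float:
    """En-route survival probability, exponential decay in voyage velocity."""
    if velocity < 0:
        raise ValueError("velocity must be non-negative")
    p = params or RiskParams()
    return math.exp(-p.gamma * velocity)


def biofouling_voyage_prob(
    voyage: Voyage, ship: Ship, source_zone: str, params: RiskParams | None = None
) -> float:
    """Per-voyage biofouling introduction probability.

    Antifouling share for the ship's type x accumulation over the source-port
    stay x survival at the voyage velocity.
    """
    p = params or RiskParams()
    if voyage.source_stay is None or voyage.velocity is None:
        raise ValueError("voyage needs source_stay and velocity (derive kinematics first)")
    return (
        p.antifouling_for(ship.ship_type)
        * biofouling_accumulation(voyage.source_stay, source_zone, p)
        * biofouling_survival(voyage.velocity, p)
    )


def ballast_discharge(
    ship: Ship, observed: float | None = None, params: RiskParams | None = None
) -> float:
    """Ballast volume discharged (m3): observed if reported, else type coefficient x GWT."""
    if observed is not None:
        return float(observed)
    p = params or RiskParams()
    return p.discharge_coeff_for(ship.ship_type) * ship.gwt


def ballast_voyage_prob(
    voyage: Voyage,
    ship: Ship,
    rho: float | None = None,
    params: RiskParams | None = None,
) -> float:
    """Per-voyage ballast introduction probability.

    ``rho * (1 - e^(-lam*D)) * e^(-mu*dt)`` with D the discharge volume and
    dt the voyage duration in days.
    """
    p = params or RiskParams()
    if voyage.duration is None:
        raise ValueError("voyage needs duration (derive kinematics first)")
    r = p.rho_default if rho is None else rho
    if not 0.0 <= r <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    d = ballast_discharge(ship, voyage.discharge_observed, p)
    return r * (1.0 - math.exp(-p.lam * d)) * math.exp(-p.mu * voyage.duration)


def aggregate_intro(voyage_probs) -> float:
    """Probability that at least one voyage introduces: ``1 - prod(1 - p_v)``.

    Order-independent; an empty list contributes zero risk.
    """
    total_log = 0.0
    for p in voyage_probs:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"voyage probability {p} outside [0, 1]")
        if p >= 1.0:
            return 1.0
        total_log += math.log1p(-p)
    return -math.expm1(total_log)


def voyage_prob(
    voyage: Voyage,
    ship: Ship,
    vector: str,
    ports: dict[str, Port],
    params: RiskParams | None = None,
) -> float:
    """Dispatch to the per-voyage probability for the requested vector."""
    if vector == "biofouling":
        zone = climate_zone(ports[voyage.source].latitude)
        return biofouling_voyage_prob(voyage, ship, zone, params)
    if vector == "ballast":
        return ballast_voyage_prob(voyage, ship, params=params)
    raise ValueError(f"unknown vector {vector!r}")


def pair_risk(
    port_i: Port,
    port_j: Port,
    vector: str,
    voyages: list[Voyage],
    ships: dict[str, Ship],
    eco: EcoregionGraph,
    params: RiskParams | None = None,
) -> PairRisk:
    """Aggregated spread risk for one ordered pair, over the given voyages."""
    p = params or RiskParams()
    ports = {port_i.port_id: port_i, port_j.port_id: port_j}
    probs = [voyage_prob(v, ships[v.ship_id], vector, ports, p) for v in voyages]
    p_non = prob_nonindigenous(port_i, port_j, eco)
    p_est = prob_establish(port_i, port_j, p)
    p_int = aggregate_intro(probs)
    return PairRisk(
        source=port_i.port_id, dest=port_j.port_id, vector=vector,
        p_nonindigenous=p_non, p_establish=p_est, p_intro=p_int,
        p_spread=p_non * p_est * p_int, n_voyages=len(voyages),
    )


def voyage_prob_table(
    voyages: list[Voyage],
    ports: dict[str, Port],
    ships: dict[str, Ship],
    vector: str,
    params: RiskParams | None = None,
) -> pd.DataFrame:
    """Vectorized per-voyage probabilities for a whole corpus.

    Self-loop voyages are excluded. Returns columns
    source, dest, ship_id, ship_type, p_voyage.
    """
    p = params or RiskParams()
    rows = []
    for v in voyages:
        if v.is_self_loop:
            continue
        rows.append((v.source, v.dest, v.ship_id,
                     v.source_stay, v.velocity, v.duration, v.discharge_observed))
    if not rows:
        return pd.DataFrame(columns=["source", "dest", "ship_id", "ship_type", "p_voyage"])
    df = pd.DataFrame(rows, columns=["source", "dest", "ship_id",
                                     "stay", "velocity", "duration", "discharge_obs"])
    type_of = {s.ship_id: p.canonical_type(s.ship_type) for s in ships.values()}
    gwt_of = {s.ship_id: s.gwt for s in ships.values()}
    df["ship_type"] = df["ship_id"].map(type_of)

    if vector == "biofouling":
        lat = {pid: pt.latitude for pid, pt in ports.items()}
        zone_tropical = df["source"].map(lat).abs() <= 35.0
        stay = df["stay"].to_numpy(dtype=float)
        b1t, b2t, b3t = p.beta_tropical
        b1p, b2p, b3p = p.beta_temperate
        acc_tr = b1t * stay**3 - b2t * stay**2 + b3t * stay
        acc_tp = b1p * stay**3 - b2p * stay**2 + b3p * stay
        acc = np.where(zone_tropical.to_numpy(), acc_tr, acc_tp)
        if p.clamp_accumulation:
            acc = np.clip(acc, 0.0, 1.0)
        surv = np.exp(-p.gamma * df["velocity"].to_numpy(dtype=float))
        af = df["ship_type"].map(p.antifouling).to_numpy(dtype=float)
        df["p_voyage"] = af * acc * surv
    elif vector == "ballast":
        coeff = df["ship_type"].map(p.discharge_coeff).to_numpy(dtype=float)
        gwt = df["ship_id"].map(gwt_of).to_numpy(dtype=float)
        obs = pd.to_numeric(df["discharge_obs"], errors="coerce").to_numpy(dtype=float)
        disc = np.where(np.isnan(obs), coeff * gwt, obs)
        df["p_voyage"] = (
            p.rho_default
            * (-np.expm1(-p.lam * disc))
            * np.exp(-p.mu * df["duration"].to_numpy(dtype=float))
        )
    else:
        raise ValueError(f"unknown vector {vector!r}")
    return df[["source", "dest", "ship_id", "ship_type", "p_voyage"]]


def pair_risk_table(
    voyages: list[Voyage],
    ports: dict[str, Port],
    ships: dict[str, Ship],
    eco: EcoregionGraph,
    vector: str,
    params: RiskParams | None = None,
) -> pd.DataFrame:
    """Per-pair aggregated spread risks for a whole corpus.

    Returns a DataFrame with one row per ordered port pair seen in the
    voyages: source, dest, vector, p_nonind, p_estab, p_intro, p_spread,
    n_voyages, sorted by (source, dest).
    """
    p = params or RiskParams()
    vdf = voyage_prob_table(voyages, ports, ships, vector, p)
    if vdf.empty:
        return pd.DataFrame(columns=["source", "dest", "vector", "p_nonind", "p_estab",
                                     "p_intro", "p_spread", "n_voyages"])
    grouped = vdf.groupby(["source", "dest"])["p_voyage"].agg(
        p_intro=lambda s: -np.expm1(np.log1p(-np.clip(s, 0.0, 1.0 - 1e-300)).sum())
        if (s < 1.0).all() else 1.0,
        n_voyages="size",
    ).reset_index()

    port_list = list(ports.values())
    temp = {pt.port_id: pt.temperature for pt in port_list}
    sal = {pt.port_id: pt.salinity for pt in port_list}
    eco_of = {pt.port_id: pt.ecoregion_id for pt in port_list}

    dt = (grouped["source"].map(temp) - grouped["dest"].map(temp)) / p.delta_t
    ds = (grouped["source"].map(sal) - grouped["dest"].map(sal)) / p.delta_s
    grouped["p_estab"] = p.alpha * np.exp(-0.5 * (dt**2 + ds**2))

    def nonind(row):
        a, b = eco_of[row["source"]], eco_of[row["dest"]]
        return 0.0 if (a == b or eco.are_neighbors(a, b)) else 1.0

    grouped["p_nonind"] = grouped.apply(nonind, axis=1)
    grouped["p_spread"] = grouped["p_nonind"] * grouped["p_estab"] * grouped["p_intro"]
    grouped["vector"] = vector
    out = grouped[["source", "dest", "vector", "p_nonind", "p_estab",
                   "p_intro", "p_spread", "n_voyages"]]
    return out.sort_values(["source", "dest"], ignore_index=True)


def write_pair_risks(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in ("p_nonind", "p_estab", "p_intro", "p_spread"):
        out[col] = out[col].map(lambda x: f"{x:.12g}")
    out.to_csv(path, index=False)
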