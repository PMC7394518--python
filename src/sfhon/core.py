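"""Domain types and voyage kinematics shared by every other module.

The central objects are ports (nodes of the shipping network, carrying the
environmental and biogeographic attributes that drive establishment risk),
ships (whose type and size drive the vector-specific introduction terms),
voyages (timed port-to-port movements), and trajectories (the per-ship
sequence of port calls from which higher-order dependencies are mined).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from datetime import date, datetime

log = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

#: latitude band (degrees, inclusive) treated as tropical/subtropical for the
#: biofouling accumulation curves
TROPICAL_LAT = 35.0

SHIP_TYPES = (
    "Container", "Auto", "Bulk", "General", "Tanker/Oil", "Chemical",
    "Gas", "Passenger", "Ref-Cargo", "Research", "Fishing", "Yacht", "Other",
)


@dataclass(frozen=True)
class Port:
    """A shipping port with the attributes needed for risk scoring.

    Ports missing temperature or salinity cannot be risk-scored and are
    dropped at read time.
    """

    port_id: str
    name: str
    latitude: float
    longitude: float
    temperature: float  # mean water temperature, deg C
    salinity: float     # mean salinity, ppt
    ecoregion_id: str
    realm_id: str
    region_id: str      # state/country used for evaluation

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"port {self.port_id}: latitude {self.latitude} out of range")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"port {self.port_id}: longitude {self.longitude} out of range")
        if self.salinity < 0:
            raise ValueError(f"port {self.port_id}: negative salinity")
        if not self.ecoregion_id or not self.realm_id:
            raise ValueError(f"port {self.port_id}: empty ecoregion/realm id")


@dataclass(frozen=True)
class Ship:
    ship_id: str
    ship_type: str
    gwt: float  # gross weight tonnage, tonnes

    def __post_init__(self) -> None:
        if self.gwt <= 0:
            raise ValueError(f"ship {self.ship_id}: gwt must be positive")


@dataclass
class Voyage:
    """One ship movement between two ports.

    ``distance``/``duration``/``velocity`` are filled in by
    :func:`derive_kinematics`; ``source_stay`` (days spent in the source port
    before sailing) by :func:`build_trajectories`.
    """

    ship_id: str
    source: str
    dest: str
    sail_date: date
    arrival_date: date
    duration: float | None = None     # days
    distance: float | None = None     # km, great-circle
    velocity: float | None = None     # km/day
    source_stay: float | None = None  # days
    discharge_observed: float | None = None  # m3, if reported

    def __post_init__(self) -> None:
        if self.arrival_date < self.sail_date:
            raise ValueError(
                f"voyage {self.ship_id} {self.source}->{self.dest}: arrival before sail"
            )

    @property
    def is_self_loop(self) -> bool:
        return self.source == self.dest


@dataclass(frozen=True)
class Visit:
    port_id: str
    arrival_date: date | None
    sail_date: date | None


@dataclass
class Trajectory:
    """Ordered port-call sequence of one ship (self-loops removed)."""

    ship_id: str
    visits: list[Visit] = field(default_factory=list)

    @property
    def ports(self) -> list[str]:
        return [v.port_id for v in self.visits]

    def __len__(self) -> int:
        return len(self.visits)


class EcoregionGraph:
    """Symmetric neighbor relation between marine ecoregions.

    Ports in the same or neighboring ecoregions are assumed to share native
    species pools, so transfers between them are not scored as nonindigenous.
    """

    def __init__(self, ecoregions, neighbor_pairs=()):
        self.ecoregions = set(ecoregions)
        self._neighbors: dict[str, set[str]] = {e: set() for e in self.ecoregions}
        for a, b in neighbor_pairs:
            self.add_neighbors(a, b)

    def add_neighbors(self, a: str, b: str) -> None:
        self.ecoregions.add(a)
        self.ecoregions.add(b)
        self._neighbors.setdefault(a, set()).add(b)
        self._neighbors.setdefault(b, set()).add(a)

    def are_neighbors(self, a: str, b: str) -> bool:
        if a not in self.ecoregions or b not in self.ecoregions:
            missing = a if a not in self.ecoregions else b
            raise KeyError(f"unknown ecoregion id: {missing}")
        return b in self._neighbors.get(a, ())

    @property
    def neighbor_pairs(self) -> set[frozenset]:
        return {
            frozenset((a, b))
            for a, nbrs in self._neighbors.items()
            for b in nbrs
        }


def parse_date(value) -> date:
    """Parse an ISO-8601 date (YYYY-MM-DD)."""
    if isinstance(value, date):
        return value
    return datetime.strptime(str(value).strip(), "%Y-%m-%d").date()


def climate_zone(latitude: float) -> str:
    """Classify a latitude as ``tropical`` or ``temperate``.

    The tropical/subtropical band is the equator +/- 35 degrees, boundary
    inclusive; the band selects which biofouling accumulation polynomial
    applies at the source port.
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude {latitude} out of range")
    return "tropical" if abs(latitude) <= TROPICAL_LAT else "temperate"


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km (spherical Earth, R = 6371 km)."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def derive_kinematics(
    voyage: Voyage, ports: dict[str, Port], duration_floor: float = 0.5
) -> Voyage:
    """Fill in distance, duration and velocity for a voyage.

    Duration is floored at ``duration_floor`` days so that same-day voyages
    do not produce infinite velocities. Self-loop voyages get distance 0 and
    are expected to be excluded downstream.
    """
    if duration_floor <= 0:
        raise ValueError("duration_floor must be positive")
    src, dst = ports[voyage.source], ports[voyage.dest]
    distance = haversine_km(src.latitude, src.longitude, dst.latitude, dst.longitude)
    raw_days = (voyage.arrival_date - voyage.sail_date).days
    duration = max(float(raw_days), duration_floor)
    return replace(
        voyage,
        distance=distance,
        duration=duration,
        velocity=distance / duration,
    )


def build_trajectories(
    voyages: list[Voyage], default_stay: float = 7.0
) -> dict[str, Trajectory]:
    """Assemble one trajectory per ship from its voyages.

    Voyages are ordered by sail date per ship; the stay at the source port
    before each departure is derived from the previous arrival there (or
    ``default_stay`` days for the ship's first observed departure).
    Self-loop voyages and immediate port repeats are removed.

    Mutates the ``source_stay`` field of the input voyages.
    """
    by_ship: dict[str, list[Voyage]] = {}
    for v in voyages:
        by_ship.setdefault(v.ship_id, []).append(v)

    out: dict[str, Trajectory] = {}
    for ship_id, vs in by_ship.items():
        vs.sort(key=lambda v: (v.sail_date, v.arrival_date))
        for prev, nxt in zip(vs, vs[1:]):
            if nxt.sail_date < prev.arrival_date:
                log.warning(
                    "ship %s: overlapping voyages (%s sails before %s arrives)",
                    ship_id, nxt.sail_date, prev.arrival_date,
                )
        traj = Trajectory(ship_id=ship_id)
        prev_arrival: date | None = None
        for v in vs:
            if prev_arrival is None:
                v.source_stay = default_stay
            else:
                v.source_stay = max(0.0, float((v.sail_date - prev_arrival).days))
            if not traj.visits:
                traj.visits.append(Visit(v.source, None, v.sail_date))
            if v.is_self_loop:
                prev_arrival = v.arrival_date
                continue
            if traj.visits[-1].port_id != v.source:
                # gap in the record: the ship repositioned unobserved
                traj.visits.append(Visit(v.source, None, v.sail_date))
            traj.visits.append(Visit(v.dest, v.arrival_date, None))
            prev_arrival = v.arrival_date
        if len(traj) >= 2:
            out[ship_id] = traj
    return out
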