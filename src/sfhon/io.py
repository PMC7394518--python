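"""CSV readers and writers for the neutral input schemas.

Schemas:
    ports.csv: port_id,name,lat,lon,temperature_c,salinity_ppt,ecoregion_id,realm_id,region_id
    ships.csv: ship_id,ship_type,gwt
    voyages.csv: ship_id,source_port,dest_port,sail_date,arrival_date[,discharge_m3]
    ecoregion_neighbors.csv: ecoregion_a,ecoregion_b (undirected)
    introductions.csv: region_id,n_first_introductions
"""

from __future__ import annotations

import logging

import pandas as pd

from .core import EcoregionGraph, Port, Ship, Voyage, parse_date

log = logging.getLogger(__name__)

PORT_COLUMNS = [
    "port_id", "name", "lat", "lon", "temperature_c", "salinity_ppt",
    "ecoregion_id", "realm_id", "region_id",
]


def read_ports(path) -> dict[str, Port]:
    """Read the port table; rows lacking temperature or salinity are dropped.

    Raises on duplicate port ids and on unparseable coordinates (naming the
    offending row). Returns a dict keyed by port_id.
    """
    df = pd.read_csv(path, dtype={"port_id": str, "ecoregion_id": str,
                                  "realm_id": str, "region_id": str})
    missing = [c for c in PORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ports file missing columns: {missing}")
    dupes = df["port_id"][df["port_id"].duplicated()].unique()
    if len(dupes):
        raise ValueError(f"duplicate port_id: {', '.join(map(str, dupes))}")

    ports: dict[str, Port] = {}
    n_dropped = 0
    for idx, row in df.iterrows():
        if pd.isna(row["temperature_c"]) or pd.isna(row["salinity_ppt"]):
            n_dropped += 1
            continue
        try:
            lat, lon = float(row["lat"]), float(row["lon"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"ports row {idx}: unparseable coordinates") from exc
        ports[row["port_id"]] = Port(
            port_id=row["port_id"],
            name=str(row["name"]),
            latitude=lat,
            longitude=lon,
            temperature=float(row["temperature_c"]),
            salinity=float(row["salinity_ppt"]),
            ecoregion_id=row["ecoregion_id"],
            realm_id=row["realm_id"],
            region_id=row["region_id"],
        )
    if n_dropped:
        log.info("read_ports: dropped %d ports missing temperature/salinity", n_dropped)
    return ports


def write_ports(ports: dict[str, Port], path) -> None:
    rows = [
        {
            "port_id": p.port_id, "name": p.name, "lat": p.latitude,
            "lon": p.longitude, "temperature_c": p.temperature,
            "salinity_ppt": p.salinity, "ecoregion_id": p.ecoregion_id,
            "realm_id": p.realm_id, "region_id": p.region_id,
        }
        for p in ports.values()
    ]
    pd.DataFrame(rows, columns=PORT_COLUMNS).to_csv(path, index=False)


def read_ships(path) -> dict[str, Ship]:
    df = pd.read_csv(path, dtype={"ship_id": str, "ship_type": str})
    dupes = df["ship_id"][df["ship_id"].duplicated()].unique()
    if len(dupes):
        raise ValueError(f"duplicate ship_id: {', '.join(map(str, dupes))}")
    return {
        row.ship_id: Ship(ship_id=row.ship_id, ship_type=row.ship_type, gwt=float(row.gwt))
        for row in df.itertuples()
    }


def write_ships(ships: dict[str, Ship], path) -> None:
    pd.DataFrame(
        [{"ship_id": s.ship_id, "ship_type": s.ship_type, "gwt": s.gwt} for s in ships.values()]
    ).to_csv(path, index=False)


def read_voyages(path, ports: dict[str, Port], ships: dict[str, Ship]) -> list[Voyage]:
    """Read voyages, dropping rows that reference unknown ports or ships.

    Rows with arrival before sail are rejected with a warning. Kinematics are
    not derived here (see :func:`sfhon.core.derive_kinematics`).
    """
    df = pd.read_csv(path, dtype={"ship_id": str, "source_port": str, "dest_port": str})
    voyages: list[Voyage] = []
    n_unknown = n_rejected = 0
    has_discharge = "discharge_m3" in df.columns
    for row in df.itertuples():
        if row.ship_id not in ships or row.source_port not in ports or row.dest_port not in ports:
            n_unknown += 1
            continue
        sail, arrival = parse_date(row.sail_date), parse_date(row.arrival_date)
        if arrival < sail:
            log.warning("voyage %s %s->%s: arrival before sail, rejected",
                        row.ship_id, row.source_port, row.dest_port)
            n_rejected += 1
            continue
        discharge = None
        if has_discharge and not pd.isna(row.discharge_m3):
            discharge = float(row.discharge_m3)
        voyages.append(Voyage(
            ship_id=row.ship_id, source=row.source_port, dest=row.dest_port,
            sail_date=sail, arrival_date=arrival, discharge_observed=discharge,
        ))
    if n_unknown:
        log.info("read_voyages: dropped %d voyages referencing unknown ports/ships", n_unknown)
    if n_rejected:
        log.info("read_voyages: rejected %d voyages with arrival before sail", n_rejected)
    return voyages


def write_voyages(voyages: list[Voyage], path) -> None:
    rows = [
        {
            "ship_id": v.ship_id, "source_port": v.source, "dest_port": v.dest,
            "sail_date": v.sail_date.isoformat(), "arrival_date": v.arrival_date.isoformat(),
            "discharge_m3": v.discharge_observed,
        }
        for v in voyages
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ecoregion_neighbors(path, extra_ecoregions=()) -> EcoregionGraph:
    df = pd.read_csv(path, dtype=str)
    eco = EcoregionGraph(extra_ecoregions)
    for row in df.itertuples():
        eco.add_neighbors(row.ecoregion_a, row.ecoregion_b)
    return eco


def write_ecoregion_neighbors(eco: EcoregionGraph, path) -> None:
    pairs = sorted(tuple(sorted(p)) for p in eco.neighbor_pairs)
    pd.DataFrame(pairs, columns=["ecoregion_a", "ecoregion_b"]).to_csv(path, index=False)


def read_introductions(path) -> pd.DataFrame:
    """Region-level first-introduction counts: region_id,n_first_introductions."""
    df = pd.read_csv(path, dtype={"region_id": str})
    if df["region_id"].duplicated().any():
        raise ValueError("duplicate region_id in introductions file")
    return df
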