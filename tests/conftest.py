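"""Shared fixtures: a tiny hand-built shipping world."""

from __future__ import annotations

from datetime import date

import pytest

from sfhon.core import EcoregionGraph, Port, Ship, Voyage
from sfhon.risk import RiskParams


def make_port(pid, lat=0.0, lon=0.0, temp=20.0, sal=30.0, eco="E1",
              realm="RL1", region="R1") -> Port:
    return Port(port_id=pid, name=pid, latitude=lat, longitude=lon,
                temperature=temp, salinity=sal, ecoregion_id=eco,
                realm_id=realm, region_id=region)


@pytest.fixture
def params() -> RiskParams:
    return RiskParams()


@pytest.fixture
def eco_graph() -> EcoregionGraph:
    # E1 - E2 neighbors; E3 isolated from both
    g = EcoregionGraph(["E1", "E2", "E3"])
    g.add_neighbors("E1", "E2")
    return g


@pytest.fixture
def toy_ports() -> dict[str, Port]:
    return {
        "A": make_port("A", lat=10.0, lon=0.0, temp=25.0, sal=30.0, eco="E1",
                       realm="RL1", region="R1"),
        "B": make_port("B", lat=12.0, lon=5.0, temp=24.0, sal=31.0, eco="E2",
                       realm="RL1", region="R1"),
        "C": make_port("C", lat=-40.0, lon=20.0, temp=12.0, sal=33.0, eco="E3",
                       realm="RL2", region="R2"),
        "D": make_port("D", lat=45.0, lon=-30.0, temp=11.0, sal=34.0, eco="E3",
                       realm="RL2", region="R2"),
    }


@pytest.fixture
def toy_ships() -> dict[str, Ship]:
    return {
        "S1": Ship("S1", "Container", 30000.0),
        "S2": Ship("S2", "Bulk", 45000.0),
    }


def make_voyage(ship="S1", src="A", dst="C", sail="2012-05-01",
                arrive="2012-05-08", **kw) -> Voyage:
    return Voyage(ship_id=ship, source=src, dest=dst,
                  sail_date=date.fromisoformat(sail),
                  arrival_date=date.fromisoformat(arrive), **kw)
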