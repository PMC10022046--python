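from importlib.resources import files

import pytest

from odflow.network import FlowEdge, FlowNetwork
from odflow.records_io import HospitalizationRecord, Municipality, read_registry
from odflow.synth import SyntheticScenario, generate_records, generate_registry


def make_muni(code, lat=-13.0, lon=-41.0, macroregion=None, **kw):
    return Municipality(code=code, name=f"M{code}", lat=lat, lon=lon,
                        macroregion=macroregion, **kw)


def make_network(year, edges, munis=None, intermunicipal_only=True):
    """Build a FlowNetwork from (origin, dest, weight, distance_km) tuples."""
    munis = munis or {}
    net = FlowNetwork(year=year, intermunicipal_only=intermunicipal_only)
    for o, d, w, dist in edges:
        mo = munis.get(o) or make_muni(o)
        md = munis.get(d) or make_muni(d)
        net.add_edge(FlowEdge(origin_code=o, dest_code=d, weight=w, distance_km=dist),
                     origin=mo, dest=md)
    return net


def record(year=2020, month=6, origin="290001", dest="290002", proc="0406010013"):
    return HospitalizationRecord(year=year, month=month, origin_code=origin,
                                 dest_code=dest, procedure_code=proc)


@pytest.fixture(scope="session")
def bcim_registry():
    """Reference city-point registry shipped with the package."""
    return read_registry(files("odflow").joinpath("data/bcim_points.csv"))


@pytest.fixture(scope="session")
def small_scenario():
    return SyntheticScenario(
        n_municipalities=12,
        provider_codes=("290001", "290002", "290003"),
        years=(2018, 2019, 2020),
        seed=7,
        theta=12.0,
        decay_km=250.0,
        procedure_codes=("0406010013", "0406010030"),
        procedure_weights=(0.7, 0.3),
    )


@pytest.fixture(scope="session")
def small_synth(small_scenario):
    registry = generate_registry(small_scenario)
    records = generate_records(small_scenario, registry)
    return small_scenario, registry, records
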