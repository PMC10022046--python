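"""Network export for visualization tools (GEXF primary, GraphML alternative).

Exports carry geographic node attributes (lat, lon, macroregion) so that a
Gephi geographic layout can reproduce map-style network views without any
extra join.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import networkx as nx

from .network import FlowEdge, FlowNetwork
from .records_io import Municipality

__all__ = ["to_networkx", "from_networkx", "export_gexf", "export_graphml"]


def to_networkx(net: FlowNetwork) -> nx.DiGraph:
    """Convert a FlowNetwork to a networkx DiGraph.

    Node attributes: label, lat, lon, macroregion; edge attributes:
    weight (journey count) and distance_km when attached.
    """
    g = nx.DiGraph(year=net.year)
    for code, m in sorted(net.vertices.items()):
        g.add_node(
            code,
            label=m.name,
            lat=float(m.lat),
            lon=float(m.lon),
            macroregion=m.macroregion or "",
        )
    for (o, d) in sorted(net.edges):
        e = net.edges[(o, d)]
        attrs = {"weight": int(e.weight)}
        if e.distance_km is not None:
            attrs["distance_km"] = float(e.distance_km)
        g.add_edge(o, d, **attrs)
    return g


def from_networkx(g: nx.DiGraph, year: int = 0, intermunicipal_only: bool = True) -> FlowNetwork:
    """Rebuild a FlowNetwork from a DiGraph read back from GEXF/GraphML."""
    year = int(g.graph.get("year", year))
    net = FlowNetwork(year=year, intermunicipal_only=intermunicipal_only)
    for o, d, attrs in g.edges(data=True):
        no, nd = g.nodes[o], g.nodes[d]
        mo = Municipality(
            code=str(o), name=str(no.get("label", o)),
            lat=float(no.get("lat", 0.0)), lon=float(no.get("lon", 0.0)),
            macroregion=str(no.get("macroregion", "")) or None,
        )
        md = Municipality(
            code=str(d), name=str(nd.get("label", d)),
            lat=float(nd.get("lat", 0.0)), lon=float(nd.get("lon", 0.0)),
            macroregion=str(nd.get("macroregion", "")) or None,
        )
        dist = attrs.get("distance_km")
        net.add_edge(
            FlowEdge(
                origin_code=str(o), dest_code=str(d),
                weight=int(attrs["weight"]),
                distance_km=None if dist is None else float(dist),
            ),
            origin=mo, dest=md,
        )
    # isolated nodes are legal in files even though builders omit them
    for n, attrs in g.nodes(data=True):
        net.vertices.setdefault(
            str(n),
            Municipality(
                code=str(n), name=str(attrs.get("label", n)),
                lat=float(attrs.get("lat", 0.0)), lon=float(attrs.get("lon", 0.0)),
                macroregion=str(attrs.get("macroregion", "")) or None,
            ),
        )
    return net


def export_gexf(net: FlowNetwork, path: Union[str, Path]) -> None:
    """Write a network as GEXF (directed, weighted, geolocated nodes)."""
    nx.write_gexf(to_networkx(net), str(path))


def export_graphml(net: FlowNetwork, path: Union[str, Path]) -> None:
    """Write a network as GraphML (directed, weighted, geolocated nodes)."""
    nx.write_graphml(to_networkx(net), str(path))
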