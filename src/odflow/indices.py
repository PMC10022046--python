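"""The six journey indices of a focal municipality and their time series.

For a focal municipality in one year's network:

* in-degree  (k_I): number of distinct municipalities with an arc into it;
* out-degree (k_O): number of distinct municipalities it has arcs to;
* incoming flow (F_I): total weight of incoming arcs (patients arriving);
* outgoing flow (F_O): total weight of outgoing arcs (residents leaving);
* mean length of incoming / outgoing arcs: the flow-weighted average of
  arc distances,  D-bar = sum_a(D_a * F_a) / sum_a(F_a),  over the arcs of
  the given direction; not applicable (NA) when the degree is zero.

NA is represented as ``None`` in memory and the literal string ``"NA"``
in CSV output; distances are rounded to two decimals and percentages to
one decimal at output time only.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Literal, Optional, Sequence, Union

from .network import FlowEdge, FlowNetwork

__all__ = [
    "Direction",
    "IndexRow",
    "MacroregionBreakdown",
    "in_degree",
    "out_degree",
    "incoming_flow",
    "outgoing_flow",
    "mean_arc_length",
    "index_row",
    "time_series",
    "macroregion_breakdown",
    "write_time_series",
    "INDEX_CSV_COLUMNS",
]

Direction = Literal["incoming", "outgoing"]

INDEX_CSV_COLUMNS = [
    "year",
    "in_degree",
    "out_degree",
    "incoming_flow",
    "outgoing_flow",
    "mean_in_length_km",
    "mean_out_length_km",
]


@dataclass(frozen=True)
class IndexRow:
    """The six indices of one focal municipality in one year."""

    year: int
    focal_code: str
    in_degree: int
    out_degree: int
    incoming_flow: int
    outgoing_flow: int
    mean_in_length: Optional[float]  # km; None == NA (in-degree is 0)
    mean_out_length: Optional[float]  # km; None == NA (out-degree is 0)

    def __post_init__(self) -> None:
        if self.in_degree < 0 or self.out_degree < 0:
            raise ValueError("degrees must be non-negative")
        if self.in_degree > 0 and self.incoming_flow < self.in_degree:
            raise ValueError("incoming flow below in-degree (arc weights are >= 1)")
        if self.out_degree > 0 and self.outgoing_flow < self.out_degree:
            raise ValueError("outgoing flow below out-degree (arc weights are >= 1)")
        if (self.mean_in_length is None) != (self.in_degree == 0):
            raise ValueError("mean_in_length must be NA exactly when in-degree is 0")
        if (self.mean_out_length is None) != (self.out_degree == 0):
            raise ValueError("mean_out_length must be NA exactly when out-degree is 0")

    def as_csv_row(self) -> List[str]:
        def fmt(v: Optional[float]) -> str:
            return "NA" if v is None else f"{v:.2f}"

        return [
            str(self.year),
            str(self.in_degree),
            str(self.out_degree),
            str(self.incoming_flow),
            str(self.outgoing_flow),
            fmt(self.mean_in_length),
            fmt(self.mean_out_length),
        ]


@dataclass(frozen=True)
class MacroregionBreakdown:
    """Counterpart municipalities of a focal vertex grouped by macroregion.

    Counts are numbers of distinct municipalities (they partition the
    degree, not the flow); percentages are 100 * count / degree at full
    precision — round at report time.
    """

    year: int
    direction: Direction
    counts: Dict[str, int]
    percentages: Dict[str, float]

    @property
    def degree(self) -> int:
        return sum(self.counts.values())

    def rounded(self, ndigits: int = 1) -> Dict[str, float]:
        return {k: round(v, ndigits) for k, v in self.percentages.items()}


def _focal_edges(net: FlowNetwork, focal: str, direction: Direction) -> List[FlowEdge]:
    if direction == "incoming":
        return net.in_edges(focal)
    if direction == "outgoing":
        return net.out_edges(focal)
    raise ValueError(f"unknown direction {direction!r}")


def in_degree(net: FlowNetwork, focal: str) -> int:
    """Number of distinct municipalities with an arc into the focal vertex."""
    return len(net.in_edges(focal))


def out_degree(net: FlowNetwork, focal: str) -> int:
    """Number of distinct municipalities the focal vertex has arcs to."""
    return len(net.out_edges(focal))


def incoming_flow(net: FlowNetwork, focal: str) -> int:
    """Total weight of arcs into the focal vertex (patients arriving)."""
    return sum(e.weight for e in net.in_edges(focal))


def outgoing_flow(net: FlowNetwork, focal: str) -> int:
    """Total weight of arcs out of the focal vertex (residents leaving)."""
    return sum(e.weight for e in net.out_edges(focal))


def mean_arc_length(
    net: FlowNetwork, focal: str, direction: Direction
) -> Optional[float]:
    """Flow-weighted mean arc distance of the focal vertex, in km.

    Computes  sum_a(D_a * F_a) / sum_a(F_a)  over the focal's arcs in the
    given direction.  Returns ``None`` (NA) when the degree is zero; an
    arc without a distance is a data error.
    """
    edges = _focal_edges(net, focal, direction)
    if not edges:
        return None
    num = 0.0
    den = 0
    for e in edges:
        if e.distance_km is None:
            raise ValueError(
                f"edge {e.origin_code}->{e.dest_code} has no distance; "
                "attach distances before computing mean arc lengths"
            )
        num += e.distance_km * e.weight
        den += e.weight
    return num / den


def index_row(net: FlowNetwork, focal: str) -> IndexRow:
    """Assemble the six indices of a focal municipality for one network."""
    return IndexRow(
        year=net.year,
        focal_code=focal,
        in_degree=in_degree(net, focal),
        out_degree=out_degree(net, focal),
        incoming_flow=incoming_flow(net, focal),
        outgoing_flow=outgoing_flow(net, focal),
        mean_in_length=mean_arc_length(net, focal, "incoming"),
        mean_out_length=mean_arc_length(net, focal, "outgoing"),
    )


def time_series(
    networks: Sequence[FlowNetwork],
    focal: str,
    years: Optional[Iterable[int]] = None,
) -> List[IndexRow]:
    """Per-year index rows for a focal municipality, sorted by year.

    ``years`` defaults to the full consecutive range spanned by the given
    networks; years in the range without a network yield the all-zero /
    NA row.  Duplicate network years are an input error.
    """
    by_year: Dict[int, FlowNetwork] = {}
    for net in networks:
        if net.year in by_year:
            raise ValueError(f"duplicate networks for year {net.year}")
        by_year[net.year] = net
    if years is None:
        if not by_year:
            return []
        years = range(min(by_year), max(by_year) + 1)
    rows: List[IndexRow] = []
    for year in sorted(set(years)):
        net = by_year.get(year)
        if net is None:
            rows.append(
                IndexRow(
                    year=year, focal_code=focal,
                    in_degree=0, out_degree=0,
                    incoming_flow=0, outgoing_flow=0,
                    mean_in_length=None, mean_out_length=None,
                )
            )
        else:
            rows.append(index_row(net, focal))
    return rows


def macroregion_breakdown(
    net: FlowNetwork, focal: str, direction: Direction
) -> MacroregionBreakdown:
    """Group the focal vertex's counterpart municipalities by macroregion.

    Incoming direction groups the origins sending patients to the focal
    municipality; outgoing groups its destinations.  Counterparts without
    a macroregion label fall into the "unknown" bucket.  Percentages are
    relative to the degree (distinct municipalities, not journeys); a
    degree of zero yields an empty, valid breakdown.
    """
    edges = _focal_edges(net, focal, direction)
    counts: Dict[str, int] = {}
    for e in edges:
        counterpart = e.origin_code if direction == "incoming" else e.dest_code
        muni = net.vertices.get(counterpart)
        label = (muni.macroregion if muni and muni.macroregion else "unknown")
        counts[label] = counts.get(label, 0) + 1
    degree = sum(counts.values())
    percentages = {k: 100.0 * v / degree for k, v in counts.items()} if degree else {}
    return MacroregionBreakdown(
        year=net.year, direction=direction, counts=counts, percentages=percentages
    )


def write_time_series(rows: Iterable[IndexRow], path: Union[str, Path]) -> int:
    """Write index rows as a CSV table, one row per year. Returns row count."""
    n = 0
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(INDEX_CSV_COLUMNS)
        for row in rows:
            writer.writerow(row.as_csv_row())
            n += 1
    return n
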