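"""Yearly origin-destination matrices and directed weighted flow networks.

A year's filtered records are first aggregated into an origin-destination
matrix (rows: municipality of residence, columns: municipality of
occurrence), then converted into a directed network whose edges carry the
journey count as weight and the inter-seat straight-line distance in km.

Self-journeys (residence == occurrence) are excluded from the network by
default — the analysis is intermunicipal — but are retained by
``count_by_provider`` so that per-provider hospitalization totals remain
reproducible.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Literal, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from . import geo
from .records_io import HospitalizationRecord, Municipality

logger = logging.getLogger(__name__)

__all__ = [
    "FlowEdge",
    "FlowNetwork",
    "ODMatrix",
    "UnresolvedReport",
    "build_od_matrix",
    "matrix_to_network",
    "records_to_network",
    "count_by_provider",
    "write_od_matrix",
    "read_od_matrix",
    "write_edge_list",
]


@dataclass(frozen=True)
class FlowEdge:
    """A directed arc: journeys from origin_code to dest_code in one year."""

    origin_code: str
    dest_code: str
    weight: int
    distance_km: Optional[float] = None

    def __post_init__(self) -> None:
        if self.weight < 1:
            raise ValueError(f"edge {self.origin_code}->{self.dest_code}: weight must be >= 1")


@dataclass
class FlowNetwork:
    """A directed weighted network G=(V, A) of one year's journeys.

    ``vertices`` maps municipality code to Municipality; every edge
    endpoint is a vertex, there is at most one edge per ordered pair, and
    vertices with no incident edge are omitted.
    """

    year: int
    vertices: Dict[str, Municipality] = field(default_factory=dict)
    edges: Dict[Tuple[str, str], FlowEdge] = field(default_factory=dict)
    intermunicipal_only: bool = True

    def add_edge(self, edge: FlowEdge, origin: Municipality, dest: Municipality) -> None:
        key = (edge.origin_code, edge.dest_code)
        if key in self.edges:
            raise ValueError(f"duplicate edge {key} in network year {self.year}")
        if self.intermunicipal_only and edge.origin_code == edge.dest_code:
            raise ValueError(f"self-loop {key} in intermunicipal-only network")
        self.edges[key] = edge
        self.vertices.setdefault(origin.code, origin)
        self.vertices.setdefault(dest.code, dest)

    def out_edges(self, code: str) -> List[FlowEdge]:
        return [e for e in self.edges.values() if e.origin_code == code]

    def in_edges(self, code: str) -> List[FlowEdge]:
        return [e for e in self.edges.values() if e.dest_code == code]

    @property
    def total_weight(self) -> int:
        return sum(e.weight for e in self.edges.values())

    def __contains__(self, code: str) -> bool:
        return code in self.vertices


@dataclass
class ODMatrix:
    """Origin-destination count matrix of one year.

    Rows are municipalities of residence, columns municipalities of
    occurrence; ``counts[i, j]`` is the number of journeys from
    ``row_codes[i]`` to ``col_codes[j]``.
    """

    year: int
    row_codes: List[str]
    col_codes: List[str]
    counts: np.ndarray  # int matrix, shape (len(row_codes), len(col_codes))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.row_codes), len(self.col_codes)):
            raise ValueError("counts shape does not match code lists")
        if len(set(self.row_codes)) != len(self.row_codes):
            raise ValueError("duplicate row codes")
        if len(set(self.col_codes)) != len(self.col_codes):
            raise ValueError("duplicate column codes")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def cell(self, origin_code: str, dest_code: str) -> int:
        try:
            i = self.row_codes.index(origin_code)
            j = self.col_codes.index(dest_code)
        except ValueError:
            return 0
        return int(self.counts[i, j])


@dataclass
class UnresolvedReport:
    """Municipality codes in the data but absent from the registry."""

    unresolved_codes: List[str] = field(default_factory=list)
    dropped_journeys: int = 0

    @property
    def any(self) -> bool:
        return bool(self.unresolved_codes)


def build_od_matrix(records: Iterable[HospitalizationRecord], year: int) -> ODMatrix:
    """Aggregate one year's records into an origin-destination matrix.

    ``records`` must already be procedure-filtered.  The matrix total
    equals the number of that year's records; a year with no records
    yields an empty matrix.
    """
    pair_counts: Dict[Tuple[str, str], int] = {}
    for rec in records:
        if rec.year != year:
            continue
        key = (rec.origin_code, rec.dest_code)
        pair_counts[key] = pair_counts.get(key, 0) + 1
    row_codes = sorted({o for o, _ in pair_counts})
    col_codes = sorted({d for _, d in pair_counts})
    counts = np.zeros((len(row_codes), len(col_codes)), dtype=np.int64)
    row_idx = {c: i for i, c in enumerate(row_codes)}
    col_idx = {c: j for j, c in enumerate(col_codes)}
    for (o, d), n in pair_counts.items():
        counts[row_idx[o], col_idx[d]] = n
    return ODMatrix(year=year, row_codes=row_codes, col_codes=col_codes, counts=counts)


def matrix_to_network(
    matrix: ODMatrix,
    registry: Mapping[str, Municipality],
    intermunicipal_only: bool = True,
    distance_method: Literal["utm", "great_circle"] = "utm",
) -> Tuple[FlowNetwork, UnresolvedReport]:
    """Convert an OD matrix into a directed weighted network.

    One edge per nonzero cell; diagonal cells are dropped when
    ``intermunicipal_only``.  Each edge gets its straight-line distance.
    Codes that cannot be resolved in the registry are excluded and
    reported (with the number of journeys dropped), never fatal.
    """
    net = FlowNetwork(year=matrix.year, intermunicipal_only=intermunicipal_only)
    report = UnresolvedReport()
    unresolved: Dict[str, bool] = {}
    for i, o in enumerate(matrix.row_codes):
        for j, d in enumerate(matrix.col_codes):
            w = int(matrix.counts[i, j])
            if w == 0:
                continue
            if intermunicipal_only and o == d:
                continue
            mo = registry.get(o)
            md = registry.get(d)
            if mo is None or md is None:
                for code, m in ((o, mo), (d, md)):
                    if m is None and code not in unresolved:
                        unresolved[code] = True
                report.dropped_journeys += w
                continue
            dist = geo.distance_km(mo, md, method=distance_method)
            net.add_edge(
                FlowEdge(origin_code=o, dest_code=d, weight=w, distance_km=dist),
                origin=mo,
                dest=md,
            )
    report.unresolved_codes = sorted(unresolved)
    if report.any:
        logger.warning(
            "year %d: %d unresolved municipality codes, %d journeys dropped: %s",
            matrix.year, len(report.unresolved_codes), report.dropped_journeys,
            report.unresolved_codes,
        )
    return net, report


def records_to_network(
    records: Iterable[HospitalizationRecord],
    year: int,
    registry: Mapping[str, Municipality],
    intermunicipal_only: bool = True,
    distance_method: Literal["utm", "great_circle"] = "utm",
) -> Tuple[FlowNetwork, UnresolvedReport]:
    """Convenience: build the OD matrix and convert it in one step."""
    matrix = build_od_matrix(records, year)
    return matrix_to_network(
        matrix, registry,
        intermunicipal_only=intermunicipal_only,
        distance_method=distance_method,
    )


def count_by_provider(
    records: Iterable[HospitalizationRecord], year: int
) -> Dict[str, int]:
    """Hospitalization counts per provider (destination) municipality.

    Unlike the network, this includes residents hospitalized in their own
    municipality: it reproduces per-provider service totals.
    """
    counts: Dict[str, int] = {}
    for rec in records:
        if rec.year != year:
            continue
        counts[rec.dest_code] = counts.get(rec.dest_code, 0) + 1
    return counts


def write_od_matrix(matrix: ODMatrix, path: Union[str, Path]) -> None:
    """Write an OD matrix as CSV with row/column code headers."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["origin\\dest"] + list(matrix.col_codes))
        for i, o in enumerate(matrix.row_codes):
            writer.writerow([o] + [int(v) for v in matrix.counts[i]])


def read_od_matrix(path: Union[str, Path], year: int) -> ODMatrix:
    """Read an OD matrix written by :func:`write_od_matrix`."""
    with Path(path).open(newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        return ODMatrix(year=year, row_codes=[], col_codes=[], counts=np.zeros((0, 0)))
    col_codes = rows[0][1:]
    row_codes = [r[0] for r in rows[1:]]
    counts = np.array([[int(v) for v in r[1:]] for r in rows[1:]], dtype=np.int64)
    if counts.size == 0:
        counts = counts.reshape(len(row_codes), len(col_codes))
    return ODMatrix(year=year, row_codes=row_codes, col_codes=col_codes, counts=counts)


def write_edge_list(net: FlowNetwork, path: Union[str, Path]) -> int:
    """Write a network as an origin,destination,weight,distance_km CSV.

    Returns the number of edges written. Distances are printed with two
    decimals (full precision is kept in memory only).
    """
    n = 0
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["origin", "destination", "weight", "distance_km"])
        for (o, d) in sorted(net.edges):
            e = net.edges[(o, d)]
            dist = "" if e.distance_km is None else f"{e.distance_km:.2f}"
            writer.writerow([o, d, e.weight, dist])
            n += 1
    return n
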