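"""Reading, validating and filtering hospitalization records and the
municipality registry from delimited text files.

Input conventions
-----------------
* Records CSV header: ``year,month,origin_code,dest_code,procedure_code``
  (remappable through a column-name mapping).
* Registry CSV header: ``code,name,lat,lon[,easting,northing,utm_zone,macroregion]``.
* Either comma- or semicolon-delimited; UTF-8 with a Latin-1 fallback.
* Municipality codes are normalised to their 6 significant digits: registry
  sources often carry a 7th check digit which is truncated so that joins
  across sources are robust.

Rows of the records file that violate an invariant are never silently
dropped: they are collected into a rejection report so that
``accepted + rejected == total rows`` always holds.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Set, Tuple, Union

logger = logging.getLogger(__name__)

__all__ = [
    "HospitalizationRecord",
    "Municipality",
    "ProcedureFilter",
    "Rejection",
    "ReadResult",
    "InputError",
    "SchemaError",
    "DataError",
    "normalize_code",
    "read_records",
    "write_records",
    "read_registry",
    "write_registry",
    "read_procedure_filter",
    "filter_by_procedure",
    "DEFAULT_RECORD_SCHEMA",
]

DEFAULT_RECORD_SCHEMA: Mapping[str, str] = {
    "year": "year",
    "month": "month",
    "origin_code": "origin_code",
    "dest_code": "dest_code",
    "procedure_code": "procedure_code",
}

#: accepted competence-year window; SIH RD files exist from the mid-1990s
DEFAULT_YEAR_RANGE: Tuple[int, int] = (1990, 2100)


class InputError(OSError):
    """A required input file is missing or unreadable."""


class SchemaError(ValueError):
    """The file header does not carry the mapped columns."""


class DataError(ValueError):
    """A row violates a data invariant that cannot be skipped."""


def normalize_code(code: str) -> str:
    """Normalise a municipality code to its 6 significant digits.

    7-digit IBGE codes carry a trailing check digit that SIH files omit;
    truncating it makes codes comparable across sources.  Non-numeric or
    shorter codes are passed through stripped.
    """
    code = str(code).strip()
    if len(code) == 7 and code.isdigit():
        return code[:6]
    return code


@dataclass(frozen=True)
class HospitalizationRecord:
    """One hospitalization authorization: a single patient journey event.

    The unit is the record (one authorization form), not a unique patient;
    duplicates are meaningful and kept.
    """

    year: int
    month: int
    origin_code: str
    dest_code: str
    procedure_code: str

    def validate(self, year_range: Tuple[int, int] = DEFAULT_YEAR_RANGE) -> None:
        lo, hi = year_range
        if not lo <= self.year <= hi:
            raise DataError(f"year {self.year} outside [{lo}, {hi}]")
        if not 1 <= self.month <= 12:
            raise DataError(f"month {self.month} outside [1, 12]")
        if not self.origin_code:
            raise DataError("empty origin_code")
        if not self.dest_code:
            raise DataError("empty dest_code")
        if not self.procedure_code:
            raise DataError("empty procedure_code")


@dataclass(frozen=True)
class Municipality:
    """A network vertex: municipality code, point location, macroregion.

    Coordinates are carried in two systems: geographic (decimal degrees,
    required) and UTM (metres, optional).  UTM fields come as a complete
    triple (easting, northing, zone) or not at all.
    """

    code: str
    name: str
    lat: float
    lon: float
    easting: Optional[float] = None
    northing: Optional[float] = None
    utm_zone: Optional[int] = None
    utm_hemisphere: str = "S"
    macroregion: Optional[str] = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise DataError(f"municipality {self.code}: latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise DataError(f"municipality {self.code}: longitude {self.lon} outside [-180, 180]")
        utm_fields = (self.easting, self.northing, self.utm_zone)
        if any(v is not None for v in utm_fields) and any(v is None for v in utm_fields):
            raise DataError(
                f"municipality {self.code}: partial UTM triple "
                "(easting, northing and utm_zone must be given together)"
            )

    @property
    def has_utm(self) -> bool:
        return self.easting is not None


@dataclass(frozen=True)
class ProcedureFilter:
    """A named set of procedure codes defining the service group of interest."""

    codes: frozenset
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "codes", frozenset(str(c).strip() for c in self.codes))
        if not self.codes:
            raise DataError("procedure filter must contain at least one code")

    def __contains__(self, code: str) -> bool:
        return code in self.codes


@dataclass(frozen=True)
class Rejection:
    """One rejected input row and the reason it failed validation."""

    row_number: int  # 1-based, counting data rows (header excluded)
    reason: str
    raw: Mapping[str, str] = field(default_factory=dict)


@dataclass
class ReadResult:
    """Accepted records plus the rejection report of one file read.

    Iterating a ``ReadResult`` iterates the accepted records, so it can be
    passed anywhere a record sequence is expected.
    """

    records: List[HospitalizationRecord]
    rejections: List[Rejection]

    def __iter__(self) -> Iterator[HospitalizationRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def total_rows(self) -> int:
        return len(self.records) + len(self.rejections)


def _open_sniffed(path: Union[str, Path]):
    """Open a delimited text file, auto-detecting encoding and delimiter.

    Returns ``(file_object, delimiter)``.  UTF-8 is tried first, falling
    back to Latin-1 (common in Brazilian administrative exports).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    raw = path.read_bytes()
    try:
        text = raw.decode("utf-8")
    except UnicodeDecodeError:
        text = raw.decode("latin-1")
    sample = text[:4096]
    delimiter = ";" if sample.count(";") > sample.count(",") else ","
    return io.StringIO(text), delimiter


def read_records(
    path: Union[str, Path],
    schema: Optional[Mapping[str, str]] = None,
    year_range: Tuple[int, int] = DEFAULT_YEAR_RANGE,
) -> ReadResult:
    """Read hospitalization records from a delimited file.

    ``schema`` maps the canonical field names (``year``, ``month``,
    ``origin_code``, ``dest_code``, ``procedure_code``) to the column names
    actually present in the file header.

    Rows failing an invariant are returned in ``result.rejections`` with
    the violated rule; the identity ``accepted + rejected == data rows``
    always holds.
    """
    schema = dict(DEFAULT_RECORD_SCHEMA if schema is None else schema)
    fobj, delimiter = _open_sniffed(path)
    reader = csv.DictReader(fobj, delimiter=delimiter)
    if reader.fieldnames is None:
        logger.warning("records file %s is empty", path)
        return ReadResult(records=[], rejections=[])
    header = set(reader.fieldnames)
    missing = [col for col in schema.values() if col not in header]
    if missing:
        raise SchemaError(f"records file {path} is missing mapped columns: {missing}")

    records: List[HospitalizationRecord] = []
    rejections: List[Rejection] = []
    for i, row in enumerate(reader, start=1):
        try:
            rec = HospitalizationRecord(
                year=int(str(row[schema["year"]]).strip()),
                month=int(str(row[schema["month"]]).strip()),
                origin_code=normalize_code(row[schema["origin_code"]]),
                dest_code=normalize_code(row[schema["dest_code"]]),
                procedure_code=str(row[schema["procedure_code"]]).strip(),
            )
            rec.validate(year_range)
        except (DataError, ValueError, TypeError) as exc:
            rejections.append(Rejection(row_number=i, reason=str(exc), raw=dict(row)))
            continue
        records.append(rec)
    if not records and not rejections:
        logger.warning("records file %s has a header but no data rows", path)
    return ReadResult(records=records, rejections=rejections)


def write_records(
    records: Iterable[HospitalizationRecord],
    path: Union[str, Path],
) -> int:
    """Write records as CSV with the documented header. Returns the row count."""
    path = Path(path)
    n = 0
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["year", "month", "origin_code", "dest_code", "procedure_code"])
        for rec in records:
            writer.writerow([rec.year, rec.month, rec.origin_code, rec.dest_code, rec.procedure_code])
            n += 1
    return n


def read_registry(path: Union[str, Path]) -> Dict[str, Municipality]:
    """Read the municipality registry into a mapping code -> Municipality.

    Duplicate codes (after 6-digit normalisation) and out-of-range
    coordinates are data errors, not warnings: a registry is reference
    data and must be internally consistent.
    """
    fobj, delimiter = _open_sniffed(path)
    reader = csv.DictReader(fobj, delimiter=delimiter)
    required = {"code", "name", "lat", "lon"}
    if reader.fieldnames is None or not required <= set(reader.fieldnames):
        raise SchemaError(
            f"registry file {path} must have columns {sorted(required)}; "
            f"found {reader.fieldnames}"
        )
    registry: Dict[str, Municipality] = {}
    for row in reader:
        code = normalize_code(row["code"])
        if code in registry:
            raise DataError(f"duplicate municipality code {code!r} in registry {path}")

        def _opt_float(key: str) -> Optional[float]:
            v = (row.get(key) or "").strip()
            return float(v) if v else None

        zone_raw = (row.get("utm_zone") or "").strip()
        hemisphere = "S"
        zone: Optional[int] = None
        if zone_raw:
            # accept "24", "24S", "24N"
            if zone_raw[-1] in "NSns":
                hemisphere = zone_raw[-1].upper()
                zone_raw = zone_raw[:-1]
            zone = int(zone_raw)
        registry[code] = Municipality(
            code=code,
            name=(row.get("name") or "").strip(),
            lat=float(row["lat"]),
            lon=float(row["lon"]),
            easting=_opt_float("easting"),
            northing=_opt_float("northing"),
            utm_zone=zone,
            utm_hemisphere=hemisphere,
            macroregion=(row.get("macroregion") or "").strip() or None,
        )
    return registry


def write_registry(registry: Mapping[str, Municipality], path: Union[str, Path]) -> None:
    """Write a municipality registry as CSV with the documented header."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["code", "name", "lat", "lon", "easting", "northing", "utm_zone", "macroregion"]
        )
        for code in sorted(registry):
            m = registry[code]
            zone = f"{m.utm_zone}{m.utm_hemisphere}" if m.utm_zone is not None else ""
            writer.writerow(
                [
                    m.code,
                    m.name,
                    repr(m.lat),
                    repr(m.lon),
                    "" if m.easting is None else repr(m.easting),
                    "" if m.northing is None else repr(m.northing),
                    zone,
                    m.macroregion or "",
                ]
            )


def read_procedure_filter(path: Union[str, Path], label: str = "") -> ProcedureFilter:
    """Read a newline-delimited procedure-code list; '#' starts a comment."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"procedure list not found: {path}")
    codes: Set[str] = set()
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            codes.add(line)
    return ProcedureFilter(codes=frozenset(codes), label=label or path.stem)


def filter_by_procedure(
    records: Iterable[HospitalizationRecord],
    procedure_filter: ProcedureFilter,
) -> List[HospitalizationRecord]:
    """Keep only the records whose procedure code is in the filter set.

    Order is preserved; an empty result is valid. The operation is
    idempotent.
    """
    return [rec for rec in records if rec.procedure_code in procedure_filter.codes]
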