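"""Data model and file I/O for survey fraud screening.

A survey export is an RFC-4180 CSV with one row per completed case. Each
conforming export carries a case identifier, start/end timestamps (ISO-8601,
ideally with a UTC offset), an IANA time-zone column when the collection
platform records one, identity fields used for consistency checks (reported
US state, 3-digit zip prefix, treatment facility, referral source, hashed
email), and one column per survey item. Which columns mean what is declared
by a :class:`SurveySchema` loaded from a JSON config.

Timestamps are kept zone-aware. A case whose timestamps cannot be parsed
with an explicit zone/offset is loaded anyway and annotated
``invalid timestamp data``; it is excluded only from time-dependent checks,
never silently dropped.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import datetime
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping
from zoneinfo import ZoneInfo

__all__ = [
    "SchemaError",
    "DataFormatError",
    "ItemSpec",
    "SurveySchema",
    "ResponseRecord",
    "ScreeningRecord",
    "ZipRegionMap",
    "load_schema",
    "load_responses",
    "write_responses",
    "load_screening",
    "write_screening",
    "load_zip_map",
    "packaged_zip_map",
    "packaged_facilities",
    "packaged_channels",
    "load_name_list",
]

ITEM_KINDS = ("closed", "open", "hidden")

# Column names every export must carry besides the per-item columns.
CASE_ID_COL = "case_id"


class SchemaError(ValueError):
    """Raised for malformed schema configs or schema/export mismatches."""


class DataFormatError(ValueError):
    """Raised for malformed export or mapping files."""


@dataclass(frozen=True)
class ItemSpec:
    item_id: str
    kind: str  # closed | open | hidden
    page: str
    domain: tuple | None = None  # permitted values for closed items


@dataclass(frozen=True)
class SurveySchema:
    """Declarative description of a survey instrument.

    ``pages`` is an ordered mapping page id -> ordered item ids; ``items``
    maps item id -> :class:`ItemSpec`. ``time_fields`` names the start/end
    timestamp columns; ``identity_fields`` maps the roles state, zip_prefix,
    facility, referral, email_hash and (optionally) tz to column names.
    """

    pages: tuple[tuple[str, tuple[str, ...]], ...]
    items: Mapping[str, ItemSpec]
    time_fields: tuple[str, str]
    identity_fields: Mapping[str, str]

    def item_ids(self, kind: str | None = None) -> list[str]:
        if kind is None:
            return list(self.items)
        return [i for i, s in self.items.items() if s.kind == kind]

    @property
    def closed_items(self) -> list[str]:
        return self.item_ids("closed")

    @property
    def open_items(self) -> list[str]:
        return self.item_ids("open")

    @property
    def hidden_items(self) -> list[str]:
        return self.item_ids("hidden")

    def page_closed_items(self) -> dict[str, list[str]]:
        """Closed item ids grouped by page, in page order."""
        out: dict[str, list[str]] = {}
        for page_id, item_ids in self.pages:
            out[page_id] = [i for i in item_ids if self.items[i].kind == "closed"]
        return out

    def export_columns(self) -> list[str]:
        cols = [CASE_ID_COL, *self.time_fields]
        cols += [self.identity_fields[k] for k in sorted(self.identity_fields)]
        cols += list(self.items)
        return cols

    def validate(self) -> None:
        seen: set[str] = set()
        for page_id, item_ids in self.pages:
            for i in item_ids:
                if i in seen:
                    raise SchemaError(f"item {i!r} appears on more than one page")
                seen.add(i)
                if i not in self.items:
                    raise SchemaError(f"page {page_id!r} lists unknown item {i!r}")
        for i, spec in self.items.items():
            if spec.kind not in ITEM_KINDS:
                raise SchemaError(f"item {i!r} has unknown kind {spec.kind!r}")
            if i not in seen:
                raise SchemaError(f"item {i!r} belongs to no page")
        if len(self.time_fields) != 2:
            raise SchemaError("time_fields must name exactly start and end columns")


@dataclass
class ResponseRecord:
    """One completed survey case, raw content plus parse annotations."""

    case_id: str
    start_ts: datetime | None
    end_ts: datetime | None
    tzname: str | None
    closed: dict[str, str]
    open: dict[str, str]
    hidden: dict[str, str]
    reported_state: str | None
    zip_prefix: str | None
    facility: str | None
    referral_source: str | None
    email_hash: str | None
    data_errors: list[str] = field(default_factory=list)

    @property
    def valid_timestamps(self) -> bool:
        return (
            self.start_ts is not None
            and self.end_ts is not None
            and self.start_ts.tzinfo is not None
            and self.end_ts.tzinfo is not None
        )


@dataclass(frozen=True)
class ScreeningRecord:
    """One eligibility-screening submission."""

    screening_id: str
    submitted_ts: datetime
    passed: bool
    case_id: str | None = None  # linked survey case when the respondent enrolled

    def __post_init__(self) -> None:
        if self.submitted_ts.tzinfo is None:
            raise DataFormatError(
                f"screening {self.screening_id}: submitted_ts must be zone-aware"
            )


@dataclass(frozen=True)
class ZipRegionMap:
    """zip3 -> state and state -> plausible IANA zones lookup tables."""

    zip3_to_state: Mapping[str, str]
    state_to_zones: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        missing = {s for s in self.zip3_to_state.values() if s not in self.state_to_zones}
        if missing:
            raise DataFormatError(
                f"states in zip3 table without zone entries: {sorted(missing)}"
            )

    @property
    def us_zones(self) -> frozenset[str]:
        out: set[str] = set()
        for zones in self.state_to_zones.values():
            out |= zones
        return frozenset(out)

    @property
    def empty(self) -> bool:
        return not self.zip3_to_state and not self.state_to_zones


# ---------------------------------------------------------------------------
# schema config


def load_schema(path: str | Path) -> SurveySchema:
    """Load and validate a survey schema from a JSON config file."""
    path = Path(path)
    with path.open() as fh:
        cfg = json.load(fh)
    return schema_from_dict(cfg)


def schema_from_dict(cfg: Mapping) -> SurveySchema:
    items: dict[str, ItemSpec] = {}
    pages = []
    item_page: dict[str, str] = {}
    for page in cfg.get("pages", []):
        pid = page["id"]
        ids = tuple(page.get("items", []))
        pages.append((pid, ids))
        for i in ids:
            if i in item_page:
                raise SchemaError(f"duplicate item id {i!r}")
            item_page[i] = pid
    for i, spec in cfg.get("items", {}).items():
        if i not in item_page:
            raise SchemaError(f"item {i!r} belongs to no page")
        domain = tuple(spec["domain"]) if spec.get("domain") else None
        items[i] = ItemSpec(i, spec["kind"], item_page[i], domain)
    for i in item_page:
        if i not in items:
            raise SchemaError(f"page lists unknown item {i!r}")
    schema = SurveySchema(
        pages=tuple(pages),
        items=items,
        time_fields=tuple(cfg["time_fields"]),
        identity_fields=dict(cfg["identity_fields"]),
    )
    schema.validate()
    return schema


def schema_to_dict(schema: SurveySchema) -> dict:
    return {
        "pages": [{"id": p, "items": list(ids)} for p, ids in schema.pages],
        "items": {
            i: {"kind": s.kind, **({"domain": list(s.domain)} if s.domain else {})}
            for i, s in schema.items.items()
        },
        "time_fields": list(schema.time_fields),
        "identity_fields": dict(schema.identity_fields),
    }


# ---------------------------------------------------------------------------
# timestamp parsing


def parse_ts(raw: str | None) -> tuple[datetime | None, bool]:
    """Parse an ISO-8601 timestamp.

    Returns ``(dt, ok)``; ``dt`` is zone-aware on success. A parseable but
    zone-naive timestamp yields ``(naive_dt, False)`` so callers can report
    invalid-zone data without losing the clock reading.
    """
    if raw is None or str(raw).strip() == "":
        return None, False
    text = str(raw).strip()
    try:
        dt = datetime.fromisoformat(text)
    except ValueError:
        return None, False
    return dt, dt.tzinfo is not None


# ---------------------------------------------------------------------------
# response exports


def _get(row: Mapping[str, str], col: str) -> str | None:
    val = row.get(col)
    if val is None or str(val).strip() == "":
        return None
    return str(val)


def load_responses(path: str | Path, schema: SurveySchema) -> list[ResponseRecord]:
    """Load a survey export CSV into :class:`ResponseRecord` objects.

    Never silently drops rows: malformed timestamps and end<start orderings
    become per-record ``data_errors`` annotations. Duplicate case ids and a
    header that does not cover the schema's declared columns are fatal.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in schema.export_columns() if c not in header]
        if missing:
            raise SchemaError(f"export header missing schema columns: {missing}")
        rows = list(reader)

    start_col, end_col = schema.time_fields
    idf = schema.identity_fields
    tz_col = idf.get("tz")
    records: list[ResponseRecord] = []
    seen: set[str] = set()
    for row in rows:
        case_id = _get(row, CASE_ID_COL)
        if case_id is None:
            raise DataFormatError("row with empty case_id")
        if case_id in seen:
            raise DataFormatError(f"duplicate case_id {case_id!r}")
        seen.add(case_id)
        errors: list[str] = []
        start_ts, start_ok = parse_ts(_get(row, start_col))
        end_ts, end_ok = parse_ts(_get(row, end_col))
        if not (start_ok and end_ok):
            errors.append("invalid timestamp data")
        elif end_ts < start_ts:
            errors.append("end timestamp precedes start timestamp")
        zip_prefix = _get(row, idf["zip_prefix"])
        if zip_prefix is not None and not (len(zip_prefix) == 3 and zip_prefix.isdigit()):
            errors.append(f"zip prefix {zip_prefix!r} is not 3 digits")
            zip_prefix = None
        records.append(
            ResponseRecord(
                case_id=case_id,
                start_ts=start_ts,
                end_ts=end_ts,
                tzname=_get(row, tz_col) if tz_col else None,
                closed={i: v for i in schema.closed_items if (v := _get(row, i)) is not None},
                open={i: v for i in schema.open_items if (v := _get(row, i)) is not None},
                hidden={i: v for i in schema.hidden_items if (v := _get(row, i)) is not None},
                reported_state=_get(row, idf["state"]),
                zip_prefix=zip_prefix,
                facility=_get(row, idf["facility"]),
                referral_source=_get(row, idf["referral"]),
                email_hash=_get(row, idf["email_hash"]),
                data_errors=errors,
            )
        )
    return records


def write_responses(
    records: Iterable[ResponseRecord], schema: SurveySchema, path: str | Path
) -> None:
    """Write records back to the CSV dialect :func:`load_responses` reads."""
    path = Path(path)
    cols = schema.export_columns()
    start_col, end_col = schema.time_fields
    idf = schema.identity_fields
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols)
        writer.writeheader()
        for rec in records:
            row = {c: "" for c in cols}
            row[CASE_ID_COL] = rec.case_id
            row[start_col] = rec.start_ts.isoformat() if rec.start_ts else ""
            row[end_col] = rec.end_ts.isoformat() if rec.end_ts else ""
            if "tz" in idf:
                row[idf["tz"]] = rec.tzname or ""
            row[idf["state"]] = rec.reported_state or ""
            row[idf["zip_prefix"]] = rec.zip_prefix or ""
            row[idf["facility"]] = rec.facility or ""
            row[idf["referral"]] = rec.referral_source or ""
            row[idf["email_hash"]] = rec.email_hash or ""
            for mapping in (rec.closed, rec.open, rec.hidden):
                for i, v in mapping.items():
                    row[i] = v
            writer.writerow(row)


# ---------------------------------------------------------------------------
# screening exports

SCREENING_COLS = ["screening_id", "submitted_ts", "passed", "case_id"]


def load_screening(path: str | Path) -> list[ScreeningRecord]:
    path = Path(path)
    out: list[ScreeningRecord] = []
    seen: set[str] = set()
    with path.open(newline="") as fh:
        for row in csv.DictReader(fh):
            sid = _get(row, "screening_id")
            if sid is None:
                raise DataFormatError("screening row with empty screening_id")
            if sid in seen:
                raise DataFormatError(f"duplicate screening_id {sid!r}")
            seen.add(sid)
            ts, ok = parse_ts(_get(row, "submitted_ts"))
            if not ok:
                raise DataFormatError(f"screening {sid}: unparseable submitted_ts")
            out.append(
                ScreeningRecord(
                    screening_id=sid,
                    submitted_ts=ts,
                    passed=_get(row, "passed") in ("1", "true", "True"),
                    case_id=_get(row, "case_id"),
                )
            )
    return out


def write_screening(records: Iterable[ScreeningRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SCREENING_COLS)
        for rec in records:
            writer.writerow(
                [
                    rec.screening_id,
                    rec.submitted_ts.isoformat(),
                    "1" if rec.passed else "0",
                    rec.case_id or "",
                ]
            )


# ---------------------------------------------------------------------------
# mapping fixtures


def load_zip_map(
    zip3_path: str | Path | None, zones_path: str | Path | None
) -> ZipRegionMap:
    """Load zip3->state and state->zones tables; ``None`` paths give an empty
    map under which every geographic check reports unverifiable."""
    zip3: dict[str, str] = {}
    zones: dict[str, frozenset[str]] = {}
    if zip3_path is not None:
        with Path(zip3_path).open(newline="") as fh:
            for row in csv.DictReader(fh):
                zip3[row["zip3"].strip()] = row["state"].strip().upper()
    if zones_path is not None:
        tmp: dict[str, set[str]] = {}
        with Path(zones_path).open(newline="") as fh:
            for row in csv.DictReader(fh):
                zone = row["zone"].strip()
                ZoneInfo(zone)  # fail fast on unknown zone names
                tmp.setdefault(row["state"].strip().upper(), set()).add(zone)
        zones = {s: frozenset(z) for s, z in tmp.items()}
    return ZipRegionMap(zip3_to_state=zip3, state_to_zones=zones)


def _data_path(name: str):
    return resources.files("fraudscreen.data").joinpath(name)


def packaged_zip_map() -> ZipRegionMap:
    """The zip3/state/zone tables shipped with the package."""
    with resources.as_file(_data_path("zip3_state.csv")) as p1, resources.as_file(
        _data_path("state_zones.csv")
    ) as p2:
        return load_zip_map(p1, p2)


def load_name_list(path: str | Path) -> list[str]:
    """One name per line, UTF-8; blank lines ignored."""
    with Path(path).open(encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def packaged_facilities() -> list[str]:
    with resources.as_file(_data_path("facilities.txt")) as p:
        return load_name_list(p)


def packaged_channels() -> list[str]:
    with resources.as_file(_data_path("channels.txt")) as p:
        return load_name_list(p)
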