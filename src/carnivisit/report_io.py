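"""Reading, validating, deduplicating and summarizing carnivore reports.

The canonical on-disk dialects:

* CSV — UTF-8 with header
  ``record_id,species,timestamp,lon,lat,event_type,attractants,foraging_success,human_present,municipality_id``;
  attractants semicolon-joined; timestamps ISO-8601 with UTC offset.
* GeoJSON — a FeatureCollection of Point features with the same
  properties (minus lon/lat, which live in the geometry).

Deduplication collapses repeated observations of (presumably) the same
individual within 100 m and 6 h into a single *visit*, keeping the
earliest record as the visit's representative.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .geo import haversine_m
from .records import (ATTRACTANTS, EVENT_TYPES, ReportRecord, ValidationError)
from .solar import classify_daynight

CSV_COLUMNS = ["record_id", "species", "timestamp", "lon", "lat", "event_type",
               "attractants", "foraging_success", "human_present",
               "municipality_id"]


# ---------------------------------------------------------------------------
# reading / writing

def _parse_row(row: dict, rownum) -> ReportRecord:
    try:
        ts = dt.datetime.fromisoformat(str(row["timestamp"]))
    except ValueError as exc:
        raise ValidationError(
            f"row {rownum}: unparseable timestamp {row['timestamp']!r}: {exc}"
        ) from exc
    raw_attr = row.get("attractants") or ""
    if isinstance(raw_attr, str):
        attractants = frozenset(a for a in raw_attr.split(";") if a)
    else:
        attractants = frozenset(raw_attr)
    hp = row.get("human_present", False)
    if isinstance(hp, str):
        hp = hp.strip().lower() in ("true", "1", "yes")
    muni = row.get("municipality_id")
    if muni is None or (isinstance(muni, float) and np.isnan(muni)) or muni == "":
        muni = None
    else:
        muni = str(muni)
    rec = ReportRecord(
        record_id=str(row["record_id"]),
        species=str(row["species"]),
        timestamp=ts,
        lon=float(row["lon"]),
        lat=float(row["lat"]),
        event_type=str(row["event_type"]),
        attractants=attractants,
        foraging_success=str(row.get("foraging_success", "not_applicable")),
        human_present=bool(hp),
        municipality_id=muni,
    )
    try:
        return rec.validate()
    except ValidationError as exc:
        raise ValidationError(f"row {rownum}: {exc}") from exc


def read_reports(path, dialect: Optional[str] = None) -> List[ReportRecord]:
    """Read and validate report records from CSV or GeoJSON.

    ``dialect`` is ``"csv"`` or ``"geojson"``; when None it is inferred
    from the file extension.
    """
    path = Path(path)
    if dialect is None:
        dialect = "geojson" if path.suffix.lower() in (".geojson", ".json") else "csv"
    if dialect == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = set(CSV_COLUMNS[:9]) - set(df.columns)
        if missing:
            raise ValidationError(f"missing columns: {sorted(missing)}")
        return [_parse_row(row, i) for i, row in enumerate(df.to_dict("records"))]
    if dialect == "geojson":
        with open(path, encoding="utf-8") as fh:
            gj = json.load(fh)
        records = []
        for i, feat in enumerate(gj.get("features", [])):
            props = dict(feat.get("properties", {}))
            lon, lat = feat["geometry"]["coordinates"][:2]
            props["lon"], props["lat"] = lon, lat
            records.append(_parse_row(props, i))
        return records
    raise ValueError(f"unknown dialect {dialect!r}")


def records_to_frame(records: Sequence[ReportRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "record_id": r.record_id,
            "species": r.species,
            "timestamp": r.timestamp.isoformat(),
            "lon": r.lon,
            "lat": r.lat,
            "event_type": r.event_type,
            "attractants": ";".join(sorted(r.attractants)),
            "foraging_success": r.foraging_success,
            "human_present": r.human_present,
            "municipality_id": r.municipality_id if r.municipality_id else "",
        })
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_reports(records: Sequence[ReportRecord], path,
                  dialect: Optional[str] = None) -> None:
    path = Path(path)
    if dialect is None:
        dialect = "geojson" if path.suffix.lower() in (".geojson", ".json") else "csv"
    if dialect == "csv":
        records_to_frame(records).to_csv(path, index=False)
        return
    if dialect == "geojson":
        feats = []
        for r in records:
            feats.append({
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [r.lon, r.lat]},
                "properties": {
                    "record_id": r.record_id,
                    "species": r.species,
                    "timestamp": r.timestamp.isoformat(),
                    "event_type": r.event_type,
                    "attractants": ";".join(sorted(r.attractants)),
                    "foraging_success": r.foraging_success,
                    "human_present": r.human_present,
                    "municipality_id": r.municipality_id or "",
                },
            })
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)
        return
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# deduplication

def deduplicate(records: Iterable[ReportRecord], radius_m: float = 100.0,
                window_h: float = 6.0) -> List[ReportRecord]:
    """Collapse repeated observations into single visits.

    Exact duplicates (same species, location and timestamp) are removed
    first. Then, per species in chronological order, a record joins an
    open visit if it lies within ``radius_m`` (great-circle) of the
    visit's *first* record and within ``window_h`` hours of the visit's
    *most recent* record; otherwise it opens a new visit. The earliest
    record of each visit is returned. Idempotent.
    """
    if radius_m <= 0 or window_h <= 0:
        raise ValueError("radius_m and window_h must be positive")
    recs = sorted(records, key=lambda r: (r.timestamp, r.record_id))
    seen = set()
    unique: List[ReportRecord] = []
    for r in recs:
        key = (r.species, r.lon, r.lat, r.timestamp)
        if key in seen:
            continue
        seen.add(key)
        unique.append(r)

    window = dt.timedelta(hours=window_h)
    out: List[ReportRecord] = []
    # open visits per species: (first_record, latest_timestamp)
    open_visits: Dict[str, List[list]] = {}
    for r in unique:
        visits = open_visits.setdefault(r.species, [])
        joined = False
        for visit in visits:
            first, latest = visit
            if (r.timestamp - latest <= window
                    and haversine_m(r.lon, r.lat, first.lon, first.lat) <= radius_m):
                visit[1] = r.timestamp
                joined = True
                break
        if not joined:
            visits.append([r, r.timestamp])
            out.append(r)
    return sorted(out, key=lambda r: (r.timestamp, r.record_id))


# ---------------------------------------------------------------------------
# descriptive summary

@dataclass
class SpeciesSummary:
    n_reports: int
    dist_building_m: Dict[str, float] = field(default_factory=dict)
    dist_forest_m: Dict[str, float] = field(default_factory=dict)
    buildings_100m: Dict[str, float] = field(default_factory=dict)
    day_fraction: float = float("nan")
    human_absent_fraction: float = float("nan")
    success_fraction: float = float("nan")
    attractant_fractions: Dict[str, float] = field(default_factory=dict)
    event_type_fractions: Dict[str, float] = field(default_factory=dict)


@dataclass
class DescriptiveSummary:
    per_species: Dict[str, SpeciesSummary]

    def to_dict(self) -> dict:
        out = {}
        for sp, s in self.per_species.items():
            out[sp] = {
                "n_reports": s.n_reports,
                "dist_building_m": s.dist_building_m,
                "dist_forest_m": s.dist_forest_m,
                "buildings_100m": s.buildings_100m,
                "day_fraction": s.day_fraction,
                "human_absent_fraction": s.human_absent_fraction,
                "success_fraction": s.success_fraction,
                "attractant_fractions": s.attractant_fractions,
                "event_type_fractions": s.event_type_fractions,
            }
        return out


def _five_number(values: np.ndarray) -> Dict[str, float]:
    # linear-interpolation quantile convention
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3),
            "min": float(values.min()), "max": float(values.max())}


def summarize_reports(records: Sequence[ReportRecord], buildings=None,
                      forests=None) -> DescriptiveSummary:
    """Per-species descriptive statistics of a report stream.

    ``buildings`` is a sequence of building point geometries (or None to
    skip distance statistics); ``forests`` a sequence of forest polygons.
    ``success_fraction`` is computed over records with an attractant
    context (foraging_success != not_applicable).
    """
    from .landscape import count_within_radius, distance_to_nearest

    records = list(records)
    if not records:
        raise ValueError("cannot summarize an empty record list")
    per_species = {}
    for sp in sorted({r.species for r in records}):
        rs = [r for r in records if r.species == sp]
        s = SpeciesSummary(n_reports=len(rs))
        if buildings is not None and len(buildings) > 0:
            d = np.array([distance_to_nearest((r.lon, r.lat), buildings) for r in rs])
            s.dist_building_m = _five_number(d)
            c = np.array([count_within_radius((r.lon, r.lat), buildings, 100.0)
                          for r in rs], dtype=float)
            s.buildings_100m = _five_number(c)
        if forests is not None and len(forests) > 0:
            d = np.array([distance_to_nearest((r.lon, r.lat), forests) for r in rs])
            s.dist_forest_m = _five_number(d)
        day = [classify_daynight(r.timestamp, r.lon, r.lat) == "day" for r in rs]
        s.day_fraction = float(np.mean(day))
        s.human_absent_fraction = float(np.mean([not r.human_present for r in rs]))
        applicable = [r for r in rs if r.foraging_success != "not_applicable"]
        s.success_fraction = (
            float(np.mean([r.foraging_success == "success" for r in applicable]))
            if applicable else float("nan"))
        s.attractant_fractions = {
            a: float(np.mean([a in r.attractants for r in rs])) for a in ATTRACTANTS}
        s.event_type_fractions = {
            e: float(np.mean([r.event_type == e for r in rs])) for e in EVENT_TYPES}
        per_species[sp] = s
    return DescriptiveSummary(per_species=per_species)
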