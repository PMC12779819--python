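"""Record I/O, validation, deduplication and descriptive summaries."""

import datetime as dt
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Point, Polygon

from carnivisit import report_io
from carnivisit.records import ReportRecord, ValidationError

UTC = dt.timezone.utc


# ---------------------------------------------------------------------------
# reading / writing

CANONICAL_CSV = """record_id,species,timestamp,lon,lat,event_type,attractants,foraging_success,human_present,municipality_id
a1,bear,2023-07-04T21:30:00+02:00,22.301,49.502,foraging_anthropogenic,waste;dogs,success,False,m01
a2,wolf,2023-07-05T02:10:00+02:00,22.310,49.510,depredation_domestic,livestock,success,True,m01
a3,bear,2023-07-06T13:00:00+02:00,22.305,49.498,other,,not_applicable,False,
"""


def test_canonical_csv_roundtrip(tmp_path):
    p = tmp_path / "reports.csv"
    p.write_text(CANONICAL_CSV)
    records = report_io.read_reports(p)
    assert len(records) == 3
    assert records[0].attractants == frozenset({"waste", "dogs"})
    assert records[1].human_present is True
    assert records[2].municipality_id is None
    out = tmp_path / "again.csv"
    report_io.write_reports(records, out)
    assert report_io.read_reports(out) == records


@pytest.mark.parametrize("dialect,suffix", [("csv", ".csv"),
                                            ("geojson", ".geojson")])
def test_synthetic_stream_roundtrip(synthetic_stream, tmp_path, dialect, suffix):
    assert len(synthetic_stream) > 50
    p = tmp_path / f"stream{suffix}"
    report_io.write_reports(synthetic_stream, p, dialect=dialect)
    back = report_io.read_reports(p, dialect=dialect)
    assert back == list(synthetic_stream)


@pytest.mark.parametrize("field,value,token", [
    ("event_type", "flying", "flying"),
    ("species", "lynx", "lynx"),
    ("attractants", "pizza", "pizza"),
    ("foraging_success", "maybe", "maybe"),
    ("timestamp", "yesterday", "yesterday"),
])
def test_closed_vocabulary_errors_name_the_token(tmp_path, field, value, token):
    lines = CANONICAL_CSV.strip().split("\n")
    header = lines[0].split(",")
    row = lines[1].split(",")
    row[header.index(field)] = value
    p = tmp_path / "bad.csv"
    p.write_text(lines[0] + "\n" + ",".join(row) + "\n")
    with pytest.raises(ValidationError, match=token):
        report_io.read_reports(p)


def test_out_of_range_coordinates_rejected(make_record):
    with pytest.raises(ValidationError, match="lat"):
        make_record(lat=91.0)
    with pytest.raises(ValidationError, match="lon"):
        make_record(lon=-190.0)


def test_success_requires_attractant_context(make_record):
    with pytest.raises(ValidationError, match="not_applicable"):
        make_record(attractants=(), foraging_success="success")


# ---------------------------------------------------------------------------
# deduplication

def _shift(make_record, lat0, meters_north, minutes, **kw):
    # 1 deg latitude = 111194.93 m on the mean-radius sphere
    return make_record(lat=lat0 + meters_north / 111194.93,
                       ts=dt.datetime(2023, 8, 1, 10, 0, tzinfo=UTC)
                       + dt.timedelta(minutes=minutes), **kw)


def test_nearby_records_collapse_to_one_visit(make_record):
    a = _shift(make_record, 49.3, 0, 0)
    b = _shift(make_record, 49.3, 50, 120)
    out = report_io.deduplicate([a, b])
    assert out == [a]


def test_distant_records_stay_separate(make_record):
    a = _shift(make_record, 49.3, 0, 0)
    b = _shift(make_record, 49.3, 150, 1)
    assert len(report_io.deduplicate([a, b])) == 2


def test_chain_is_anchored_to_first_record(make_record):
    """A->B (80 m, 3 h) joins; C at 160 m from the anchor A starts a new
    visit even though it is within 80 m / 3 h of B."""
    a = _shift(make_record, 49.3, 0, 0)
    b = _shift(make_record, 49.3, 80, 180)
    c = _shift(make_record, 49.3, 160, 360)
    out = report_io.deduplicate([a, b, c])
    assert out == [a, c]


def test_exact_duplicates_removed_first(make_record):
    ts = dt.datetime(2023, 8, 1, 10, 0, tzinfo=UTC)
    a = make_record(ts=ts, record_id="x1")
    b = make_record(ts=ts, record_id="x2")  # same place, same time
    assert len(report_io.deduplicate([a, b])) == 1


def test_species_are_deduplicated_independently(make_record):
    a = _shift(make_record, 49.3, 0, 0, species="bear")
    b = _shift(make_record, 49.3, 10, 30, species="wolf")
    assert len(report_io.deduplicate([a, b])) == 2


def test_invalid_dedup_parameters(make_record):
    with pytest.raises(ValueError):
        report_io.deduplicate([make_record()], radius_m=0)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.lists(
    st.tuples(st.floats(0, 400), st.floats(0, 720), st.booleans()),
    min_size=0, max_size=25))
def test_dedup_idempotent_and_order_stable(offsets):
    """Deduplication applied twice equals once, and shuffling the input
    yields the same visit set (records re-sorted by time internally)."""
    t0 = dt.datetime(2023, 8, 1, tzinfo=UTC)
    records = []
    for i, (north_m, minutes, is_bear) in enumerate(offsets):
        records.append(ReportRecord(
            record_id=f"h{i}", species="bear" if is_bear else "wolf",
            timestamp=t0 + dt.timedelta(minutes=minutes),
            lon=22.0, lat=49.3 + north_m / 111194.93,
            event_type="other").validate())
    once = report_io.deduplicate(records)
    assert report_io.deduplicate(once) == once
    shuffled = records[:]
    random.Random(0).shuffle(shuffled)
    assert report_io.deduplicate(shuffled) == once
    assert len(once) <= len(records)


# ---------------------------------------------------------------------------
# descriptive summary

def test_singleton_summary_statistics(make_record):
    rec = make_record(lon=22.0, lat=49.3, ts="2023-08-01T12:00:00+02:00")
    building = Point(22.0, 49.3 + 10.0 / 111194.93)   # 10 m north
    s = report_io.summarize_reports([rec], buildings=[building])
    bear = s.per_species["bear"]
    assert bear.n_reports == 1
    assert bear.dist_building_m["median"] == pytest.approx(10.0, abs=0.05)
    assert bear.dist_building_m["q1"] == bear.dist_building_m["q3"]
    assert bear.human_absent_fraction == 1.0


def test_summary_fractions(synthetic_stream, small_landscape):
    s = report_io.summarize_reports(
        synthetic_stream, buildings=small_landscape.buildings,
        forests=[small_landscape.forest])
    bear = s.per_species["bear"]
    # the six event types are exclusive and exhaustive
    assert sum(bear.event_type_fractions.values()) == pytest.approx(1.0)
    assert 0.0 <= bear.day_fraction <= 1.0
    assert 0.0 <= bear.success_fraction <= 1.0
    for frac in bear.attractant_fractions.values():
        assert 0.0 <= frac <= 1.0
    assert bear.n_reports == len(synthetic_stream)


def test_empty_summary_rejected():
    with pytest.raises(ValueError, match="empty"):
        report_io.summarize_reports([])
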