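"""The synthetic landscape and food-conditioned report generator."""

import datetime as dt

import numpy as np
import pytest
from shapely.prepared import prep

from carnivisit import landscape as ls
from carnivisit import synthetic as syn
from conftest import lattice_cells

UTC = dt.timezone.utc


def homogeneous_config(baseline, gain=0.0, days=360, seed=0, **kw):
    params = syn.SpeciesParams(
        baseline_rate=baseline, attractant_effects={},
        conditioning_gain=gain, success_prob=kw.pop("success_prob", 0.6),
        detection_prob=kw.pop("detection_prob", 1.0),
        duplicate_report_rate=0.0)
    return syn.SimulationConfig(
        species_params={"bear": params},
        start_date=dt.date(2023, 7, 1),
        end_date=dt.date(2023, 7, 1) + dt.timedelta(days=days - 1),
        seed=seed)


def homogeneous_cells(n=100):
    # 10x10 aligned block; all attractants off
    side = int(np.sqrt(n))
    return lattice_cells(side, side, lon0=22.0, lat0=49.0)


def simulate_homogeneous(baseline, gain=0.0, days=360, seed=0, n_cells=100,
                         attractants=()):
    from shapely.geometry import box
    cells = homogeneous_cells(n_cells)
    boundary = box(22.0, 49.0, 22.0 + 0.01 * int(np.sqrt(n_cells)),
                   49.0 + 0.01 * int(np.sqrt(n_cells)))
    land = syn.Landscape(buildings=[], forest=syn.MultiPolygon([]),
                         boundary=boundary)
    cfg = homogeneous_config(baseline, gain=gain, days=days, seed=seed)
    sites = {c.cell_id: frozenset(attractants) for c in cells}
    return syn.simulate_reports(land, cfg, cells=cells, cell_attractants=sites)


# ---------------------------------------------------------------------------
# configuration invariants

def test_degenerate_extent_rejected():
    with pytest.raises(syn.InvalidConfigError):
        syn.LandscapeConfig(extent=(22.0, 49.0, 22.0, 49.1))


def test_forest_fraction_bounds():
    with pytest.raises(syn.InvalidConfigError):
        syn.LandscapeConfig(forest_fraction=1.2)


def test_probability_bounds():
    with pytest.raises(syn.InvalidConfigError):
        syn.SpeciesParams(detection_prob=1.5)


def test_date_order():
    with pytest.raises(syn.InvalidConfigError):
        syn.SimulationConfig(species_params={}, start_date=dt.date(2024, 1, 1),
                             end_date=dt.date(2023, 1, 1))


# ---------------------------------------------------------------------------
# landscape generation

def test_no_villages_no_buildings():
    land = syn.generate_landscape(syn.LandscapeConfig(n_villages=0, seed=1))
    assert land.buildings == []


def test_landscape_seed_determinism():
    cfg = syn.LandscapeConfig(seed=5)
    a = syn.generate_landscape(cfg)
    b = syn.generate_landscape(syn.LandscapeConfig(seed=5))
    assert [p.wkb for p in a.buildings] == [p.wkb for p in b.buildings]
    assert a.forest.wkb == b.forest.wkb
    c = syn.generate_landscape(syn.LandscapeConfig(seed=6))
    assert a.forest.wkb != c.forest.wkb


def test_realized_forest_fraction_tracks_target():
    """Over 20 seeds the realized forest area fraction stays within 0.1
    of the configured 0.5 on a ~10x10 km extent."""
    for seed in range(20):
        cfg = syn.LandscapeConfig(forest_fraction=0.5, seed=seed)
        land = syn.generate_landscape(cfg)
        frac = land.forest.area / land.boundary.area
        assert abs(frac - 0.5) < 0.1, seed


def test_buildings_inside_boundary(small_landscape):
    prepared = prep(small_landscape.boundary)
    assert all(prepared.contains(p) for p in small_landscape.buildings)


# ---------------------------------------------------------------------------
# report simulation

def test_zero_baseline_gives_no_reports():
    assert simulate_homogeneous(0.0, days=30) == []


def test_poisson_limit_of_unconditioned_process():
    """No attractants, no conditioning: total count is Poisson with mean
    cells * days * baseline = 100 * 360 * 0.001 = 36; a seeded draw must
    fall within 3 standard deviations."""
    recs = simulate_homogeneous(0.001, days=360, seed=42)
    assert abs(len(recs) - 36.0) <= 3 * np.sqrt(36.0)


def test_records_within_period_and_boundary(synthetic_stream, small_landscape):
    prepared = prep(small_landscape.boundary)
    lo = dt.datetime(2023, 7, 1, tzinfo=UTC)
    hi = dt.datetime(2023, 10, 1, tzinfo=UTC)
    for r in synthetic_stream:
        assert lo <= r.timestamp < hi
        assert prepared.contains(syn.Point(r.lon, r.lat))


def test_simulation_seed_determinism(small_landscape, small_cells):
    cfg = homogeneous_config(0.01, days=60, seed=9)
    a = syn.simulate_reports(small_landscape, cfg, cells=small_cells)
    b = syn.simulate_reports(small_landscape, cfg, cells=small_cells)
    assert a == b


def test_depredation_and_beehive_events_always_successful(synthetic_stream):
    for r in synthetic_stream:
        if r.event_type in ("depredation_domestic", "beehive_damage"):
            assert r.foraging_success == "success"


def test_conditioning_induces_overdispersion():
    """Self-excitation makes per-cell counts overdispersed: with a food
    attractant present (so feeding can succeed and condition the cell)
    the index of dispersion under conditioning_gain=1 exceeds the
    unconditioned one, which itself stays near the Poisson value 1."""
    import math

    def per_cell_counts(gain, seeds):
        counts = []
        cells = homogeneous_cells(25)
        for seed in seeds:
            recs = simulate_homogeneous(0.01, gain=gain, days=120, seed=seed,
                                        n_cells=25, attractants=("waste",))
            per = {}
            for r in recs:
                key = (math.floor(r.lon / 0.01), math.floor(r.lat / 0.01))
                per[key] = per.get(key, 0) + 1
            counts.extend(per.get((c.col_index, c.row_index), 0)
                          for c in cells)
        return np.array(counts, dtype=float)

    plain = per_cell_counts(0.0, range(100))
    conditioned = per_cell_counts(1.0, range(100, 150))
    iod_plain = plain.var(ddof=1) / plain.mean()
    iod_cond = conditioned.var(ddof=1) / conditioned.mean()
    assert iod_plain == pytest.approx(1.0, abs=0.1)
    assert iod_cond > iod_plain


def test_duplicate_reports_collapse_under_dedup(small_landscape, small_cells):
    from carnivisit import report_io
    params = syn.SpeciesParams(baseline_rate=0.02, attractant_effects={},
                               conditioning_gain=0.0,
                               duplicate_report_rate=0.5)
    cfg = syn.SimulationConfig(species_params={"bear": params},
                               start_date=dt.date(2023, 7, 1),
                               end_date=dt.date(2023, 8, 31), seed=2)
    recs = syn.simulate_reports(small_landscape, cfg, cells=small_cells)
    visits = report_io.deduplicate(recs)
    assert len(visits) < len(recs)
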