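import datetime as dt

import numpy as np
import pytest

from carnivisit import landscape as ls
from carnivisit import synthetic as syn
from carnivisit.records import ReportRecord

UTC = dt.timezone.utc


@pytest.fixture
def make_record():
    """Factory for valid records with minimal boilerplate."""
    counter = {"n": 0}

    def _make(lon=22.005, lat=49.305, ts="2023-08-01T10:00:00+00:00",
              species="bear", event_type="other", attractants=(),
              foraging_success=None, **kw):
        counter["n"] += 1
        attractants = frozenset(attractants)
        if foraging_success is None:
            foraging_success = "failure" if attractants else "not_applicable"
        return ReportRecord(
            record_id=kw.pop("record_id", f"r{counter['n']:04d}"),
            species=species,
            timestamp=dt.datetime.fromisoformat(ts) if isinstance(ts, str) else ts,
            lon=lon, lat=lat, event_type=event_type,
            attractants=attractants, foraging_success=foraging_success,
            **kw).validate()

    return _make


@pytest.fixture(scope="session")
def small_landscape():
    cfg = syn.LandscapeConfig(extent=(22.0, 49.3, 22.06, 49.34),
                              n_villages=3, buildings_per_village_mean=40,
                              forest_fraction=0.4, seed=7)
    return syn.generate_landscape(cfg)


@pytest.fixture(scope="session")
def small_cells(small_landscape):
    cells = ls.build_grid([small_landscape.boundary])
    return ls.add_cell_covariates(cells, small_landscape.buildings,
                                  [small_landscape.forest])


@pytest.fixture(scope="session")
def synthetic_stream(small_landscape, small_cells):
    """A deterministic three-month single-species report stream, dense
    enough (baseline raised above the 12-month default) for the round
    trip / aggregation / window tests to see a few hundred records."""
    import dataclasses
    base = syn.default_simulation_config(0)
    bear = dataclasses.replace(base.species_params["bear"],
                               baseline_rate=0.02)
    cfg = syn.SimulationConfig(
        species_params={"bear": bear},
        start_date=dt.date(2023, 7, 1), end_date=dt.date(2023, 9, 30),
        seed=11)
    return syn.simulate_reports(small_landscape, cfg, cells=small_cells)


def lattice_cells(n_cols, n_rows, lon0=22.0, lat0=49.0, size=0.01,
                  skip=()):
    """Plain rectangular lattice of GridCells for weight/window tests."""
    cells = []
    i0 = round(lon0 / size)
    j0 = round(lat0 / size)
    for j in range(n_rows):
        for i in range(n_cols):
            if (i, j) in skip:
                continue
            cells.append(ls.GridCell(
                cell_id=f"c{i0 + i}_{j0 + j}", row_index=j0 + j,
                col_index=i0 + i,
                bounds=((i0 + i) * size, (j0 + j) * size,
                        (i0 + i + 1) * size, (j0 + j + 1) * size),
                fraction_in_study_area=1.0,
                centroid_lon=(i0 + i + 0.5) * size,
                centroid_lat=(j0 + j + 0.5) * size))
    return cells
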