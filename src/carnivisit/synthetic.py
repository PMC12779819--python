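"""Synthetic landscapes and food-conditioned carnivore report streams.

Emulates a rural mountain municipality: buildings clustered in a handful
of valley villages, forest covering roughly half the area, and a
12-month, two-species (brown bear / grey wolf) stream of verified
reports from built-up areas. Visits follow a daily discrete-time
self-exciting process per grid cell::

    E[visits(cell, day)] = baseline_rate
                           * exp(sum of attractant effects present in cell)
                           * exp(conditioning_gain * S(cell, day))

where S counts *successful feeding events* in the cell during the
preceding ``memory_days`` days — the food-conditioning feedback. With
``conditioning_gain = 0`` and no attractants the per-cell counts are
exactly Poisson, which anchors the generator analytically.

All generator parameters are free choices of this package (the source
study reports no generative model); they are documented in the methods
note and must not be read as estimates from any field data.
"""

from __future__ import annotations

import datetime as dt
import math
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from shapely.geometry import MultiPolygon, Point, box
from shapely.ops import unary_union
from shapely.prepared import prep

from .landscape import GridCell, add_cell_covariates, build_grid
from .records import ATTRACTANTS, ReportRecord
from .solar import sun_events_utc


class InvalidConfigError(ValueError):
    pass


@dataclass
class LandscapeConfig:
    extent: Tuple[float, float, float, float] = (22.0, 49.3, 22.14, 49.39)
    n_villages: int = 6
    buildings_per_village_mean: float = 60.0
    forest_fraction: float = 0.56
    boundary: Optional[object] = None  # shapely polygon; default: extent box
    seed: int = 0
    village_sd_deg: float = 0.004      # scatter of buildings round a village
    forest_patch_radius_deg: float = 0.012

    def __post_init__(self):
        lon0, lat0, lon1, lat1 = self.extent
        if lon1 <= lon0 or lat1 <= lat0:
            raise InvalidConfigError("extent must have positive width and height")
        if not 0.0 <= self.forest_fraction <= 1.0:
            raise InvalidConfigError("forest_fraction must be in [0, 1]")
        if self.n_villages < 0:
            raise InvalidConfigError("n_villages must be >= 0")


@dataclass
class Landscape:
    buildings: List[Point]
    forest: MultiPolygon
    boundary: object                   # shapely Polygon/MultiPolygon


def generate_landscape(cfg: LandscapeConfig) -> Landscape:
    """Draw a valley-village landscape with a target forest fraction.

    Buildings are Gaussian-scattered around village centres; forest is a
    union of random circular patches grown until the realized area
    fraction reaches ``forest_fraction`` of the boundary.
    """
    rng = np.random.default_rng(cfg.seed)
    lon0, lat0, lon1, lat1 = cfg.extent
    boundary = cfg.boundary if cfg.boundary is not None else box(*cfg.extent)
    prepared = prep(boundary)

    # villages in the inner 80% of the extent so clusters stay inside
    mx, my = 0.1 * (lon1 - lon0), 0.1 * (lat1 - lat0)
    buildings: List[Point] = []
    for _ in range(cfg.n_villages):
        c_lon = rng.uniform(lon0 + mx, lon1 - mx)
        c_lat = rng.uniform(lat0 + my, lat1 - my)
        n_b = rng.poisson(cfg.buildings_per_village_mean)
        placed = 0
        while placed < n_b:
            p = Point(rng.normal(c_lon, cfg.village_sd_deg),
                      rng.normal(c_lat, cfg.village_sd_deg))
            if prepared.contains(p):
                buildings.append(p)
                placed += 1

    patches = []
    total = boundary.area
    target = cfg.forest_fraction * total
    forest = MultiPolygon([])
    area = 0.0
    for _ in range(2000):
        if area >= target:
            break
        c = Point(rng.uniform(lon0, lon1), rng.uniform(lat0, lat1))
        patches.append(c.buffer(cfg.forest_patch_radius_deg, quad_segs=8))
        merged = unary_union(patches).intersection(boundary)
        area = merged.area
        forest = merged if isinstance(merged, MultiPolygon) else MultiPolygon([merged])
    return Landscape(buildings=buildings, forest=forest, boundary=boundary)


@dataclass
class SpeciesParams:
    baseline_rate: float = 0.003       # expected visits per cell per day
    attractant_effects: Dict[str, float] = field(default_factory=dict)
    conditioning_gain: float = 0.8     # log-rate bump per recent feeding success
    memory_days: int = 30
    # conditioning saturates: at most this many recent successes count,
    # which keeps the self-exciting process subcritical
    max_conditioning_events: int = 3
    success_prob: float = 0.55
    detection_prob: float = 0.8
    day_fraction: float = 0.5
    human_present_prob: float = 0.15
    # a visit may be reported by more than one person: expected number of
    # extra near-duplicate reports per detected visit
    duplicate_report_rate: float = 0.0

    def __post_init__(self):
        if self.baseline_rate < 0:
            raise InvalidConfigError("baseline_rate must be >= 0")
        for name, v in (("success_prob", self.success_prob),
                        ("detection_prob", self.detection_prob),
                        ("day_fraction", self.day_fraction),
                        ("human_present_prob", self.human_present_prob)):
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0, 1]")
        if self.duplicate_report_rate < 0:
            raise InvalidConfigError("duplicate_report_rate must be >= 0")
        unknown = set(self.attractant_effects) - set(ATTRACTANTS)
        if unknown:
            raise InvalidConfigError(f"unknown attractants {sorted(unknown)}")


@dataclass
class SimulationConfig:
    species_params: Dict[str, SpeciesParams]
    start_date: dt.date = dt.date(2023, 7, 1)
    end_date: dt.date = dt.date(2024, 6, 30)
    seed: int = 0

    def __post_init__(self):
        if self.start_date >= self.end_date:
            raise InvalidConfigError("start_date must precede end_date")


def default_simulation_config(seed: int = 0) -> SimulationConfig:
    """Two-species defaults for a 12-month rural-Carpathian-like stream."""
    bear = SpeciesParams(
        baseline_rate=0.003,
        attractant_effects={"waste": 1.0, "fruit_trees_shrubs": 0.6,
                            "beehives": 0.8, "livestock": 0.4,
                            "wild_ungulates": 0.3},
        conditioning_gain=0.8, success_prob=0.55, detection_prob=0.8,
        day_fraction=0.69, duplicate_report_rate=0.03)
    wolf = SpeciesParams(
        baseline_rate=0.003,
        attractant_effects={"dogs": 1.0, "livestock": 0.8,
                            "wild_ungulates": 0.5, "waste": 0.3},
        conditioning_gain=0.8, success_prob=0.50, detection_prob=0.8,
        day_fraction=0.52, duplicate_report_rate=0.03)
    return SimulationConfig(species_params={"bear": bear, "wolf": wolf},
                            seed=seed)


#: per-attractant presence probability in (built-up, unbuilt) cells
DEFAULT_ATTRACTANT_PROBS: Dict[str, Tuple[float, float]] = {
    "waste": (0.50, 0.05),
    "dogs": (0.45, 0.05),
    "livestock": (0.30, 0.05),
    "beehives": (0.12, 0.02),
    "fruit_trees_shrubs": (0.35, 0.20),
    "wild_ungulates": (0.25, 0.40),
}


def assign_cell_attractants(cells: Sequence[GridCell], seed: int,
                            probs: Optional[Dict[str, Tuple[float, float]]] = None
                            ) -> Dict[str, frozenset]:
    """Static per-cell attractant sets (site properties, drawn once)."""
    probs = DEFAULT_ATTRACTANT_PROBS if probs is None else probs
    rng = np.random.default_rng(seed)
    out = {}
    for c in cells:
        built = c.building_count > 0
        present = {a for a, (pb, pu) in sorted(probs.items())
                   if rng.uniform() < (pb if built else pu)}
        out[c.cell_id] = frozenset(present)
    return out


def _draw_event(rng, attractants: frozenset, success_prob: float):
    """Event type and foraging outcome given the cell's attractant set."""
    if not attractants:
        return "other", "not_applicable"
    u = rng.uniform()
    if u < 0.20:
        return "other", "failure"
    if u < 0.25:
        return "property_damage", "failure"
    a = sorted(attractants)[rng.integers(len(attractants))]
    success = rng.uniform() < success_prob
    if a in ("livestock", "dogs"):
        return ("depredation_domestic", "success") if success else ("other", "failure")
    if a == "beehives":
        return ("beehive_damage", "success") if success else ("other", "failure")
    if a == "waste":
        return "foraging_anthropogenic", "success" if success else "failure"
    return "foraging_natural", "success" if success else "failure"


_FEEDING_EVENTS = {"depredation_domestic", "beehive_damage",
                   "foraging_anthropogenic", "foraging_natural"}


def _draw_timestamp(rng, date: dt.date, lon: float, lat: float,
                    day_fraction: float) -> dt.datetime:
    events = sun_events_utc(date, lon, lat)
    day0 = dt.datetime(date.year, date.month, date.day, tzinfo=dt.timezone.utc)
    if events is None:
        return day0 + dt.timedelta(hours=float(rng.uniform(0, 24)))
    sunrise, sunset = events
    if rng.uniform() < day_fraction:
        span = (sunset - sunrise).total_seconds()
        return sunrise + dt.timedelta(seconds=float(rng.uniform(0, span)))
    before = (sunrise - day0).total_seconds()
    after = (day0 + dt.timedelta(days=1) - sunset).total_seconds()
    u = rng.uniform(0, before + after)
    if u < before:
        return day0 + dt.timedelta(seconds=float(u))
    return sunset + dt.timedelta(seconds=float(u - before))


def _sample_point_in_cell(rng, cell: GridCell, prepared) -> Tuple[float, float]:
    lon0, lat0, lon1, lat1 = cell.bounds
    for _ in range(200):
        lon = float(rng.uniform(lon0, lon1))
        lat = float(rng.uniform(lat0, lat1))
        if prepared.contains(Point(lon, lat)):
            return lon, lat
    return cell.centroid_lon, cell.centroid_lat


def simulate_reports(landscape: Landscape, cfg: SimulationConfig,
                     cells: Optional[Sequence[GridCell]] = None,
                     attractant_probs: Optional[dict] = None,
                     cell_attractants: Optional[Dict[str, frozenset]] = None,
                     min_fraction: float = 0.75) -> List[ReportRecord]:
    """Simulate the report stream over a landscape.

    The intensity process runs on *all* visits; each realized visit is
    then emitted as a record with probability ``detection_prob`` (the
    animal's conditioning does not depend on whether anyone reported it).
    """
    if cells is None:
        cells = build_grid([landscape.boundary], min_fraction=min_fraction)
        cells = add_cell_covariates(cells, landscape.buildings,
                                    [landscape.forest] if not landscape.forest.is_empty else None)
    cells = list(cells)
    prepared = prep(landscape.boundary)
    if cell_attractants is None:
        cell_attractants = assign_cell_attractants(
            cells, seed=cfg.seed + 101, probs=attractant_probs)

    n_days = (cfg.end_date - cfg.start_date).days + 1
    n_cells = len(cells)
    records: List[ReportRecord] = []
    counter = 0
    for sp in sorted(cfg.species_params):
        params = cfg.species_params[sp]
        # stable per-species substream (crc32: process-independent)
        rng = np.random.default_rng((cfg.seed, zlib.crc32(sp.encode())))
        static_log_rate = np.full(n_cells, -np.inf)
        if params.baseline_rate > 0:
            static_log_rate = np.log(params.baseline_rate) + np.array([
                sum(params.attractant_effects.get(a, 0.0)
                    for a in cell_attractants[c.cell_id]) for c in cells])
        success_by_day = np.zeros((n_cells, n_days), dtype=np.int32)
        for d in range(n_days):
            date = cfg.start_date + dt.timedelta(days=d)
            lo = max(0, d - params.memory_days)
            recent = success_by_day[:, lo:d].sum(axis=1) if d > lo else np.zeros(n_cells)
            recent = np.minimum(recent, params.max_conditioning_events)
            rate = np.exp(static_log_rate + params.conditioning_gain * recent)
            n_visits = rng.poisson(rate)
            for ci in np.flatnonzero(n_visits):
                cell = cells[ci]
                for _ in range(int(n_visits[ci])):
                    event, outcome = _draw_event(
                        rng, cell_attractants[cell.cell_id], params.success_prob)
                    if event in _FEEDING_EVENTS and outcome == "success":
                        success_by_day[ci, d] += 1
                    if rng.uniform() >= params.detection_prob:
                        continue
                    lon, lat = _sample_point_in_cell(rng, cell, prepared)
                    ts = _draw_timestamp(rng, date, lon, lat, params.day_fraction)
                    counter += 1
                    base = ReportRecord(
                        record_id=f"{sp[0]}{counter:06d}",
                        species=sp, timestamp=ts, lon=lon, lat=lat,
                        event_type=event,
                        attractants=cell_attractants[cell.cell_id],
                        foraging_success=outcome,
                        human_present=bool(rng.uniform() < params.human_present_prob),
                    ).validate()
                    records.append(base)
                    # independent witnesses of the same visit: small
                    # spatial jitter, reported within a couple of hours
                    for _ in range(int(rng.poisson(params.duplicate_report_rate))):
                        counter += 1
                        jlon = min(max(lon + float(rng.normal(0, 2e-4)),
                                       cell.bounds[0]), cell.bounds[2])
                        jlat = min(max(lat + float(rng.normal(0, 2e-4)),
                                       cell.bounds[1]), cell.bounds[3])
                        if not prepared.contains(Point(jlon, jlat)):
                            jlon, jlat = lon, lat
                        dts = ts + dt.timedelta(
                            minutes=float(rng.uniform(1, 120)))
                        records.append(ReportRecord(
                            record_id=f"{sp[0]}{counter:06d}",
                            species=sp, timestamp=dts,
                            lon=jlon, lat=jlat,
                            event_type=event,
                            attractants=cell_attractants[cell.cell_id],
                            foraging_success=outcome,
                            human_present=bool(
                                rng.uniform() < params.human_present_prob),
                        ).validate())
    return sorted(records, key=lambda r: (r.timestamp, r.record_id))
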