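"""Grid construction, landscape covariates and report-to-cell assignment.

The study area is tiled with 0.01-degree cells (~1 km at mid-latitudes)
anchored on the global lattice of integer multiples of the cell size, so
the grid is reproducible regardless of the data extent. Cells with less
than 75% of their area inside the study-area boundary are excluded to
avoid edge bias from unsampled margins.

Distances are great-circle metres; areas are computed in a local
equirectangular projection centred on the geometry (see :mod:`.geo`).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Point, Polygon, box, shape
from shapely.ops import unary_union
from shapely.prepared import prep

from .geo import LocalProjection, geometry_area_km2, haversine_m
from .records import ReportRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridCell:
    cell_id: str
    row_index: int          # latitude index on the global lattice
    col_index: int          # longitude index on the global lattice
    bounds: Tuple[float, float, float, float]  # lon_min, lat_min, lon_max, lat_max
    fraction_in_study_area: float
    centroid_lon: float
    centroid_lat: float
    building_count: int = 0
    forest_area_km2: float = 0.0


def _as_polygon(boundary) -> MultiPolygon:
    if isinstance(boundary, (Polygon, MultiPolygon)):
        geom = boundary
    else:
        geom = unary_union(list(boundary))
    if geom.is_empty:
        return geom
    if isinstance(geom, Polygon):
        geom = MultiPolygon([geom])
    return geom


def build_grid(boundary_polygons, cell_size_deg: float = 0.01,
               min_fraction: float = 0.75) -> List[GridCell]:
    """Tile the boundary's bounding box with lattice-aligned cells.

    ``fraction_in_study_area`` is the fraction of each cell's area inside
    the boundary (degree-space polygon intersection; over a ~1 km cell the
    metric distortion is constant and cancels in the ratio). Cells below
    ``min_fraction`` are dropped.
    """
    geom = _as_polygon(boundary_polygons)
    if geom.is_empty:
        return []
    prepared = prep(geom)
    lon_min, lat_min, lon_max, lat_max = geom.bounds
    i0 = math.floor(lon_min / cell_size_deg)
    i1 = math.ceil(lon_max / cell_size_deg)
    j0 = math.floor(lat_min / cell_size_deg)
    j1 = math.ceil(lat_max / cell_size_deg)
    cells: List[GridCell] = []
    for j in range(j0, j1):
        for i in range(i0, i1):
            b = box(i * cell_size_deg, j * cell_size_deg,
                    (i + 1) * cell_size_deg, (j + 1) * cell_size_deg)
            if not prepared.intersects(b):
                continue
            if prepared.contains_properly(b):
                frac = 1.0
            else:
                frac = b.intersection(geom).area / b.area
            if frac + 1e-12 < min_fraction:
                continue
            cells.append(GridCell(
                cell_id=f"c{i}_{j}",
                row_index=j, col_index=i,
                bounds=b.bounds,
                fraction_in_study_area=min(frac, 1.0),
                centroid_lon=(i + 0.5) * cell_size_deg,
                centroid_lat=(j + 0.5) * cell_size_deg,
            ))
    return cells


def add_cell_covariates(cells: Sequence[GridCell], buildings=None,
                        forests=None) -> List[GridCell]:
    """Return cells with building counts and forest area (km^2) filled in."""
    b_lon = np.array([p.x for p in buildings]) if buildings else np.empty(0)
    b_lat = np.array([p.y for p in buildings]) if buildings else np.empty(0)
    forest = _as_polygon(forests) if forests is not None else None
    forest_prep = prep(forest) if forest is not None and not forest.is_empty else None
    out = []
    for c in cells:
        lon0, lat0, lon1, lat1 = c.bounds
        n_b = int(np.sum((b_lon >= lon0) & (b_lon < lon1)
                         & (b_lat >= lat0) & (b_lat < lat1))) if b_lon.size else 0
        area = 0.0
        if forest_prep is not None:
            cell_box = box(*c.bounds)
            if forest_prep.intersects(cell_box):
                area = geometry_area_km2(cell_box.intersection(forest))
        out.append(GridCell(
            cell_id=c.cell_id, row_index=c.row_index, col_index=c.col_index,
            bounds=c.bounds, fraction_in_study_area=c.fraction_in_study_area,
            centroid_lon=c.centroid_lon, centroid_lat=c.centroid_lat,
            building_count=n_b, forest_area_km2=area))
    return out


def distance_to_nearest(point: Tuple[float, float], geometries) -> float:
    """Minimum great-circle distance (m) from a lon/lat point to any geometry.

    Zero if the point lies on or inside a geometry (interior convention:
    a report inside a forest polygon is at distance 0 from the forest).
    """
    geoms = list(geometries)
    if not geoms:
        raise ValueError("empty geometry set")
    lon, lat = point
    p = Point(lon, lat)
    proj = LocalProjection(lon, lat)
    pp = proj.project_geometry(p)
    best = math.inf
    for g in geoms:
        if g.covers(p):
            return 0.0
        if isinstance(g, Point):
            # great-circle for point targets: exact and symmetric
            best = min(best, float(haversine_m(lon, lat, g.x, g.y)))
        else:
            best = min(best, proj.project_geometry(g).distance(pp))
    return best


def count_within_radius(point: Tuple[float, float], points,
                        radius_m: float = 100.0) -> int:
    """Number of points within ``radius_m`` (boundary inclusive)."""
    if radius_m <= 0:
        raise ValueError("radius_m must be positive")
    pts = list(points)
    if not pts:
        return 0
    lon, lat = point
    lons = np.array([p.x for p in pts])
    lats = np.array([p.y for p in pts])
    d = haversine_m(lon, lat, lons, lats)
    return int(np.sum(d <= radius_m + 1e-9))


def cell_index(cells: Sequence[GridCell],
               cell_size_deg: float = 0.01) -> Dict[Tuple[int, int], GridCell]:
    return {(c.col_index, c.row_index): c for c in cells}


def locate_cell(lon: float, lat: float, index: Dict[Tuple[int, int], GridCell],
                cell_size_deg: float = 0.01) -> Optional[GridCell]:
    key = (math.floor(lon / cell_size_deg), math.floor(lat / cell_size_deg))
    return index.get(key)


#: event types that raise the per-cell binary covariates of the count GLM
FLAG_EVENTS = {
    "flag_anthropogenic_feeding": lambda r: r.event_type == "foraging_anthropogenic",
    "flag_depredation_domestic": lambda r: r.event_type == "depredation_domestic",
    "flag_beehive_damage": lambda r: r.event_type == "beehive_damage",
    # no dedicated event category exists for killing wild ungulates; it is
    # a natural-food foraging event with wild ungulates among the attractants
    "flag_wild_ungulate_kill": lambda r: (r.event_type == "foraging_natural"
                                          and "wild_ungulates" in r.attractants),
}


def aggregate_cells(records: Sequence[ReportRecord], cells: Sequence[GridCell],
                    cell_size_deg: float = 0.01) -> pd.DataFrame:
    """One row per (occupied cell, species) with counts and event flags.

    Reports outside all retained cells are counted in the returned frame's
    ``attrs["n_outside"]`` (per species) and logged, never silently
    dropped.
    """
    index = cell_index(cells, cell_size_deg)
    per: Dict[Tuple[str, str], dict] = {}
    n_outside: Dict[str, int] = {}
    for r in records:
        cell = locate_cell(r.lon, r.lat, index, cell_size_deg)
        if cell is None:
            n_outside[r.species] = n_outside.get(r.species, 0) + 1
            continue
        key = (cell.cell_id, r.species)
        row = per.setdefault(key, {
            "cell_id": cell.cell_id, "species": r.species, "n_reports": 0,
            "forest_area_km2": cell.forest_area_km2,
            "building_count": cell.building_count,
            "centroid_lon": cell.centroid_lon, "centroid_lat": cell.centroid_lat,
            **{f: 0 for f in FLAG_EVENTS}})
        row["n_reports"] += 1
        for flag, pred in FLAG_EVENTS.items():
            if pred(r):
                row[flag] = 1
    if n_outside:
        log.warning("reports outside retained grid: %s", n_outside)
    cols = ["cell_id", "species", "n_reports", "forest_area_km2",
            "building_count", *FLAG_EVENTS, "centroid_lon", "centroid_lat"]
    df = pd.DataFrame(sorted(per.values(), key=lambda d: (d["species"], d["cell_id"])),
                      columns=cols)
    df.attrs["n_outside"] = n_outside
    return df


# ---------------------------------------------------------------------------
# GeoJSON layer I/O

def read_layer(path) -> List:
    """Read geometries from a GeoJSON file (any geometry type)."""
    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        return [shape(f["geometry"]) for f in gj["features"]]
    if gj.get("type") == "Feature":
        return [shape(gj["geometry"])]
    return [shape(gj)]


def write_layer(geometries, path, properties: Optional[List[dict]] = None) -> None:
    feats = []
    for i, g in enumerate(geometries):
        props = properties[i] if properties else {}
        feats.append({"type": "Feature", "geometry": g.__geo_interface__,
                      "properties": props})
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": feats}),
        encoding="utf-8")


def grid_to_geojson(cells: Sequence[GridCell], path) -> None:
    geoms = [box(*c.bounds) for c in cells]
    props = [{"cell_id": c.cell_id, "row_index": c.row_index,
              "col_index": c.col_index,
              "fraction_in_study_area": c.fraction_in_study_area,
              "building_count": c.building_count,
              "forest_area_km2": c.forest_area_km2} for c in cells]
    write_layer(geoms, path, props)
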