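"""Climate-stability (refuge) mapping and range-change diagnostics.

A refuge is a cell where a category's distribution is predicted present
under both current climate and the cross-GCM future consensus. Range change
is summarized by two descriptors: area (km^2, spherical cell areas) and the
area-weighted latitudinal/longitudinal centroid, whose displacement is
reported as great-circle distance plus initial bearing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point, shape
from shapely.prepared import prep

from .grid_io import EARTH_RADIUS_KM

__all__ = [
    "Extirpated",
    "stability_map",
    "range_area",
    "centroid",
    "displacement",
    "refuges_by_region",
    "RefugeReport",
]

logger = logging.getLogger(__name__)


class Extirpated:
    """Sentinel for an empty range: no centroid or displacement exists."""

    def __repr__(self) -> str:  # pragma: no cover
        return "Extirpated"

    def __eq__(self, other) -> bool:
        return isinstance(other, Extirpated)

    def __hash__(self) -> int:
        return hash("Extirpated")


EXTIRPATED = Extirpated()


def stability_map(current_binary: np.ndarray, future_binary: np.ndarray) -> np.ndarray:
    """Cells where the category persists: current AND future presence."""
    if current_binary.shape != future_binary.shape:
        raise ValueError(
            f"grid mismatch: {current_binary.shape} vs {future_binary.shape}"
        )
    return np.asarray(current_binary, bool) & np.asarray(future_binary, bool)


def range_area(binary: np.ndarray, cell_areas: np.ndarray) -> tuple[float, float]:
    """(km^2 of the range, % of the modelled domain area)."""
    if binary.shape != cell_areas.shape:
        raise ValueError("binary map and cell areas have different shapes")
    total = float(cell_areas.sum())
    area = float(cell_areas[np.asarray(binary, bool)].sum())
    return area, 100.0 * area / total


def centroid(
    binary: np.ndarray, lat: np.ndarray, lon: np.ndarray, cell_areas: np.ndarray
):
    """Area-weighted mean (lat, lon) of present cells; Extirpated if empty.

    Latitude and longitude are averaged separately (the domain is assumed
    far from the antimeridian).
    """
    mask = np.asarray(binary, bool)
    if not mask.any():
        return EXTIRPATED
    w = cell_areas[mask]
    return (
        float(np.average(lat[mask], weights=w)),
        float(np.average(lon[mask], weights=w)),
    )


def displacement(centroid_current, centroid_future):
    """Great-circle distance (km) and initial bearing (deg) between centroids.

    Haversine on a sphere of radius 6371 km; bearing is measured clockwise
    from north at the current centroid. Returns Extirpated if either
    endpoint is.
    """
    if isinstance(centroid_current, Extirpated) or isinstance(centroid_future, Extirpated):
        return EXTIRPATED
    lat1, lon1 = np.radians(centroid_current)
    lat2, lon2 = np.radians(centroid_future)
    dlat, dlon = lat2 - lat1, lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    dist = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    bearing = float(np.degrees(np.arctan2(y, x)) % 360.0)
    return float(dist), bearing


def load_regions(path: str | Path) -> dict[str, dict]:
    """Region polygons from GeoJSON: feature property 'name' -> geometry."""
    payload = json.loads(Path(path).read_text())
    out = {}
    for feat in payload["features"]:
        name = feat["properties"].get("name", f"region_{len(out)}")
        out[name] = feat["geometry"]
    return out


def refuges_by_region(
    refuge_binaries: dict[str, np.ndarray],
    regions: dict[str, dict],
    lat: np.ndarray,
    lon: np.ndarray,
    cell_areas: np.ndarray,
) -> pd.DataFrame:
    """Refuge area per region polygon and category.

    A cell belongs to the region whose polygon contains its center
    (boundary-inclusive); overlapping polygons are rejected, gaps are
    allowed and logged. Returns rows (region, category, area_km2,
    pct_of_region).
    """
    geoms = {name: shape(g) for name, g in regions.items()}
    prepared = {name: prep(g.buffer(1e-9)) for name, g in geoms.items()}
    points = [Point(x, y) for x, y in zip(lon.ravel(), lat.ravel())]
    membership = np.full(len(points), None, dtype=object)
    for name in sorted(geoms):
        hits = np.array([prepared[name].contains(pt) for pt in points])
        clash = hits & (membership != None)  # noqa: E711
        if clash.any():
            other = membership[clash][0]
            raise ValueError(
                f"overlapping region polygons: {name!r} and {other!r} both "
                f"contain {int(clash.sum())} cell centers"
            )
        membership[hits] = name
    uncovered = int((membership == None).sum())  # noqa: E711
    if uncovered:
        logger.info("%d cell centers fall in no region polygon", uncovered)

    membership = membership.reshape(lat.shape)
    areas = cell_areas
    rows = []
    for region in sorted(geoms):
        in_region = membership == region
        region_area = float(areas[in_region].sum())
        for cat, refuge in sorted(refuge_binaries.items()):
            if refuge.shape != lat.shape:
                raise ValueError(f"refuge map for {cat!r} is on a different grid")
            a = float(areas[in_region & refuge.astype(bool)].sum())
            rows.append(
                {
                    "region": region,
                    "category": cat,
                    "area_km2": a,
                    "pct_of_region": 100.0 * a / region_area if region_area else np.nan,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class RefugeReport:
    """Stability diagnostics for every category under one RCP."""

    rcp_id: str
    refuge_maps: dict[str, np.ndarray]
    table: pd.DataFrame  # per category: areas, % of domain, centroids, displacement
    by_region: pd.DataFrame | None = None

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def build_report(
    rcp_id: str,
    current: dict[str, np.ndarray],
    future_consensus: dict[str, np.ndarray],
    lat: np.ndarray,
    lon: np.ndarray,
    cell_areas: np.ndarray,
    regions: dict[str, dict] | None = None,
) -> RefugeReport:
    """Assemble refuge maps, areas, centroids and displacements per category."""
    refuge_maps: dict[str, np.ndarray] = {}
    rows = []
    for cat in sorted(current):
        if cat not in future_consensus:
            raise ValueError(f"category {cat!r} missing from the future consensus")
        refuge = stability_map(current[cat], future_consensus[cat])
        refuge_maps[cat] = refuge
        cur_area, cur_pct = range_area(current[cat], cell_areas)
        fut_area, fut_pct = range_area(future_consensus[cat], cell_areas)
        ref_area, ref_pct = range_area(refuge, cell_areas)
        c_cur = centroid(current[cat], lat, lon, cell_areas)
        c_fut = centroid(future_consensus[cat], lat, lon, cell_areas)
        disp = displacement(c_cur, c_fut)
        extirpated = isinstance(c_fut, Extirpated)
        rows.append(
            {
                "category": cat,
                "rcp": rcp_id,
                "current_area_km2": cur_area,
                "current_pct": cur_pct,
                "future_area_km2": fut_area,
                "future_pct": fut_pct,
                "refuge_area_km2": ref_area,
                "refuge_pct": ref_pct,
                "extirpated": extirpated,
                "centroid_current_lat": None if isinstance(c_cur, Extirpated) else c_cur[0],
                "centroid_current_lon": None if isinstance(c_cur, Extirpated) else c_cur[1],
                "centroid_future_lat": None if extirpated else c_fut[0],
                "centroid_future_lon": None if extirpated else c_fut[1],
                "displacement_km": None if isinstance(disp, Extirpated) else disp[0],
                "bearing_deg": None if isinstance(disp, Extirpated) else disp[1],
            }
        )
    table = pd.DataFrame(rows)
    by_region = None
    if regions is not None:
        by_region = refuges_by_region(refuge_maps, regions, lat, lon, cell_areas)
    return RefugeReport(
        rcp_id=rcp_id, refuge_maps=refuge_maps, table=table, by_region=by_region
    )
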