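"""Raster and cell-table I/O, landcover upscaling, cell geometry.

Rasters use the ESRI ASCII grid format (plain text, north-up, cell-registered,
WGS84 by package convention); cell tables are CSV with one row per grid cell.
Categorical rasters travel as integer codes resolved against a
:class:`CategoryRegistry` (YAML on disk).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._grid import ConfigurationError, DomainSpec

__all__ = [
    "EARTH_RADIUS_KM",
    "CategoryRegistry",
    "cell_area_km2",
    "upscale_majority",
    "drop_anthropogenic_categories",
    "write_raster",
    "read_raster",
    "write_cells",
    "read_cells",
]

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


def cell_area_km2(lat_center, cell_size: float):
    """Area of a lat/lon cell from the spherical band formula.

    A = R^2 * dlambda * (sin(phi_top) - sin(phi_bottom)) with R = 6371 km.
    Accepts scalar or array latitudes; area decreases with \\|lat\\|.
    """
    lat = np.asarray(lat_center, dtype=float)
    half = cell_size / 2.0
    if np.any(np.abs(lat) + half > 90.0 + 1e-12):
        raise ValueError("cell extends beyond the poles")
    top = np.radians(lat + half)
    bottom = np.radians(lat - half)
    dlon = np.radians(cell_size)
    area = EARTH_RADIUS_KM**2 * dlon * (np.sin(top) - np.sin(bottom))
    return float(area) if np.isscalar(lat_center) else area


@dataclass(frozen=True)
class CategoryRegistry:
    """Landcover label registry: label -> (integer ordinal, native flag).

    Ordinals are the deterministic tie-break order for the majority vote and
    the integer codes used in categorical rasters.
    """

    entries: tuple[tuple[str, int, bool], ...]  # (label, ordinal, native)

    def __post_init__(self) -> None:
        labels = [e[0] for e in self.entries]
        ordinals = [e[1] for e in self.entries]
        if len(set(labels)) != len(labels) or len(set(ordinals)) != len(ordinals):
            raise ConfigurationError("registry labels and ordinals must be unique")

    @classmethod
    def from_labels(
        cls, native: tuple[str, ...] | list[str], anthropogenic: tuple[str, ...] | list[str] = ()
    ) -> "CategoryRegistry":
        entries = [(lab, i + 1, True) for i, lab in enumerate(native)]
        entries += [(lab, len(native) + i + 1, False) for i, lab in enumerate(anthropogenic)]
        return cls(tuple(entries))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(e[0] for e in self.entries)

    @property
    def native_labels(self) -> tuple[str, ...]:
        return tuple(e[0] for e in self.entries if e[2])

    def ordinal(self, label: str) -> int:
        for lab, ordn, _ in self.entries:
            if lab == label:
                return ordn
        raise KeyError(f"unknown landcover label {label!r}")

    def label_of(self, ordinal: int) -> str:
        for lab, ordn, _ in self.entries:
            if ordn == ordinal:
                return lab
        raise KeyError(f"unknown landcover ordinal {ordinal}")

    def is_native(self, label: str) -> bool:
        for lab, _, native in self.entries:
            if lab == label:
                return native
        raise KeyError(f"unknown landcover label {label!r}")

    def to_yaml(self, path: str | Path) -> None:
        payload = [
            {"label": lab, "id": ordn, "native": bool(nat)} for lab, ordn, nat in self.entries
        ]
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CategoryRegistry":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(tuple((d["label"], int(d["id"]), bool(d["native"])) for d in payload))


def default_registry() -> CategoryRegistry:
    from .synthetic_world import ANTHROPOGENIC_CATEGORIES, NATIVE_CATEGORIES

    return CategoryRegistry.from_labels(NATIVE_CATEGORIES, ANTHROPOGENIC_CATEGORIES)


def upscale_majority(
    fine_landcover: np.ndarray,
    fine_domain: DomainSpec,
    grid: DomainSpec,
    registry: CategoryRegistry,
) -> pd.DataFrame:
    """Upscale a fine categorical map to the analysis grid by native majority.

    Each coarse cell gets the most abundant NATIVE category among its fine
    pixels; anthropogenic pixels are excluded from the vote but counted in
    ``anthro_fraction``. Ties break toward the smaller registry ordinal.
    Cells with no native pixel at all are dropped (logged).
    """
    if fine_landcover.shape != fine_domain.shape:
        raise ConfigurationError("fine map shape does not match its domain")
    for attr in ("lat_min", "lat_max", "lon_min", "lon_max"):
        if getattr(fine_domain, attr) != getattr(grid, attr):
            raise ConfigurationError(
                f"fine and coarse domains disagree on {attr}: "
                f"{getattr(fine_domain, attr)} vs {getattr(grid, attr)}"
            )
    ratio = grid.cell_size / fine_domain.cell_size
    k = round(ratio)
    if abs(ratio - k) > 1e-9 or k < 1:
        raise ConfigurationError(
            f"fine resolution {fine_domain.cell_size} does not divide "
            f"coarse cell size {grid.cell_size}"
        )

    # order labels by ordinal so np.argmax's first-max tie rule implements
    # the smaller-ordinal tie-break
    by_ordinal = sorted(registry.entries, key=lambda e: e[1])
    labels = [e[0] for e in by_ordinal]
    native_mask = np.array([e[2] for e in by_ordinal])
    code = {lab: i for i, lab in enumerate(labels)}
    unknown = set(np.unique(fine_landcover)) - set(labels)
    if unknown:
        raise ConfigurationError(f"fine map contains labels not in registry: {sorted(unknown)}")

    coded = np.vectorize(code.__getitem__, otypes=[int])(fine_landcover)
    nr, nc = grid.shape
    blocks = coded.reshape(nr, k, nc, k).transpose(0, 2, 1, 3).reshape(nr, nc, k * k)
    counts = np.stack(
        [(blocks == i).sum(axis=2) for i in range(len(labels))], axis=2
    )  # (nr, nc, n_labels)
    native_counts = counts[:, :, native_mask]
    native_labels = [lab for lab, m in zip(labels, native_mask) if m]
    n_native = native_counts.sum(axis=2)
    winner = np.argmax(native_counts, axis=2)

    lat, lon = grid.center_grids()
    anthro = counts[:, :, ~native_mask].sum(axis=2) / (k * k)
    table = pd.DataFrame(
        {
            "cell_id": grid.cell_ids().ravel(),
            "lat": lat.ravel(),
            "lon": lon.ravel(),
            "landcover": np.array(native_labels, dtype=object)[winner].ravel(),
            "anthro_fraction": anthro.ravel(),
            "n_native_pixels": n_native.ravel(),
        }
    )
    empty = table["n_native_pixels"] == 0
    if empty.any():
        logger.info("dropping %d cells with no native fine pixels", int(empty.sum()))
        table = table[~empty].reset_index(drop=True)
    table["area_km2"] = cell_area_km2(table["lat"].to_numpy(), grid.cell_size)
    return table


def drop_anthropogenic_categories(
    cell_table: pd.DataFrame, registry: CategoryRegistry
) -> pd.DataFrame:
    """Remove cells whose landcover label is anthropogenic.

    ``anthro_fraction`` (if present) is retained on the surviving rows for
    the sensitivity analysis. An all-anthropogenic input yields an empty
    table with an explicit warning.
    """
    unknown = set(cell_table["landcover"].unique()) - set(registry.labels)
    if unknown:
        raise ConfigurationError(f"cell table contains unknown labels: {sorted(unknown)}")
    keep = cell_table["landcover"].map(registry.is_native)
    out = cell_table[keep].reset_index(drop=True)
    if out.empty:
        warnings.warn("all cells are anthropogenic; result is empty", stacklevel=2)
    return out


_NODATA = -9999.0


def write_raster(path: str | Path, array: np.ndarray, domain: DomainSpec) -> None:
    """Write a single-band raster as an ESRI ASCII grid (north-up, WGS84)."""
    if array.shape != domain.shape:
        raise ConfigurationError(
            f"array shape {array.shape} does not match domain grid {domain.shape}"
        )
    header = (
        f"ncols {domain.n_cols}\n"
        f"nrows {domain.n_rows}\n"
        f"xllcorner {domain.lon_min!r}\n"
        f"yllcorner {domain.lat_min!r}\n"
        f"cellsize {domain.cell_size!r}\n"
        f"NODATA_value {_NODATA!r}\n"
    )
    data = np.where(np.isfinite(array.astype(float)), array, _NODATA)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt="%.10g")


def read_raster(
    path: str | Path, allow_nodata: bool = False
) -> tuple[np.ndarray, DomainSpec]:
    """Read an ESRI ASCII grid back into (array, DomainSpec).

    Missing-data cells are rejected unless ``allow_nodata``; rejected reads
    list the offending (row, col) positions.
    """
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        array = np.loadtxt(fh, ndmin=2)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if array.shape != (nrows, ncols):
        raise ConfigurationError(
            f"raster data shape {array.shape} contradicts header ({nrows}, {ncols})"
        )
    cs = header["cellsize"]
    domain = DomainSpec(
        lat_min=header["yllcorner"],
        lat_max=header["yllcorner"] + nrows * cs,
        lon_min=header["xllcorner"],
        lon_max=header["xllcorner"] + ncols * cs,
        cell_size=cs,
    )
    nodata = header.get("nodata_value", _NODATA)
    missing = array == nodata
    if missing.any():
        if not allow_nodata:
            cells = [(int(r), int(c)) for r, c in np.argwhere(missing)[:20]]
            raise ValueError(f"raster has missing data inside the domain at cells {cells}")
        array = np.where(missing, np.nan, array)
    return array, domain


def write_cells(path: str | Path, cell_table: pd.DataFrame) -> None:
    """Write a cell table to CSV (lossless float round-trip)."""
    cell_table.to_csv(path, index=False, float_format="%.17g")


def read_cells(path: str | Path) -> pd.DataFrame:
    """Read a cell table from CSV, canonically ordered by cell_id."""
    table = pd.read_csv(path)
    if "cell_id" not in table.columns:
        raise ConfigurationError("cell table lacks a cell_id column")
    if table["cell_id"].duplicated().any():
        dupes = table.loc[table["cell_id"].duplicated(), "cell_id"].tolist()[:10]
        raise ConfigurationError(f"duplicate cell_ids: {dupes}")
    return table.sort_values("cell_id").reset_index(drop=True)
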