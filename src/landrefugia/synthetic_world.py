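"""Synthetic gridded world with known climate-landcover coupling.

Emulates the ingredients of a continental landcover/climate analysis on a
desk-scale 0.5-degree grid: 19 bioclimatic variables built from smooth
latitudinal (temperature-like) or longitudinal (precipitation-like) gradients
plus Gaussian noise, a landcover map generated from explicit
variable-threshold rules, an anthropogenic-cover fraction field, and additive
per-GCM/RCP climate shifts. Because the generating rules are known, every
downstream stage (tree partition, distribution models, refuge maps) can be
scored against exact ground truth.

Temperature-like variables are in degrees Celsius, precipitation-like in mm;
units are recorded per variable in :data:`VARIABLE_INFO`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._grid import ConfigurationError, DomainSpec

__all__ = [
    "BIOCLIM_VARIABLES",
    "VARIABLE_INFO",
    "DomainSpec",
    "ScenarioSpec",
    "ClimateStack",
    "Rule",
    "RuleSet",
    "ConfigurationError",
    "generate_climate",
    "generate_landcover",
    "generate_fine_landcover",
    "anthropogenic_fraction_field",
    "apply_anthropogenic",
    "true_future_distribution",
    "default_domain",
    "default_rules",
    "default_scenarios",
    "default_noise_sd",
    "NATIVE_CATEGORIES",
    "ANTHROPOGENIC_CATEGORIES",
]

BIOCLIM_VARIABLES: tuple[str, ...] = tuple(f"bio{i}" for i in range(1, 20))

# (axis, intercept, slope, unit): value = intercept + slope * lat (axis "lat")
# or intercept + slope * lon (axis "lon").  bio1-bio11 are temperature-like
# and follow the latitudinal gradient; bio12-bio19 are precipitation-like and
# follow the longitudinal gradient (wet west, dry east).
VARIABLE_INFO: dict[str, tuple[str, float, float, str]] = {
    "bio1": ("lat", 28.0, 0.60, "degC"),
    "bio2": ("lat", 12.0, 0.10, "degC"),
    "bio3": ("lat", 80.0, 0.50, "percent"),
    "bio4": ("lat", 300.0, -20.0, "degC*100 sd"),
    "bio5": ("lat", 33.0, 0.55, "degC"),
    "bio6": ("lat", 21.0, 0.70, "degC"),
    "bio7": ("lat", 12.0, -0.15, "degC"),
    "bio8": ("lat", 27.0, 0.58, "degC"),
    "bio9": ("lat", 26.0, 0.62, "degC"),
    "bio10": ("lat", 29.0, 0.52, "degC"),
    "bio11": ("lat", 25.0, 0.66, "degC"),
    "bio12": ("lon", -4000.0, -100.0, "mm"),
    "bio13": ("lon", -500.0, -14.0, "mm"),
    "bio14": ("lon", -180.0, -4.0, "mm"),
    "bio15": ("lon", -100.0, -2.5, "percent"),
    "bio16": ("lon", -1300.0, -36.0, "mm"),
    "bio17": ("lon", -560.0, -13.0, "mm"),
    "bio18": ("lon", -900.0, -25.0, "mm"),
    "bio19": ("lon", -700.0, -18.0, "mm"),
}

TEMPERATURE_VARS = tuple(v for v in BIOCLIM_VARIABLES if VARIABLE_INFO[v][0] == "lat")
PRECIPITATION_VARS = tuple(v for v in BIOCLIM_VARIABLES if VARIABLE_INFO[v][0] == "lon")

NATIVE_CATEGORIES: tuple[str, ...] = (
    "closed_vegetation",
    "open_vegetation",
    "closed_deciduous_forest",
    "mosaic",
    "sparse_vegetation",
)
ANTHROPOGENIC_CATEGORIES: tuple[str, ...] = ("agriculture", "urban")


@dataclass(frozen=True)
class ScenarioSpec:
    """One (GCM, RCP) climate scenario as additive per-variable offsets.

    ``shifts`` maps variable name -> constant additive offset applied on top
    of the baseline gradient. The baseline scenario has all-zero shifts.
    """

    gcm_id: str
    rcp_id: str  # "baseline", "rcp45" or "rcp85"
    horizon_year: int = 2080
    shifts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rcp_id == "baseline" and any(v != 0.0 for v in self.shifts.values()):
            raise ConfigurationError("baseline scenario must have zero shifts")
        unknown = set(self.shifts) - set(BIOCLIM_VARIABLES)
        if unknown:
            raise ConfigurationError(f"unknown variables in shifts: {sorted(unknown)}")

    def shift_for(self, variable: str) -> float:
        return self.shifts.get(variable, 0.0)


@dataclass
class ClimateStack:
    """19 co-registered climate layers on one grid for one scenario.

    ``data`` has shape ``(n_variables, n_rows, n_cols)`` in the order of
    ``variables``; rows run north to south.
    """

    domain: DomainSpec
    scenario: ScenarioSpec
    variables: tuple[str, ...]
    data: np.ndarray
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.shape != (len(self.variables), *self.domain.shape):
            raise ConfigurationError(
                f"data shape {self.data.shape} does not match "
                f"{len(self.variables)} variables on grid {self.domain.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ConfigurationError("climate stack contains non-finite values")

    def layer(self, variable: str) -> np.ndarray:
        try:
            i = self.variables.index(variable)
        except ValueError:
            raise KeyError(f"variable {variable!r} not in stack") from None
        return self.data[i]

    def to_frame(self) -> pd.DataFrame:
        """Cells as rows (row-major, cell_id index), variables as columns."""
        n = self.domain.n_cells
        frame = pd.DataFrame(
            self.data.reshape(len(self.variables), n).T, columns=list(self.variables)
        )
        frame.index.name = "cell_id"
        return frame


def gradient_field(variable: str, domain: DomainSpec) -> np.ndarray:
    """Closed-form deterministic part of a variable at cell centers."""
    axis, intercept, slope, _ = VARIABLE_INFO[variable]
    lat, lon = domain.center_grids()
    coord = lat if axis == "lat" else lon
    return intercept + slope * coord


def default_noise_sd() -> dict[str, float]:
    """Default per-variable noise standard deviations.

    Roughly half an inter-cell gradient step on a 0.5-degree grid: spatial
    structure dominates but samples are jittered in climate space.
    """
    out = {}
    for v in BIOCLIM_VARIABLES:
        _, _, slope, _ = VARIABLE_INFO[v]
        out[v] = abs(slope) * 0.25
    return out


def generate_climate(
    domain: DomainSpec,
    scenario: ScenarioSpec,
    noise_sd: dict[str, float] | float | None = None,
    seed: int = 0,
    smooth_sigma: float = 0.0,
) -> ClimateStack:
    """Build a climate stack: gradient + scenario shift + Gaussian noise.

    The noise field depends only on ``(domain, noise_sd, seed)`` — never on
    the scenario — so differencing two scenarios generated with the same seed
    recovers the configured shift exactly. ``smooth_sigma > 0`` applies a
    Gaussian filter (in cell units) to the noise field, introducing spatial
    autocorrelation while preserving the marginal standard deviation.
    """
    if domain.n_rows <= 0 or domain.n_cols <= 0:
        raise ConfigurationError("domain has non-positive grid dimensions")
    if noise_sd is None:
        noise_sd = default_noise_sd()
    if np.isscalar(noise_sd):
        noise_sd = {v: float(noise_sd) for v in BIOCLIM_VARIABLES}
    bad = [v for v, s in noise_sd.items() if s < 0]
    if bad:
        raise ConfigurationError(f"negative noise_sd for {bad}")

    rng = np.random.default_rng(seed)
    shape = (len(BIOCLIM_VARIABLES), *domain.shape)
    noise = rng.standard_normal(shape)
    if smooth_sigma > 0:
        from scipy.ndimage import gaussian_filter

        for i in range(noise.shape[0]):
            sm = gaussian_filter(noise[i], sigma=smooth_sigma, mode="nearest")
            sd = sm.std()
            noise[i] = sm / sd if sd > 0 else sm

    data = np.empty(shape)
    for i, v in enumerate(BIOCLIM_VARIABLES):
        data[i] = (
            gradient_field(v, domain)
            + scenario.shift_for(v)
            + noise_sd.get(v, 0.0) * noise[i]
        )
    return ClimateStack(
        domain=domain,
        scenario=scenario,
        variables=BIOCLIM_VARIABLES,
        data=data,
        units={v: VARIABLE_INFO[v][3] for v in BIOCLIM_VARIABLES},
    )


_OPS = {
    ">": np.greater,
    ">=": np.greater_equal,
    "<": np.less,
    "<=": np.less_equal,
}


@dataclass(frozen=True)
class Rule:
    """One landcover rule: a conjunction of variable-threshold conditions.

    ``conditions`` is a sequence of ``(variable, op, threshold)`` with op in
    {">", ">=", "<", "<="}. An empty conjunction always matches.
    """

    category: str
    conditions: tuple[tuple[str, str, float], ...]

    def __post_init__(self) -> None:
        for var, op, _ in self.conditions:
            if op not in _OPS:
                raise ConfigurationError(f"unknown operator {op!r} in rule for {self.category}")
            if var not in BIOCLIM_VARIABLES:
                raise ConfigurationError(f"unknown variable {var!r} in rule for {self.category}")

    def mask(self, stack: ClimateStack) -> np.ndarray:
        out = np.ones(stack.domain.shape, dtype=bool)
        for var, op, thr in self.conditions:
            out &= _OPS[op](stack.layer(var), thr)
        return out


@dataclass(frozen=True)
class RuleSet:
    """Ordered first-match-wins rules plus a default category.

    The default makes the rule set exhaustive over climate space; with
    ``default_category=None`` exhaustiveness of the explicit rules is required
    and any uncovered cell raises :class:`ConfigurationError`.
    """

    rules: tuple[Rule, ...]
    default_category: str | None = None

    def categories(self) -> tuple[str, ...]:
        cats = [r.category for r in self.rules]
        if self.default_category is not None and self.default_category not in cats:
            cats.append(self.default_category)
        # preserve first-appearance order, deduplicated
        seen: dict[str, None] = {}
        for c in cats:
            seen.setdefault(c)
        return tuple(seen)

    def classify(self, stack: ClimateStack) -> np.ndarray:
        """Per-cell category labels (object array of str), first match wins."""
        labels = np.full(stack.domain.shape, None, dtype=object)
        unassigned = np.ones(stack.domain.shape, dtype=bool)
        for rule in self.rules:
            hit = rule.mask(stack) & unassigned
            labels[hit] = rule.category
            unassigned &= ~hit
        if unassigned.any():
            if self.default_category is None:
                r, c = np.argwhere(unassigned)[0]
                raise ConfigurationError(
                    f"rule set is not exhaustive: cell (row={r}, col={c}) matches no rule"
                )
            labels[unassigned] = self.default_category
        return labels


def generate_landcover(climate: ClimateStack, rules: RuleSet) -> np.ndarray:
    """Apply the rule set to a climate stack, yielding a category map."""
    return rules.classify(climate)


def generate_fine_landcover(
    domain: DomainSpec,
    scenario: ScenarioSpec,
    rules: RuleSet,
    k: int,
    noise_sd: dict[str, float] | float | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, DomainSpec]:
    """Category map at ``k``-fold finer resolution (rules at subcell centers)."""
    fine = domain.refine(k)
    stack = generate_climate(fine, scenario, noise_sd=noise_sd, seed=seed)
    return rules.classify(stack), fine


def anthropogenic_fraction_field(
    domain: DomainSpec,
    hotspots: list[dict] | None,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell anthropogenic-cover fraction from disc-shaped hotspots.

    Each hotspot is ``{"lat": .., "lon": .., "radius_deg": .., "intensity": ..,
    "noise_sd": ..}``; inside the disc the fraction equals ``intensity`` plus
    optional Gaussian jitter, hotspots combine by maximum, result clipped to
    [0, 1]. No hotspots -> all-zero field.
    """
    frac = np.zeros(domain.shape)
    if not hotspots:
        return frac
    rng = np.random.default_rng(seed)
    lat, lon = domain.center_grids()
    for spot in hotspots:
        d2 = (lat - spot["lat"]) ** 2 + (lon - spot["lon"]) ** 2
        inside = d2 <= spot["radius_deg"] ** 2
        level = np.where(inside, float(spot["intensity"]), 0.0)
        sd = float(spot.get("noise_sd", 0.0))
        if sd > 0:
            level = np.where(inside, level + sd * rng.standard_normal(domain.shape), 0.0)
        frac = np.maximum(frac, level)
    return np.clip(frac, 0.0, 1.0)


def apply_anthropogenic(
    landcover: np.ndarray,
    climate: ClimateStack,
    hotspots: list[dict] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Assemble the per-cell table: coordinates, climate, native label, fraction.

    The native landcover label is preserved unchanged next to the
    anthropogenic fraction, so the >50 %-anthropogenic sensitivity analysis
    can filter cells without losing labels.
    """
    from .grid_io import cell_area_km2

    domain = climate.domain
    if landcover.shape != domain.shape:
        raise ConfigurationError("landcover map does not match the climate grid")
    lat, lon = domain.center_grids()
    frac = anthropogenic_fraction_field(domain, hotspots, seed=seed)
    table = pd.DataFrame(
        {
            "cell_id": domain.cell_ids().ravel(),
            "lat": lat.ravel(),
            "lon": lon.ravel(),
        }
    )
    climate_frame = climate.to_frame().reset_index(drop=True)
    table = pd.concat([table, climate_frame], axis=1)
    table["landcover"] = landcover.ravel()
    table["anthro_fraction"] = frac.ravel()
    table["area_km2"] = cell_area_km2(lat.ravel(), domain.cell_size)
    return table


def true_future_distribution(
    rules: RuleSet,
    baseline: ClimateStack,
    future: ClimateStack,
) -> dict[str, dict[str, np.ndarray]]:
    """Ground-truth current/future/refuge binary maps per category.

    The refuge map of a category is the cellwise conjunction of its baseline
    and future presence under the same generating rules.
    """
    if baseline.domain != future.domain:
        raise ConfigurationError("baseline and future stacks are on different grids")
    cur = rules.classify(baseline)
    fut = rules.classify(future)
    out: dict[str, dict[str, np.ndarray]] = {}
    for cat in rules.categories():
        cur_b = cur == cat
        fut_b = fut == cat
        out[cat] = {"current": cur_b, "future": fut_b, "refuge": cur_b & fut_b}
    return out


def default_regions(domain: DomainSpec | None = None) -> dict[str, dict]:
    """Four quadrant 'countries' partitioning the domain (GeoJSON geometries)."""
    d = domain or default_domain()
    lat_mid = (d.lat_min + d.lat_max) / 2.0
    lon_mid = (d.lon_min + d.lon_max) / 2.0
    def box(lat0, lat1, lon0, lon1):
        return {
            "type": "Polygon",
            "coordinates": [
                [[lon0, lat0], [lon1, lat0], [lon1, lat1], [lon0, lat1], [lon0, lat0]]
            ],
        }
    return {
        "northwest": box(lat_mid, d.lat_max, d.lon_min, lon_mid),
        "northeast": box(lat_mid, d.lat_max, lon_mid, d.lon_max),
        "southwest": box(d.lat_min, lat_mid, d.lon_min, lon_mid),
        "southeast": box(d.lat_min, lat_mid, lon_mid, d.lon_max),
    }


def write_regions_geojson(path, regions: dict[str, dict]) -> None:
    import json

    payload = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {"name": name}, "geometry": geom}
            for name, geom in regions.items()
        ],
    }
    from pathlib import Path

    Path(path).write_text(json.dumps(payload))


def default_domain() -> DomainSpec:
    """40x40 cells of 0.5 degrees spanning 20S-0, 70W-50W."""
    return DomainSpec(lat_min=-20.0, lat_max=0.0, lon_min=-70.0, lon_max=-50.0)


def default_rules() -> RuleSet:
    """Five native categories from nested thresholds on bio1 and bio12.

    Warm/wet -> closed vegetation; warm/dry -> open vegetation; the cool half
    splits by moisture into mosaic (wet), closed deciduous forest
    (intermediate) and sparse vegetation (driest).
    """
    return RuleSet(
        rules=(
            Rule("closed_vegetation", (("bio1", ">=", 22.0), ("bio12", ">=", 2000.0))),
            Rule("open_vegetation", (("bio1", ">=", 22.0), ("bio12", "<", 2000.0))),
            Rule("mosaic", (("bio1", "<", 22.0), ("bio12", ">=", 2000.0))),
            Rule("closed_deciduous_forest", (("bio1", "<", 22.0), ("bio12", ">=", 1400.0))),
            Rule("sparse_vegetation", ()),
        ),
    )


# Per-pseudo-GCM warming (degC, applied to temperature-like variables) and
# drying (mm, subtracted from precipitation-like variables) under RCP 4.5;
# RCP 8.5 doubles both. The three GCMs disagree in magnitude, which is what
# drives the cross-GCM consensus step.
_GCM_PARAMS: dict[str, tuple[float, float]] = {
    "gcm_a": (1.2, 150.0),
    "gcm_b": (1.0, 180.0),
    "gcm_c": (1.4, 120.0),
}
_RCP_FACTORS = {"baseline": 0.0, "rcp45": 1.0, "rcp85": 2.0}


def _scenario_shifts(warming: float, drying: float) -> dict[str, float]:
    shifts: dict[str, float] = {}
    for v in TEMPERATURE_VARS:
        scale = abs(VARIABLE_INFO[v][2]) / abs(VARIABLE_INFO["bio1"][2])
        shifts[v] = warming * scale
    for v in PRECIPITATION_VARS:
        scale = abs(VARIABLE_INFO[v][2]) / abs(VARIABLE_INFO["bio12"][2])
        shifts[v] = -drying * scale
    return shifts


def default_scenarios() -> dict[str, dict[str, ScenarioSpec]]:
    """Scenario grid: ``{gcm_id: {rcp_id: ScenarioSpec}}`` for 3 pseudo-GCMs."""
    out: dict[str, dict[str, ScenarioSpec]] = {}
    for gcm, (warming, drying) in _GCM_PARAMS.items():
        out[gcm] = {}
        for rcp, factor in _RCP_FACTORS.items():
            shifts = (
                {} if factor == 0.0 else _scenario_shifts(warming * factor, drying * factor)
            )
            out[gcm][rcp] = ScenarioSpec(gcm_id=gcm, rcp_id=rcp, shifts=shifts)
    return out
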