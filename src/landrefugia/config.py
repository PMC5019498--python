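"""Run configuration: schema, defaults, YAML round-trip.

Every pipeline run resolves its configuration once, validates it up front
(unknown method ids or malformed blocks fail before any compute), and
writes the resolved copy next to the outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from ._grid import ConfigurationError
from .sdm_methods import FAMILIES, METHODS

__all__ = ["RunConfig", "load_config"]


@dataclass
class SyntheticBlock:
    lat_min: float = -20.0
    lat_max: float = 0.0
    lon_min: float = -70.0
    lon_max: float = -50.0
    cell_size: float = 0.5
    noise_sd: float | None = None  # None -> per-variable defaults
    smooth_sigma: float = 0.0
    hotspots: list = field(
        default_factory=lambda: [
            {"lat": -4.0, "lon": -56.0, "radius_deg": 2.5, "intensity": 0.75},
            {"lat": -15.0, "lon": -63.0, "radius_deg": 2.0, "intensity": 0.6},
        ]
    )


@dataclass
class PartitionBlock:
    min_node_size: int = 20
    cv_reps: int = 200
    cv_folds: int = 10
    use_1se: bool = True
    rf_trees: int = 500


@dataclass
class ModelingBlock:
    methods: list = field(default_factory=lambda: list(METHODS))
    sample_frac: float = 0.25
    calib_frac: float = 0.75
    n_replicates: int = 10
    cutoff: float = 0.7
    hyperparams: dict = field(default_factory=dict)


@dataclass
class ProjectionBlock:
    family: str = "statistical"
    consensus: str = "unanimity"
    rcps: list = field(default_factory=lambda: ["rcp45", "rcp85"])


@dataclass
class RefugiaBlock:
    regions: str = "synthetic"  # path to GeoJSON, or the built-in quadrants


@dataclass
class RunConfig:
    synthetic: SyntheticBlock = field(default_factory=SyntheticBlock)
    partition: PartitionBlock = field(default_factory=PartitionBlock)
    modeling: ModelingBlock = field(default_factory=ModelingBlock)
    projection: ProjectionBlock = field(default_factory=ProjectionBlock)
    refugia: RefugiaBlock = field(default_factory=RefugiaBlock)
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.modeling.methods) - set(METHODS)
        if unknown:
            raise ConfigurationError(
                f"unknown method ids {sorted(unknown)}; valid: {METHODS}"
            )
        if self.projection.family not in FAMILIES:
            raise ConfigurationError(
                f"unknown ensemble family {self.projection.family!r}; "
                f"valid: {sorted(FAMILIES)}"
            )
        if self.projection.consensus not in ("unanimity", "majority"):
            raise ConfigurationError(
                f"unknown consensus rule {self.projection.consensus!r}"
            )
        for rcp in self.projection.rcps:
            if rcp not in ("rcp45", "rcp85"):
                raise ConfigurationError(f"unknown RCP {rcp!r}")
        missing = set(FAMILIES[self.projection.family]) - set(self.modeling.methods)
        if missing:
            raise ConfigurationError(
                f"projection family {self.projection.family!r} needs methods "
                f"{sorted(missing)} in modeling.methods"
            )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


_BLOCKS = {
    "synthetic": SyntheticBlock,
    "partition": PartitionBlock,
    "modeling": ModelingBlock,
    "projection": ProjectionBlock,
    "refugia": RefugiaBlock,
}


def load_config(source: str | Path | dict | None = None) -> RunConfig:
    """Build a RunConfig from a YAML file or dict; missing keys use defaults."""
    if source is None:
        return RunConfig()
    payload = (
        dict(source)
        if isinstance(source, dict)
        else (yaml.safe_load(Path(source).read_text()) or {})
    )
    unknown = set(payload) - set(_BLOCKS) - {"seed"}
    if unknown:
        raise ConfigurationError(f"unknown config blocks {sorted(unknown)}")
    kwargs = {}
    for name, cls in _BLOCKS.items():
        block = payload.get(name, {})
        bad = set(block) - set(cls.__dataclass_fields__)
        if bad:
            raise ConfigurationError(f"unknown keys in {name!r} block: {sorted(bad)}")
        kwargs[name] = cls(**block)
    return RunConfig(seed=int(payload.get("seed", 0)), **kwargs)
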