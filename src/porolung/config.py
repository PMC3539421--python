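"""Run configuration: YAML schema, validation, defaults and hashing.

A run is fully described by a RunConfig: phantom geometry, material fields,
inlet waveform, solver settings, landmarks, output directory and the master
seed.  Defaults encode the reference study conditions: Poisson ratio 0.4,
tissue density 700 kg/m^3, mean Young's modulus 178 Pa (range 10-500 Pa for
the heterogeneous field) and a 4 s breathing period.  Unknown keys are
rejected with their key path; physical-range violations report the offending
value.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .fsi import SolverConfig, Waveform
from .materials import (
    AIR_COMPRESSIBILITY,
    AIR_DENSITY,
    AIR_VISCOSITY,
    DEFAULT_PERMEABILITY_SCALE,
    DEFAULT_POISSON,
    DEFAULT_POROSITY,
    LUNG_TISSUE_DENSITY,
    ElasticityFieldSpec,
)
from .phantom import PhantomSpec

logger = logging.getLogger("porolung")

__all__ = ["MaterialConfig", "RunConfig", "ConfigError", "load_config",
           "dump_config", "config_hash", "setup_logging"]


class ConfigError(ValueError):
    """Invalid configuration file: unknown key, bad type or physical range."""


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


@dataclass(frozen=True)
class MaterialConfig:
    """Elasticity field spec plus fluid constants and the permeability profile."""

    elasticity: ElasticityFieldSpec = field(default_factory=ElasticityFieldSpec)
    poisson: float = DEFAULT_POISSON
    porosity: float = DEFAULT_POROSITY
    tissue_density: float = LUNG_TISSUE_DENSITY
    branch_radii: tuple[float, ...] | None = None   # default: halving from 2 mm
    permeability_scale: float = DEFAULT_PERMEABILITY_SCALE
    air_density: float = AIR_DENSITY
    air_viscosity: float = AIR_VISCOSITY
    air_compressibility: float = AIR_COMPRESSIBILITY

    def __post_init__(self) -> None:
        if not 0.0 < self.poisson < 0.5:
            raise ConfigError(
                f"Poisson ratio must lie in (0, 0.5), got {self.poisson}"
            )
        if not 0.0 < self.porosity < 1.0:
            raise ConfigError(f"porosity must lie in (0, 1), got {self.porosity}")
        if self.tissue_density <= 0:
            raise ConfigError(f"tissue density must be > 0, got {self.tissue_density}")
        if self.permeability_scale <= 0:
            raise ConfigError(
                f"permeability_scale must be > 0, got {self.permeability_scale}"
            )


@dataclass
class RunConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    material: MaterialConfig = field(default_factory=MaterialConfig)
    waveform: Waveform = field(default_factory=Waveform)
    solver: SolverConfig = field(default_factory=SolverConfig)
    landmarks: str | list[dict] = "auto"
    output_dir: str = "porolung_out"
    seed: int = 0
    log_level: str = "INFO"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RunConfig):
            return NotImplemented
        return asdict_config(self) == asdict_config(other)


def asdict_config(cfg: RunConfig) -> dict:
    d = {
        "phantom": asdict(cfg.phantom),
        "material": asdict(cfg.material),
        "waveform": asdict(cfg.waveform),
        "solver": asdict(cfg.solver),
        "landmarks": cfg.landmarks,
        "output_dir": cfg.output_dir,
        "seed": cfg.seed,
        "log_level": cfg.log_level,
    }
    return _listify(d)


def _listify(obj):
    """Tuples -> lists so YAML round-trips structurally."""
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    return obj


def _build(cls, data: dict, path: str, tuple_fields=(), optional_tuple_fields=()):
    known = set(cls.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} under '{path}'")
    kwargs = dict(data)
    for name in tuple_fields:
        if name in kwargs and kwargs[name] is not None:
            kwargs[name] = tuple(kwargs[name])
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid value under '{path}': {exc}") from exc


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration, filling defaults.

    A minimal file (even just ``output_dir``) yields the full default study
    conditions.  Unknown keys anywhere raise ConfigError naming the key path.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    known = {"phantom", "material", "waveform", "solver", "landmarks",
             "output_dir", "seed", "log_level"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")

    phantom = _build(
        PhantomSpec, raw.get("phantom", {}), "phantom",
        tuple_fields=("semi_axes", "shell_fractions", "target_edge_length",
                      "inlet_location"),
    )
    mat_raw = dict(raw.get("material", {}))
    elast_raw = mat_raw.pop("elasticity", {})
    # the field generator inherits the master seed unless given its own
    if "seed" not in elast_raw:
        elast_raw = dict(elast_raw, seed=int(raw.get("seed", 0)))
    elasticity = _build(
        ElasticityFieldSpec, elast_raw, "material.elasticity",
        tuple_fields=("axis_contrast", "tumor_center"),
    )
    material = _build(
        MaterialConfig, dict(mat_raw, elasticity=elasticity), "material",
        tuple_fields=("branch_radii",),
    )
    waveform = _build(Waveform, raw.get("waveform", {}), "waveform")
    solver = _build(
        SolverConfig, raw.get("solver", {}), "solver",
        tuple_fields=("body_force", "gravity"),
    )
    if "extra_dirichlet" in raw.get("solver", {}):
        solver = replace(
            solver,
            extra_dirichlet=tuple(
                (str(t), str(c)) for t, c in raw["solver"]["extra_dirichlet"]
            ),
        )
    landmarks = raw.get("landmarks", "auto")
    if landmarks != "auto":
        if not isinstance(landmarks, list):
            raise ConfigError("'landmarks' must be 'auto' or a list of mappings")
        for i, lm in enumerate(landmarks):
            extra = set(lm) - {"id", "node_index", "description"}
            if extra:
                raise ConfigError(f"unknown key(s) {sorted(extra)} under 'landmarks[{i}]'")
            if "id" not in lm or "node_index" not in lm:
                raise ConfigError(f"'landmarks[{i}]' needs 'id' and 'node_index'")
    return RunConfig(
        phantom=phantom,
        material=material,
        waveform=waveform,
        solver=solver,
        landmarks=landmarks,
        output_dir=str(raw.get("output_dir", "porolung_out")),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
    )


def dump_config(cfg: RunConfig) -> str:
    """Canonical YAML serialization; ``load`` of the dump equals ``cfg``."""
    return yaml.safe_dump(asdict_config(cfg), sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash identifying the exact run configuration."""
    return hashlib.sha256(dump_config(cfg).encode()).hexdigest()[:12]
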