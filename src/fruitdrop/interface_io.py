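"""Configuration, logging, reproducibility and report plumbing.

A single validated configuration object (YAML or JSON on disk) feeds
every stage; unknown keys are rejected with the offending key path.
Reports are written as a deterministic CSV + JSON + VTK bundle with a
manifest of content hashes, so re-running with the same config and seed
reproduces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .damage_metrics import DamageThresholds
from .explicit_fem import SolverConfig
from .synthetic_fruit import FruitGeometry
from .tissue_mechanics import MaterialParams, load_material_library

__all__ = [
    "PipelineConfig",
    "load_config",
    "write_report",
    "RunManifest",
    "get_logger",
]

log = logging.getLogger("fruitdrop")


def get_logger() -> logging.Logger:
    if not log.handlers:
        h = logging.StreamHandler()
        h.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        log.addHandler(h)
        log.setLevel(logging.INFO)
    return log


class GeometryConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    length: float = 64.18
    d_max: float = 53.46
    d_min: float = 50.72
    skin_thickness: float = 0.3
    core_length_fraction: float = 0.55
    core_diameter_fraction: float = 0.25

    def build(self) -> FruitGeometry:
        return FruitGeometry(**self.model_dump())


class MaterialConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    young_modulus: Optional[float] = None
    tangent_modulus: Optional[float] = None
    bio_yield_stress: Optional[float] = None
    density: Optional[float] = None
    poisson_ratio: Optional[float] = None

    @field_validator("poisson_ratio")
    @classmethod
    def _nu_range(cls, v):
        if v is not None and not 0 < v < 0.5:
            raise ValueError("poisson_ratio must be in (0, 0.5)")
        return v


class SolverSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    time_step_safety: float = 0.9
    penalty_reference_thickness: float = 10.0
    foundation_modulus_cap: float = 250.0
    bulk_viscosity_linear: float = 0.06
    output_interval: int = 1
    contact_friction: float = 0.0
    nodal_pressure_averaging: bool = False
    instability_tolerance: float = 0.05

    def build(self) -> SolverConfig:
        return SolverConfig(**self.model_dump())


class ThresholdSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    flesh_yield: float = 0.26
    skin_yield: float = 0.52
    core_yield: float = 1.12

    def build(self) -> DamageThresholds:
        return DamageThresholds(**self.model_dump())


class PipelineConfig(BaseModel):
    """Validated top-level configuration (defaults reproduce the
    reference fruit and the published material table)."""

    model_config = ConfigDict(extra="forbid")
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    materials: dict[str, MaterialConfig] = Field(default_factory=dict)
    solver: SolverSection = Field(default_factory=SolverSection)
    thresholds: ThresholdSection = Field(default_factory=ThresholdSection)
    element_size: float = 2.0
    seed: int = 0
    energy_definition: str = "internal_peak"

    def build_materials(self) -> dict[str, MaterialParams]:
        lib = load_material_library()
        out = {}
        for name, base in lib.items():
            override = self.materials.get(name)
            if override is None:
                out[name] = base
                continue
            fields = {
                k: v if v is not None else getattr(base, k)
                for k, v in override.model_dump().items()
            }
            out[name] = MaterialParams(name=name, spread=base.spread, **fields)
        return out


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML/JSON config; an empty file gives the
    full defaults."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    raw = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else (
        json.loads(text) if text.strip() else None
    )
    if path.suffix in (".yml", ".yaml") and raw is None:
        raw = {}
    return PipelineConfig.model_validate(raw or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class RunManifest:
    """Record of a report bundle: config snapshot, seed, artifact hashes."""

    def __init__(self, config: PipelineConfig, seed: int):
        self.data = {
            "package": "fruitdrop",
            "version": _package_version(),
            "seed": seed,
            "config": config.model_dump(),
            "artifacts": {},
            "wall_time_s": None,
        }
        self._t0 = time.time()

    def add(self, path: Path) -> None:
        self.data["artifacts"][path.name] = _sha256(path)

    def write(self, path: Path) -> None:
        self.data["wall_time_s"] = round(time.time() - self._t0, 3)
        path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("fruitdrop")
    except Exception:
        return "unknown"


def write_report(grid, models: dict, outdir, config: Optional[PipelineConfig] = None,
                 seed: int = 0) -> Path:
    """Write the sweep results as a CSV + JSON bundle with a manifest.

    The CSV is byte-deterministic for fixed inputs (fixed float format,
    fixed row order).  A partial grid is written with its failure
    annotations; an empty grid produces a header-only CSV and a logged
    warning.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config or PipelineConfig(), seed)

    df = grid.to_dataframe()
    csv_path = outdir / "scenario_grid.csv"
    df.to_csv(csv_path, index=False, float_format="%.6g")
    manifest.add(csv_path)
    if df.empty:
        get_logger().warning("empty scenario grid: header-only CSV written")

    models_path = outdir / "response_surfaces.json"
    payload = {}
    for name, m in models.items():
        payload[name] = {
            "coefficients": list(np.asarray(m.coefficients, dtype=float)),
            "source": m.source,
            "r_squared": m.r_squared,
            "p_values": None if m.p_values is None else list(map(float, m.p_values)),
            "standardized_effects": m.standardized_effects,
        }
    models_path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    manifest.add(models_path)

    manifest_path = outdir / "manifest.json"
    manifest.write(manifest_path)
    return outdir


def plot_response_surface(model, path, x_bounds=(0.25, 1.0), y_bounds=(0.0, 90.0)):
    """PNG surface plot of one fitted/printed quadratic model."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = np.linspace(*x_bounds, 40)
    ys = np.linspace(*y_bounds, 40)
    gx, gy = np.meshgrid(xs, ys)
    z = model.predict(gx, gy)
    fig = plt.figure(figsize=(6, 4.5))
    ax = fig.add_subplot(111, projection="3d")
    ax.plot_surface(gx, gy, z, cmap="viridis", linewidth=0)
    ax.set_xlabel("drop height X (m)")
    ax.set_ylabel("collision angle Y (deg)")
    ax.set_zlabel("BS (mm$^3$ J$^{-1}$)")
    ax.set_title(f"Bruise susceptibility: {model.surface_material} ({model.source})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
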