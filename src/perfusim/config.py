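"""Run configuration, manifests and file outputs.

Configurations are YAML mappings validated against a strict schema (unknown
keys are rejected); every omitted field falls back to the bundled defaults
profile that reproduces the published parameter table.  Each run emits a
manifest recording the configuration hash, package version, wall time,
per-stage status and the inventory of files written, so that any number in a
report traces back to a configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator

from . import __version__
from .physics import TABLE_DEFAULTS, HenryLaw, km_to_concentration
from .scenarios import ScenarioSpec, run_scenario

__all__ = ["RunConfig", "ConfigError", "load_config", "write_outputs", "execute_run"]

log = logging.getLogger("perfusim")


class ConfigError(ValueError):
    """Schema violation with an itemized error list."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in self.errors))


class RunConfig(BaseModel):
    """Validated scenario + solver configuration."""

    model_config = ConfigDict(extra="forbid")

    bioreactor: str = "quasivivo"
    mode: str = "all"
    flow_rate_mL_min: float | None = None
    gas_fraction: float = 0.21
    species: str = "test_compound"
    cell_count: float | None = None
    width_variant: str = "original"
    recirculating: bool = False
    reservoir_volume_mL: float = 2.0
    duration_min: float = 60.0
    uniformity_threshold: float = 0.95
    resolution_mm: tuple[float, float] | None = None
    geometry_overrides: dict[str, float] | None = None
    viscosity: float = TABLE_DEFAULTS.fluid.viscosity
    density: float = TABLE_DEFAULTS.fluid.density
    oxygen_inlet: float = TABLE_DEFAULTS.c0  # mol/m^3
    km_mmHg: float = TABLE_DEFAULTS.km_mmhg
    output_dir: str = "runs"
    seed: int = 0

    @field_validator("viscosity", "density", "oxygen_inlet", "km_mmHg")
    @classmethod
    def _positive(cls, v, info):
        if v <= 0:
            raise ValueError(f"{info.field_name} must be positive")
        return v

    @field_validator("duration_min", "reservoir_volume_mL", "uniformity_threshold")
    @classmethod
    def _positive2(cls, v, info):
        if v <= 0:
            raise ValueError(f"{info.field_name} must be positive")
        return v

    def scenario(self) -> ScenarioSpec:
        return ScenarioSpec(
            bioreactor=self.bioreactor,
            flow_rate=None if self.flow_rate_mL_min is None else self.flow_rate_mL_min * 1e-6 / 60.0,
            gas_fraction=self.gas_fraction,
            species=self.species,
            cell_count=self.cell_count,
            mode=self.mode,
            width_variant=self.width_variant,
            recirculating=self.recirculating,
            reservoir_volume=self.reservoir_volume_mL * 1e-6,
            duration=self.duration_min * 60.0,
            uniformity_threshold=self.uniformity_threshold,
            resolution=None if self.resolution_mm is None else tuple(r * 1e-3 for r in self.resolution_mm),
            geometry_overrides=self.geometry_overrides,
            seed=self.seed,
        )

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load and validate a YAML configuration; empty file = all defaults."""
    raw = Path(path).read_text()
    data = yaml.safe_load(raw) or {}
    if not isinstance(data, dict):
        raise ConfigError(["top level must be a mapping"])
    try:
        cfg = RunConfig(**data)
    except ValidationError as exc:
        raise ConfigError(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
        ) from exc
    defaults = RunConfig()
    filled = {k: v for k, v in cfg.model_dump().items() if k not in data}
    log.info("config %s: defaults filled for %s", cfg.config_hash(), sorted(filled))
    log.info(
        "km conversion: %.3g mmHg -> %.4g mol/m^3 via K_O2 = %.1f atm/(mol/L)",
        cfg.km_mmHg, km_to_concentration(cfg.km_mmHg, HenryLaw()), HenryLaw().k_o2,
    )
    del defaults
    return cfg


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def write_outputs(result, manifest: dict, output_dir) -> list:
    """Write metric tables and the manifest; returns the file inventory."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    summary = result.summary()
    path = outdir / "summary.json"
    path.write_text(json.dumps(summary, indent=2, sort_keys=True, default=_json_default) + "\n")
    written.append(str(path))

    if result.transport is not None:
        path = outdir / "transport_timeseries.csv"
        result.transport.metrics.to_csv(path, index=False)
        written.append(str(path))
    if result.oxygen is not None:
        path = outdir / "oxygen_field.csv"
        _field_to_csv(result.oxygen, path)
        written.append(str(path))

    manifest = dict(manifest)
    manifest["outputs"] = written
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=_json_default) + "\n")
    written.append(str(mpath))
    return written


def _field_to_csv(field_, path) -> None:
    mesh = field_.mesh
    X, Y = mesh.cell_centers()
    mask = mesh.fluid
    import pandas as pd

    pd.DataFrame(
        {
            "x_m": X[mask],
            "y_m": Y[mask],
            "region": [mesh.region_names[r] for r in mesh.region[mask]],
            "c_mol_m3": field_.values[mask],
        }
    ).to_csv(path, index=False)


def execute_run(cfg: RunConfig) -> dict:
    """Run a configured scenario and write outputs; returns the manifest."""
    t0 = time.time()
    manifest = {
        "config": cfg.model_dump(),
        "config_hash": cfg.config_hash(),
        "version": __version__,
        "stages": {},
    }
    spec = cfg.scenario()
    try:
        result = run_scenario(spec)
        manifest["stages"]["scenario"] = "ok"
    except Exception as exc:
        manifest["stages"]["scenario"] = f"failed: {exc}"
        manifest["wall_time_s"] = time.time() - t0
        outdir = Path(cfg.output_dir) / cfg.config_hash()
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=_json_default) + "\n"
        )
        raise
    manifest["geometry_defaults"] = result.geometry.describe()
    manifest["wall_time_s"] = time.time() - t0
    written = write_outputs(result, manifest, Path(cfg.output_dir) / cfg.config_hash())
    manifest["outputs"] = written
    return manifest
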