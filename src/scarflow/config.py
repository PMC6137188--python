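"""Validated run configuration shared by the CLI and the end-to-end driver.

A run config is a YAML mapping of blocks (``device``, ``model``,
``culture``, ``optics``, ``segmentation``, ``sort``, ``output``); every
key has a default, unknown keys are rejected, and each block is converted
into its module's typed object (which re-validates the physical
invariants).  Validation errors name the offending key path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigError
from .focusing import DEFAULT_FORCE_MODEL, DEFAULT_OUTLET_EDGES, ForceModel
from .hydraulics import ChannelGeometry, Fluid, FlowCondition
from .imaging import LayoutParams, OpticsConfig
from .pipeline import SegmentationParams
from .population import CultureParams, DiameterModel

__all__ = ["RunConfig", "load_config", "dump_config", "config_from_dict"]

_DEVICE_KEYS = {
    "width_um": 200.0,
    "height_um": 33.0,
    "radius_um": 900.0,
    "n_arcs": 4,
    "n_outlets": 5,
    "flow_ul_min": 1500.0,
    "rho": 998.0,
    "mu": 0.9983e-3,
}

_MODEL_KEYS = {
    "c_sg": DEFAULT_FORCE_MODEL.c_sg,
    "c_w": DEFAULT_FORCE_MODEL.c_w,
    "c_d": DEFAULT_FORCE_MODEL.c_d,
    "beta": DEFAULT_FORCE_MODEL.beta,
    "sigma_f": DEFAULT_FORCE_MODEL.sigma_f,
    "skew_cap": DEFAULT_FORCE_MODEL.skew_cap,
}

_CULTURE_KEYS = {
    "mode": "high_density",
    "n": 2000,
    "seed": 0,
    "t0_h": 1.5,
    "stress_slope": 0.1,
    "duration_h": 9.0,
    "daughter_survival": 0.48,
    "d0_um": 2.3,
    "slope_um_per_scar": 0.8,
    "noise_sd_um": 1.0,
    "k_sat": 11,
}

_OPTICS_KEYS = {
    "pixel_size_um": 0.1,
    "psf_sigma_px": 1.2,
    "image_size": [512, 512],
    "background": 20.0,
    "photon_gain": 0.8,
    "read_noise_sd": 4.0,
}

_SEGMENTATION_KEYS = {
    "d_min_um": 1.5,
    "d_max_um": 15.0,
    "pixel_size_um": 0.1,
    "threshold_correction_cells": 2.0,
    "threshold_correction_puncta": 1.5,
    "adaptive_window_px": 200,
    "declump_h_px": 2.0,
    "dilation_px": 2.0,
}

_SORT_KEYS = {
    "outlet_edges": list(DEFAULT_OUTLET_EDGES),
}

_OUTPUT_KEYS = {
    "directory": "scarflow_out",
    "qc_plots": False,
}

_SCHEMA = {
    "device": _DEVICE_KEYS,
    "model": _MODEL_KEYS,
    "culture": _CULTURE_KEYS,
    "optics": _OPTICS_KEYS,
    "segmentation": _SEGMENTATION_KEYS,
    "sort": _SORT_KEYS,
    "output": _OUTPUT_KEYS,
}


@dataclass(frozen=True)
class RunConfig:
    """Fully validated configuration with typed module objects."""

    raw: dict = field(repr=False)
    geometry: ChannelGeometry = field(repr=False)
    fluid: Fluid = field(repr=False)
    flow: FlowCondition = field(repr=False)
    force_model: ForceModel = field(repr=False)
    culture: CultureParams = field(repr=False)
    diameter_model: DiameterModel = field(repr=False)
    culture_mode: str = "high_density"
    culture_n: int = 2000
    seed: int = 0
    optics: OpticsConfig = field(default=None, repr=False)
    layout: LayoutParams = field(default=None, repr=False)
    segmentation: SegmentationParams = field(default=None, repr=False)
    outlet_edges: tuple = DEFAULT_OUTLET_EDGES
    output_dir: Path = Path("scarflow_out")
    qc_plots: bool = False


def _merge_block(name: str, user: Any) -> dict:
    defaults = dict(_SCHEMA[name])
    if user is None:
        return defaults
    if not isinstance(user, dict):
        raise ConfigError(f"{name}: expected a mapping")
    for key, value in user.items():
        if key not in defaults:
            raise ConfigError(f"unknown key {name}.{key}")
        default = defaults[key]
        if isinstance(default, bool):
            if not isinstance(value, bool):
                raise ConfigError(f"{name}.{key}: expected a boolean")
        elif isinstance(default, (int, float)) and not isinstance(value, (int, float)):
            raise ConfigError(f"{name}.{key}: expected a number")
        defaults[key] = value
    return defaults


def config_from_dict(data: dict | None) -> RunConfig:
    """Validate a raw mapping and build the typed configuration."""
    data = data or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    for block in data:
        if block not in _SCHEMA:
            raise ConfigError(f"unknown configuration block '{block}'")
    merged = {name: _merge_block(name, data.get(name)) for name in _SCHEMA}

    dev = merged["device"]
    try:
        geometry = ChannelGeometry(
            width_um=dev["width_um"],
            height_um=dev["height_um"],
            radius_um=dev["radius_um"],
            n_arcs=int(dev["n_arcs"]),
            n_outlets=int(dev["n_outlets"]),
        )
    except Exception as exc:
        raise ConfigError(f"device: {exc}") from exc
    try:
        fluid = Fluid(density=dev["rho"], dynamic_viscosity=dev["mu"])
        flow = FlowCondition(dev["flow_ul_min"], geometry, fluid)
    except Exception as exc:
        raise ConfigError(f"device: {exc}") from exc

    try:
        force_model = ForceModel(**merged["model"])
    except Exception as exc:
        raise ConfigError(f"model: {exc}") from exc

    cul = merged["culture"]
    if cul["mode"] not in ("exponential", "high_density"):
        raise ConfigError("culture.mode must be 'exponential' or 'high_density'")
    if int(cul["n"]) < 1:
        raise ConfigError("culture.n must be at least 1")
    try:
        culture = CultureParams(
            t0_h=cul["t0_h"],
            stress_slope=cul["stress_slope"],
            duration_h=cul["duration_h"],
            daughter_survival=cul["daughter_survival"],
        )
        diameter_model = DiameterModel(
            d0_um=cul["d0_um"],
            slope_um_per_scar=cul["slope_um_per_scar"],
            noise_sd_um=cul["noise_sd_um"],
            k_sat=int(cul["k_sat"]),
        )
    except Exception as exc:
        raise ConfigError(f"culture: {exc}") from exc

    opt = merged["optics"]
    try:
        optics = OpticsConfig(
            pixel_size_um=opt["pixel_size_um"],
            psf_sigma_px=opt["psf_sigma_px"],
            image_size=tuple(int(v) for v in opt["image_size"]),
            background=opt["background"],
            photon_gain=opt["photon_gain"],
            read_noise_sd=opt["read_noise_sd"],
        )
    except ConfigError:
        raise
    except Exception as exc:
        raise ConfigError(f"optics: {exc}") from exc

    try:
        segmentation = SegmentationParams(**merged["segmentation"])
    except Exception as exc:
        raise ConfigError(f"segmentation: {exc}") from exc

    edges = tuple(float(e) for e in merged["sort"]["outlet_edges"])

    out = merged["output"]
    return RunConfig(
        raw=merged,
        geometry=geometry,
        fluid=fluid,
        flow=flow,
        force_model=force_model,
        culture=culture,
        diameter_model=diameter_model,
        culture_mode=cul["mode"],
        culture_n=int(cul["n"]),
        seed=int(cul["seed"]),
        optics=optics,
        layout=LayoutParams(),
        segmentation=segmentation,
        outlet_edges=edges,
        output_dir=Path(out["directory"]),
        qc_plots=bool(out["qc_plots"]),
    )


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML config file; ``None`` or empty file = defaults."""
    if path is None:
        return config_from_dict({})
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
    return config_from_dict(data)


def dump_config(config: RunConfig) -> str:
    """Serialise the normalised configuration back to YAML."""
    return yaml.safe_dump(config.raw, sort_keys=True)
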