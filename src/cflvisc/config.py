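"""Structured-text run configuration (YAML, schema-versioned).

Keys carry explicit units in their names (``*_um``, ``*_mPa_s``) to
prevent unit drift between the configuration and the µm/mPa·s interface of
the model.  A fluid may reference a preset from the built-in catalog or be
given inline.
"""

from __future__ import annotations

import yaml

from .field import ChannelGeometry, GridSpec
from .kinematics import CFLDevelopment, calibrate_parabola
from .model import GapFlowModel
from .rheology import FluidSpec
from .synthetic import ProfileScenario, presets

__all__ = [
    "ConfigError",
    "SCHEMA_VERSION",
    "load_config",
    "build_fluid",
    "build_geometry",
    "build_development",
    "build_grid",
    "build_scenario",
    "build_model",
]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Invalid run configuration."""


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("configuration must be a mapping")
    version = cfg.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(
            f"unsupported schema_version {version} (expected {SCHEMA_VERSION})"
        )
    return cfg


def build_fluid(cfg: dict) -> FluidSpec:
    spec = cfg.get("fluid")
    if spec is None:
        raise ConfigError("missing 'fluid' section")
    if "preset" in spec:
        catalog = presets()["fluids"]
        name = spec["preset"]
        if name not in catalog:
            raise ConfigError(
                f"unknown fluid preset {name!r}; available: {sorted(catalog)}"
            )
        return catalog[name]
    try:
        return FluidSpec.from_mpas(
            mu_carrier_mPa_s=float(spec["mu_carrier_mPa_s"]),
            mu_rheo_mPa_s=float(spec["mu_rheo_mPa_s"]),
            phi_bulk=float(spec.get("phi_bulk", 0.0)),
            density=float(spec.get("density_kg_m3", 1050.0)),
            label=str(spec.get("label", "")),
        )
    except KeyError as exc:
        raise ConfigError(f"fluid section missing key {exc}") from exc


def build_geometry(cfg: dict) -> ChannelGeometry:
    g = cfg.get("geometry", {})
    return ChannelGeometry(
        H_um=float(g.get("H_um", 150.0)),
        W_um=float(g.get("W_um", 1200.0)),
        L_um=float(g.get("L_um", 10_000.0)),
    )


def build_development(cfg: dict, geom: ChannelGeometry) -> CFLDevelopment:
    d = cfg.get("development")
    if d is None:
        raise ConfigError("missing 'development' section")
    if "planes" in d:
        planes = d["planes"]
        if len(planes) < 2:
            raise ConfigError("'planes' needs two [x_um, h_cfl_um] pairs")
        return calibrate_parabola(
            tuple(map(float, planes[0])),
            tuple(map(float, planes[1])),
            x0_um=float(d.get("x0_um", 1.0)),
            H_um=geom.H_um,
            exponent=float(d.get("exponent", 0.5)),
            h_ss_um=float(d["h_ss_um"]) if "h_ss_um" in d else None,
        )
    try:
        return CFLDevelopment(
            a=float(d["a"]),
            x0_um=float(d.get("x0_um", 1.0)),
            x_star_um=float(d["x_star_um"]) if "x_star_um" in d else None,
            h_ss_um=float(d["h_ss_um"]) if "h_ss_um" in d else None,
            exponent=float(d.get("exponent", 0.5)),
        )
    except KeyError as exc:
        raise ConfigError(f"development section missing key {exc}") from exc


def build_grid(cfg: dict) -> GridSpec:
    g = cfg.get("grid", {})
    return GridSpec(
        n_h=int(g.get("n_h", 256)),
        n_x_dev=int(g.get("n_x_dev", 64)),
        n_x_steady=int(g.get("n_x_steady", 16)),
    )


def build_scenario(cfg: dict) -> ProfileScenario:
    s = cfg.get("scenario", {})
    kwargs = {}
    if "phi_bulk" in s:
        kwargs["phi_bulk"] = float(s["phi_bulk"])
    if "h_cfl_um" in s:
        kwargs["h_cfl_um"] = tuple(map(float, s["h_cfl_um"]))
    if "core_shape" in s:
        kwargs["core_shape"] = str(s["core_shape"])
    if "noise_sd" in s:
        kwargs["noise_sd"] = float(s["noise_sd"])
    if "n_bins" in s:
        kwargs["n_bins"] = int(s["n_bins"])
    if "measurement_planes_um" in s:
        kwargs["measurement_planes_um"] = tuple(map(float, s["measurement_planes_um"]))
    kwargs["seed"] = int(cfg.get("seed", s.get("seed", 0)))
    return ProfileScenario(**kwargs)


def build_model(cfg: dict) -> GapFlowModel:
    fluid = build_fluid(cfg)
    geom = build_geometry(cfg)
    dev = build_development(cfg, geom)
    grid = build_grid(cfg)
    submodel = cfg.get("submodel", "step")
    convention = cfg.get("convention", "total")
    steady_profile = None
    if submodel == "local_distribution":
        from .synthetic import generate_profile

        scenario = build_scenario(cfg)
        steady_profile = generate_profile(scenario, geom)
    return GapFlowModel(
        fluid,
        geom,
        dev,
        submodel=submodel,
        steady_profile=steady_profile,
        grid=grid,
        convention=convention,
    )


def reynolds_list(cfg: dict) -> list[float]:
    cond = cfg.get("conditions", {})
    re = cond.get("reynolds", [100.0])
    if isinstance(re, (int, float)):
        re = [re]
    if not re:
        raise ConfigError("'conditions.reynolds' must be a non-empty list")
    return [float(r) for r in re]
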