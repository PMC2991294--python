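"""YAML run configuration: schema, validation, and (de)serialisation.

A run config has three sections::

    particle:            # shape + pose
      kind: sphere | spheroid | spiral
      ...dimensions...
      orientation: tip_first | side_on     # spheroids only
    params:              # energy parameters, units as conventionally printed
      kappa_b: 1.3e-2        # pN um
      sigma_mN_per_m: 6.2e-6 # mN/m
      kappa_P: 2.56e-5       # pN um^-5
      epsilon: 58.5          # pN/um
      temperature: 310.0     # K
    simulation:          # Monte Carlo configuration (see SimulationConfig)
      mode: active
      seed: 1
      ...

R0 (contact-shell width = contact mesh size) defaults to 0.05 times the
particle radius; the refinement range defaults to the particle radius.
"""

from __future__ import annotations

import numpy as np
import yaml

from .energy import EnergyParams, MN_PER_M_TO_PN_PER_UM
from .particles import (
    Sphere, Spheroid, SpiralRod, make_spiral,
    spheroid_tip_first, spheroid_side_on,
)
from .simulate import SimulationConfig


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


def _require(d, key, section):
    if key not in d:
        raise ConfigError(f"missing required key '{key}' in section "
                          f"'{section}'")
    return d[key]


def shape_from_config(d: dict):
    kind = _require(d, "kind", "particle")
    if kind == "sphere":
        r = float(_require(d, "radius", "particle"))
        if r <= 0:
            raise ConfigError("particle.radius must be positive")
        return Sphere(radius=r)
    if kind == "spheroid":
        r1 = float(d.get("r1", 1.5))
        r3 = float(d.get("r3", 4.2))
        orient = d.get("orientation", "tip_first")
        if orient == "tip_first":
            return spheroid_tip_first(r1, r3)
        if orient == "side_on":
            return spheroid_side_on(r1, r3)
        raise ConfigError(
            f"particle.orientation must be 'tip_first' or 'side_on', "
            f"got {orient!r}")
    if kind == "spiral":
        if "tube_radius" in d:
            return SpiralRod(
                helix_radius=float(d.get("helix_radius", 1.2)),
                pitch=float(d.get("pitch", 2.0)),
                tube_radius=float(d["tube_radius"]),
                n_turns=float(d.get("n_turns", 3.0)))
        return make_spiral(
            float(d.get("volume_equivalent_radius", 2.2)),
            helix_radius=float(d.get("helix_radius", 1.2)),
            pitch=float(d.get("pitch", 2.0)),
            n_turns=float(d.get("n_turns", 3.0)))
    raise ConfigError(f"unknown particle kind {kind!r}")


def characteristic_radius(shape) -> float:
    """The 'particle radius R' used for R0, refinement range and move
    widths: the radius for spheres, the volume-equivalent radius otherwise."""
    if isinstance(shape, Sphere):
        return shape.radius
    return (3.0 * shape.volume() / (4.0 * np.pi)) ** (1.0 / 3.0)


def load_config(path_or_dict):
    """Parse and validate a YAML config.

    Returns (SimulationConfig, EnergyParams, shape).
    """
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        with open(path_or_dict) as fh:
            try:
                raw = yaml.safe_load(fh)
            except yaml.YAMLError as exc:
                raise ConfigError(f"malformed YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    for section in ("particle",):
        if section not in raw:
            raise ConfigError(f"missing section '{section}'")
    shape = shape_from_config(raw["particle"])
    R = characteristic_radius(shape)

    pd = dict(raw.get("params", {}))
    pd.setdefault("R0", 0.05 * R)
    if pd["R0"] >= 0.1 * R:
        raise ConfigError(
            f"params.R0 = {pd['R0']} violates the contact-width bound "
            f"R0 < 0.1 R = {0.1 * R}")
    try:
        params = EnergyParams.from_dict(pd)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid params section: {exc}") from exc

    sd = dict(raw.get("simulation", {}))
    sd.setdefault("mesh_size", params.R0)
    sd.setdefault("refine_range", R)
    try:
        config = SimulationConfig(**sd)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid simulation section: {exc}") from exc
    if config.temperature != params.temperature:
        params = params.with_(temperature=config.temperature)
    return config, params, shape


def dump_config(config: SimulationConfig, params: EnergyParams, shape,
                path=None) -> str:
    from dataclasses import asdict

    doc = {
        "particle": shape.to_dict(),
        "params": params.to_dict(),
        "simulation": {k: v for k, v in asdict(config).items()
                       if v is not None},
    }
    # numpy types are not YAML-native
    text = yaml.safe_dump(_pythonify(doc), sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _pythonify(obj):
    if isinstance(obj, dict):
        return {k: _pythonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_pythonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
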