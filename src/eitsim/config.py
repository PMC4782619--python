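"""YAML run configuration.

User-facing units follow lab convention — millimetres, degrees and
milliamperes — and are converted to SI (metres, radians, amperes) on load.
A minimal configuration needs only the phantom's radius and background
conductivity; everything else has documented defaults.  The ``phantom``
block may also be the name of a catalogue fixture (see
:mod:`eitsim.fixtures`).

Example
-------
.. code-block:: yaml

    phantom:
      radius_mm: 75
      background_conductivity: 0.21
      inhomogeneities:
        - {center_r_mm: 37.5, center_theta_deg: 45, radius_mm: 25,
           conductivity: 0.005}
    mesh: {n_rings: 16, n_sectors: 8, inverse_n_rings: 8}
    protocol: {mode: grounded, amplitude_ma: 1.0}
    noise: {sd_volts: 0.0, seed: 0}
    inverse: {regularization: auto, variant: eq20, max_iter: 15, tol: 1.0e-6}
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .fixtures import make_fixture
from .inverse import InverseSettings
from .phantom import Inhomogeneity, PhantomSpec
from .protocol import MODES

__all__ = ["RunConfig", "ConfigError", "load_config", "config_from_dict"]


class ConfigError(ValueError):
    """Configuration validation failure, reported with its field path."""


@dataclass(frozen=True)
class RunConfig:
    """Fully validated run configuration in SI units."""

    phantom: PhantomSpec
    n_rings: int = 16
    n_sectors: int = 8
    inverse_n_rings: int = 8
    n_electrodes: int = 16
    mode: str = "grounded"
    amplitude: float = 1e-3
    noise_sd: float = 0.0
    seed: int = 0
    inverse: InverseSettings = field(default_factory=InverseSettings)


def _get(d: dict, key: str, default, path: str, types):
    value = d.get(key, default)
    if value is None:
        raise ConfigError(f"{path}.{key}: missing required field")
    if not isinstance(value, types) or isinstance(value, bool):
        raise ConfigError(
            f"{path}.{key}: expected {types}, got {type(value).__name__}"
        )
    return value


def _parse_phantom(block, path: str = "phantom") -> PhantomSpec:
    if isinstance(block, str):
        try:
            return make_fixture(block)
        except ValueError as exc:
            raise ConfigError(f"{path}: {exc}") from None
    if not isinstance(block, dict):
        raise ConfigError(f"{path}: expected a mapping or a fixture name")
    radius = _get(block, "radius_mm", None, path, (int, float)) * 1e-3
    sigma_b = _get(block, "background_conductivity", None, path, (int, float))
    inhs = []
    for i, item in enumerate(block.get("inhomogeneities") or []):
        p = f"{path}.inhomogeneities[{i}]"
        if not isinstance(item, dict):
            raise ConfigError(f"{p}: expected a mapping")
        inhs.append(
            Inhomogeneity(
                center_r=_get(item, "center_r_mm", 0.0, p, (int, float)) * 1e-3,
                center_theta=math.radians(
                    _get(item, "center_theta_deg", 0.0, p, (int, float))
                ),
                radius=_get(item, "radius_mm", None, p, (int, float)) * 1e-3,
                conductivity=_get(item, "conductivity", None, p, (int, float)),
            )
        )
    try:
        return PhantomSpec(
            domain_radius=radius,
            background_conductivity=sigma_b,
            inhomogeneities=tuple(inhs),
        )
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from None


def config_from_dict(raw: dict) -> RunConfig:
    """Validate a parsed configuration mapping and fill defaults."""
    if not isinstance(raw, dict) or "phantom" not in raw:
        raise ConfigError("top level: a 'phantom' block is required")
    phantom = _parse_phantom(raw["phantom"])

    mesh = raw.get("mesh") or {}
    n_rings = _get(mesh, "n_rings", 16, "mesh", int)
    n_sectors = _get(mesh, "n_sectors", 8, "mesh", int)
    inverse_n_rings = _get(mesh, "inverse_n_rings", 8, "mesh", int)

    proto = raw.get("protocol") or {}
    mode = _get(proto, "mode", "grounded", "protocol", str)
    if mode not in MODES:
        raise ConfigError(f"protocol.mode: {mode!r} is not one of {MODES}")
    amplitude = _get(proto, "amplitude_ma", 1.0, "protocol", (int, float)) * 1e-3
    n_electrodes = _get(proto, "n_electrodes", 16, "protocol", int)

    noise = raw.get("noise") or {}
    noise_sd = _get(noise, "sd_volts", 0.0, "noise", (int, float))
    seed = _get(noise, "seed", 0, "noise", int)
    if noise_sd < 0:
        raise ConfigError("noise.sd_volts: must be >= 0")

    inv = raw.get("inverse") or {}
    try:
        inverse = InverseSettings(
            regularization=inv.get("regularization", "auto"),
            variant=_get(inv, "variant", "eq20", "inverse", str),
            max_iter=_get(inv, "max_iter", 15, "inverse", int),
            tol=_get(inv, "tol", 1e-6, "inverse", (int, float)),
            sigma0=inv.get("sigma0", phantom.background_conductivity),
        )
    except ValueError as exc:
        raise ConfigError(f"inverse: {exc}") from None

    return RunConfig(
        phantom=phantom,
        n_rings=n_rings,
        n_sectors=n_sectors,
        inverse_n_rings=inverse_n_rings,
        n_electrodes=n_electrodes,
        mode=mode,
        amplitude=amplitude,
        noise_sd=noise_sd,
        seed=seed,
        inverse=inverse,
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text())
    return config_from_dict(raw if raw is not None else {})
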