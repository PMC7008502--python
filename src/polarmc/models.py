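"""Named optical models of the skin dermal layer.

Three slab model families are used to interpret transmission Mueller
microscopy of dermal tissue:

* ``SC``  — spheres + aligned cylinders in an isotropic host
  (``delta_n = 0``): scattering anisotropy only;
* ``SB``  — spheres in a uniaxial linearly birefringent host
  (``mu_c = 0``): intrinsic birefringence only;
* ``SCB`` — spheres + aligned cylinders in the birefringent host:
  both mechanisms.

Shared defaults: scatterer indices 1.45, host (ordinary) index 1.33,
wavelength 0.533 um, sphere radius 0.05 um (subwavelength, Rayleigh
regime), sphere scattering coefficient 1500 cm^-1; the birefringent
hosts use the best-fit delta_n = 0.009 with in-plane optic axis along
X, and cylinders of radius 0.05 um aligned along X.  Model detection
averages the forward Mueller image over a central 600-um circle within
a 20-deg angular acceptance cone (a microscope objective collects a
finite angular range; see the methods note).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass


import yaml

from .engine import ModelConfig

__all__ = ["ModelPreset", "make_preset", "preset", "PRESET_NAMES", "load_config", "save_config"]

PRESET_NAMES = ("SC", "SB", "SCB")

#: thickness grid of the standard sweeps (um)
THICKNESS_GRID = tuple(float(d) for d in range(3, 31, 3))

#: thickness grid of the cylinder-bearing models: the cumulative
#: retardance and attenuation of the SC/SCB slabs push the matrix
#: logarithm against its principal-branch limit beyond ~24 um at
#: tractable photon budgets, so their standard sweeps stop at 21 um
THICKNESS_GRID_CYL = tuple(float(d) for d in range(3, 22, 3))

#: cylinder scattering coefficient sweep of the SCB model (cm^-1)
MU_C_GRID = (500.0, 1000.0, 1500.0)

#: cylinder radius sweep (um)
RC_GRID = (0.05, 0.5, 2.0)

_COMMON = dict(
    thickness_um=15.0,
    wavelength_um=0.533,
    mu_s_cm=1500.0,
    radius_sphere_um=0.05,
    n_sphere=1.45,
    n_cyl=1.45,
    n_host=1.33,
    accept_half_angle_deg=20.0,
)

_PRESETS = {
    "SC": dict(_COMMON, mu_c_cm=1500.0, radius_cyl_um=0.05, delta_n=0.0),
    "SB": dict(_COMMON, mu_c_cm=0.0, delta_n=0.009),
    "SCB": dict(_COMMON, mu_c_cm=1500.0, radius_cyl_um=0.05, delta_n=0.009),
}

# studied parameter envelope: diameters 0.01-0.5 um, mu 5-5000 cm^-1,
# host delta_n sweep 1e-5..1e-3 plus the 0.009 best fit
_DIAMETER_RANGE = (0.01, 0.5)
_MU_RANGE = (5.0, 5000.0)
_DELTA_N_MAX = 0.009


@dataclass(frozen=True)
class ModelPreset:
    """A named model family plus its standard sweep axes."""

    name: str
    base: ModelConfig
    thicknesses_um: tuple = THICKNESS_GRID
    mu_c_values_cm: tuple = ()
    rc_values_um: tuple = ()


def make_preset(name: str, **overrides) -> ModelConfig:
    """Fully populated configuration for one of the named models.

    Overrides are shallow-merged onto the preset defaults and validated
    against the model-class invariants (an SB model cannot carry
    cylinders, an SC model cannot carry host birefringence).
    Parameters outside the studied envelope produce a warning, not an
    error.
    """
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    params = dict(_PRESETS[name])
    params.update(overrides)
    cfg = ModelConfig(**params)
    if name == "SB" and cfg.mu_c_cm != 0.0:
        raise ValueError("SB model has no cylindrical scatterers (mu_c must be 0)")
    if name == "SC" and cfg.delta_n != 0.0:
        raise ValueError("SC model has an isotropic host (delta_n must be 0)")
    if name == "SCB" and (cfg.mu_c_cm <= 0.0 or cfg.delta_n <= 0.0):
        raise ValueError("SCB model requires mu_c > 0 and delta_n > 0")
    _warn_envelope(cfg)
    return cfg


def preset(name: str, **overrides) -> ModelPreset:
    """The named preset with its standard sweep axes attached."""
    base = make_preset(name, **overrides)
    sweeps = {}
    if name == "SCB":
        sweeps = dict(mu_c_values_cm=MU_C_GRID, rc_values_um=RC_GRID)
    if name in ("SC", "SCB"):
        sweeps["thicknesses_um"] = THICKNESS_GRID_CYL
    return ModelPreset(name=name, base=base, **sweeps)


def _warn_envelope(cfg: ModelConfig) -> None:
    lo, hi = _DIAMETER_RANGE
    for label, radius in (("sphere", cfg.radius_sphere_um), ("cylinder", cfg.radius_cyl_um)):
        relevant = cfg.mu_s_cm > 0 if label == "sphere" else cfg.mu_c_cm > 0
        if relevant and not lo <= 2.0 * radius <= hi:
            warnings.warn(
                f"{label} diameter {2 * radius} um is outside the studied "
                f"range {_DIAMETER_RANGE} um",
                stacklevel=3,
            )
    for label, mu in (("mu_s", cfg.mu_s_cm), ("mu_c", cfg.mu_c_cm)):
        if mu > 0 and not _MU_RANGE[0] <= mu <= _MU_RANGE[1]:
            warnings.warn(
                f"{label}={mu} cm^-1 is outside the studied range {_MU_RANGE}",
                stacklevel=3,
            )
    if cfg.delta_n > _DELTA_N_MAX:
        warnings.warn(
            f"delta_n={cfg.delta_n} exceeds the studied maximum {_DELTA_N_MAX}",
            stacklevel=3,
        )


def save_config(path, cfg: ModelConfig) -> None:
    """Write a configuration as YAML (or JSON if the suffix is .json)."""
    d = cfg.to_dict()
    text = (
        json.dumps(d, indent=2)
        if str(path).endswith(".json")
        else yaml.safe_dump(d, sort_keys=False)
    )
    with open(path, "w") as fh:
        fh.write(text)


def load_config(path) -> ModelConfig:
    """Read a configuration written by :func:`save_config`."""
    with open(path) as fh:
        text = fh.read()
    d = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return ModelConfig.from_dict(d)
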