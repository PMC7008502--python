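"""Shared fixtures.

The expensive Monte Carlo sweeps are session-scoped so that the
acceptance checks (thickness laws, null results, model discrimination)
all reuse one simulation per model family.
"""

from __future__ import annotations

import numpy as np
import pytest

from polarmc.experiments import thickness_sweep, parameter_sweep
from polarmc.models import make_preset

ACCEPT_SEED = 20260922
ACCEPT_PHOTONS = 100_000


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sb_sweep():
    """SB preset thickness sweep, 3-30 um, 1e5 photons/state."""
    cfg = make_preset("SB")
    return thickness_sweep(
        cfg, [float(d) for d in range(3, 31, 3)],
        n_photons=ACCEPT_PHOTONS, seed=ACCEPT_SEED, model="SB",
    )


@pytest.fixture(scope="session")
def scb_sweep():
    """SCB preset (mu_c=1500/cm) thickness sweep, 3-21 um."""
    cfg = make_preset("SCB", mu_c_cm=1500.0)
    return thickness_sweep(
        cfg, [float(d) for d in range(3, 22, 3)],
        n_photons=ACCEPT_PHOTONS, seed=ACCEPT_SEED, model="SCB",
    )


@pytest.fixture(scope="session")
def sc_sweep():
    """SC preset thickness sweep (isotropic host), 3-21 um."""
    cfg = make_preset("SC")
    return thickness_sweep(
        cfg, [float(d) for d in range(3, 22, 3)],
        n_photons=ACCEPT_PHOTONS, seed=ACCEPT_SEED, model="SC",
    )


@pytest.fixture(scope="session")
def scb_mu_c_sweep():
    """aLA vs cylinder scattering coefficient at the thickest SCB slab."""
    cfg = make_preset("SCB", thickness_um=21.0)
    return parameter_sweep(
        cfg, "mu_c_cm", [500.0, 1000.0, 1500.0],
        n_photons=10 * ACCEPT_PHOTONS, seed=ACCEPT_SEED, model="SCB",
    )


@pytest.fixture(scope="session")
def scb_rc_sweep():
    """aLA vs cylinder radius at the thickest SCB slab."""
    cfg = make_preset("SCB", thickness_um=21.0, mu_c_cm=1500.0)
    return parameter_sweep(
        cfg, "radius_cyl_um", [0.05, 0.5, 2.0],
        n_photons=10 * ACCEPT_PHOTONS, seed=ACCEPT_SEED, model="SCB",
    )
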