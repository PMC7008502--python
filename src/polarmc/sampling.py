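"""Tabulated phase functions and polarization-aware angle sampling.

The rejection samplers draw scattering angles from the *polarized*
single-scattering phase function of the incident Stokes vector,

    sphere:    p(theta, phi) ~ S11(theta) + S12(theta) (q cos 2phi + u sin 2phi),
    cylinder:  p(Theta)      ~ m11 + m12 q + m13 u + m14 v   on the zeta-cone,

using envelopes precomputed on dense angle grids (a documented safety
factor of 1.05 is applied; a sampled density exceeding the envelope is
a hard error, indicating a too-coarse grid).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import _kernel
from .cylinder import cylinder_efficiencies, cylinder_mueller
from .mie import single_scatter_mueller

__all__ = [
    "EnvelopeError",
    "SphereTables",
    "CylinderTables",
    "build_sphere_tables",
    "build_cylinder_tables",
    "sample_sphere_angles",
    "sample_cylinder_angles",
]

#: smallest tabulated angle between the propagation direction and the
#: cylinder axis; near-axial incidence is clamped to this value
ZETA_MIN = np.deg2rad(0.5)


class EnvelopeError(RuntimeError):
    """Sampled density exceeded the rejection envelope (grid too coarse)."""


@dataclass(frozen=True)
class SphereTables:
    """Tabulated sphere phase-function elements on a uniform theta grid."""

    x: float
    m: float
    s11: np.ndarray
    s12: np.ndarray
    s33: np.ndarray
    s34: np.ndarray
    pmax: float

    @property
    def n_theta(self) -> int:
        return self.s11.shape[0]


@dataclass(frozen=True)
class CylinderTables:
    """Tabulated cylinder Mueller matrices on a (zeta, Theta) grid.

    ``mueller`` has shape (n_zeta, n_theta, 4, 4) with zeta uniform on
    [ZETA_MIN, pi/2] and Theta uniform on [0, 2 pi].  ``crow`` holds the
    azimuth-integrated first row (the polarized total scattered power
    coefficients) per zeta row; ``env`` the per-row phase-function
    envelope.
    """

    x: float
    m: float
    zeta0: float
    dzeta: float
    mueller: np.ndarray
    crow: np.ndarray
    env: np.ndarray
    #: per-row scattering efficiencies for E parallel / perpendicular to
    #: the (direction, axis) plane, normalized by the unpolarized
    #: normal-incidence efficiency — these set the polarized extinction
    #: rates relative to the configured (unpolarized) mu_c
    ext_par: np.ndarray
    ext_perp: np.ndarray


@lru_cache(maxsize=16)
def build_sphere_tables(x: float, m: float, n_theta: int = 721) -> SphereTables:
    """Tabulate S11, S12, S33, S34 of the Mie Mueller block over [0, pi]."""
    theta = np.linspace(0.0, np.pi, n_theta)
    M = single_scatter_mueller(x, m, theta)
    s11 = np.ascontiguousarray(M[:, 0, 0])
    s12 = np.ascontiguousarray(M[:, 0, 1])
    s33 = np.ascontiguousarray(M[:, 2, 2])
    s34 = np.ascontiguousarray(M[:, 2, 3])
    pmax = float(np.max(s11 + np.abs(s12)))
    if pmax <= 0.0:
        pmax = 1.0  # index-matched scatterer: flat (never exercised) envelope
    return SphereTables(x=x, m=m, s11=s11, s12=s12, s33=s33, s34=s34, pmax=pmax)


@lru_cache(maxsize=16)
def build_cylinder_tables(
    x: float, m: float, n_zeta: int = 91, n_theta: int = 721
) -> CylinderTables:
    """Tabulate the oblique-incidence cylinder Mueller matrix."""
    zetas = np.linspace(ZETA_MIN, np.pi / 2.0, n_zeta)
    thetas = np.linspace(0.0, 2.0 * np.pi, n_theta)
    tab = np.zeros((n_zeta, n_theta, 4, 4))
    crow = np.zeros((n_zeta, 4))
    env = np.zeros(n_zeta)
    q_par = np.zeros(n_zeta)
    q_perp = np.zeros(n_zeta)
    for i, z in enumerate(zetas):
        tab[i] = cylinder_mueller(x, m, z, thetas)
        for j in range(4):
            crow[i, j] = np.trapezoid(tab[i, :, 0, j], thetas)
        env[i] = float(
            np.max(tab[i, :, 0, 0] + np.linalg.norm(tab[i, :, 0, 1:], axis=1))
        )
        q_par[i], q_perp[i] = cylinder_efficiencies(x, m, z)
    qbar_normal = 0.5 * (q_par[-1] + q_perp[-1])
    if qbar_normal > 0.0:
        ext_par = q_par / qbar_normal
        ext_perp = q_perp / qbar_normal
    else:  # index matched: no extinction correction
        ext_par = np.ones(n_zeta)
        ext_perp = np.ones(n_zeta)
    if np.all(env <= 0.0):
        env[:] = 1.0
        crow[:, 0] = 1.0
    return CylinderTables(
        x=x,
        m=m,
        zeta0=ZETA_MIN,
        dzeta=float(zetas[1] - zetas[0]),
        mueller=tab,
        crow=crow,
        env=env,
        ext_par=ext_par,
        ext_perp=ext_perp,
    )


def sample_sphere_angles(stokes, x: float, m: float, rng, n: int = 1):
    """Draw ``n`` polarized (theta, phi) pairs for sphere scattering.

    ``stokes`` is the incident Stokes vector (any positive s0); ``rng``
    a ``numpy.random.Generator``.  Returns arrays (theta, phi).
    """
    S = np.asarray(stokes, dtype=float)
    if S[0] <= 0.0:
        raise ValueError("incident Stokes vector must have s0 > 0")
    t = build_sphere_tables(x, m)
    q, uu = S[1] / S[0], S[2] / S[0]
    thetas = np.empty(n)
    phis = np.empty(n)
    for i in range(n):
        th, ph, err = _kernel._sample_sphere_angles(
            rng, q, uu, t.s11, t.s12, t.pmax, t.n_theta
        )
        if err != _kernel.ERR_OK:
            raise EnvelopeError("sphere phase-function envelope violated")
        thetas[i] = th
        phis[i] = ph
    return thetas, phis


def sample_cylinder_angles(stokes, x: float, m: float, zeta: float, rng, n: int = 1):
    """Draw ``n`` azimuths Theta on the zeta-cone for cylinder scattering.

    The Stokes vector must be referenced to the incidence plane (the
    plane containing the propagation direction and the cylinder axis).
    """
    if not 0.0 < zeta <= np.pi / 2.0 + 1e-12:
        raise ValueError(f"zeta must be in (0, pi/2], got {zeta}")
    S = np.asarray(stokes, dtype=float)
    if S[0] <= 0.0:
        raise ValueError("incident Stokes vector must have s0 > 0")
    t = build_cylinder_tables(x, m)
    out = np.empty(n)
    for i in range(n):
        th, err = _kernel._sample_cylinder_theta(
            rng, S, max(zeta, t.zeta0), t.zeta0, t.dzeta, t.mueller, t.env
        )
        if err != _kernel.ERR_OK:
            raise EnvelopeError("cylinder phase-function envelope violated")
        out[i] = th
    return out
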