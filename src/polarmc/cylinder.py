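"""Scattering by an infinitely long circular cylinder at oblique incidence.

Partial-wave solution for a homogeneous cylinder of size parameter
``x = 2 pi R n_host / lambda`` and relative index ``m``, illuminated at
angle ``zeta`` between the incident direction and the cylinder axis
(``zeta = pi/2`` is normal incidence).  The scattered direction is
constrained to the cone making the same angle ``zeta`` with the axis
and is parameterized by the azimuth ``Theta`` around the axis, with
``Theta = 0`` the forward direction.

The four complex amplitudes (T1, T2, T3, T4) form the amplitude matrix

    [E_par_s ]   [T1 T4] [E_par_i ]
    [E_perp_s] ~ [T3 T2] [E_perp_i]

where "parallel" is the plane containing the propagation direction and
the cylinder axis.  At normal incidence the cross-polar amplitudes
T3, T4 vanish identically.
"""

from __future__ import annotations

import numpy as np
from scipy.special import h1vp, hankel1, jv, jvp

from .mie import mueller_from_jones, series_order

__all__ = [
    "cylinder_coefficients",
    "cylinder_amplitudes",
    "cylinder_mueller",
    "cylinder_efficiencies",
]


def cylinder_coefficients(x: float, m: float, zeta: float):
    """Partial-wave coefficients (aI, bI, aII, bII), orders n = 0..N.

    Case I is incident E parallel to the (direction, axis) plane, case
    II perpendicular.  ``zeta`` must satisfy ``0 < zeta <= pi/2``
    (grazing incidence along the axis has no scattering solution).
    """
    if x <= 0.0:
        raise ValueError(f"size parameter must be positive, got {x}")
    if not 0.0 < zeta <= np.pi / 2.0 + 1e-12:
        raise ValueError(f"incidence angle zeta must be in (0, pi/2], got {zeta}")
    n_stop = series_order(x)
    n = np.arange(0, n_stop + 1)
    cz = np.cos(zeta)
    xi = x * np.sin(zeta)
    eta = x * np.sqrt(m**2 - cz**2 + 0j)
    Jx, Jxp = jv(n, xi), jvp(n, xi)
    Hx, Hxp = hankel1(n, xi), h1vp(n, xi)
    Je, Jep = jv(n, eta), jvp(n, eta)
    A = 1j * xi * (xi * Jep * Jx - eta * Je * Jxp)
    B = xi * (m**2 * xi * Jep * Jx - eta * Je * Jxp)
    C = n * cz * eta * Je * Jx * (xi**2 / eta**2 - 1.0)
    D = n * cz * eta * Je * Hx * (xi**2 / eta**2 - 1.0)
    V = xi * (m**2 * xi * Jep * Hx - eta * Je * Hxp)
    W = 1j * xi * (eta * Je * Hxp - xi * Jep * Hx)
    den = W * V + 1j * D**2
    aI = (C * V - B * D) / den
    bI = (W * B + 1j * D * C) / den
    aII = -(A * V - 1j * C * D) / den
    bII = -1j * (C * W + A * D) / den
    return aI, bI, aII, bII


def cylinder_amplitudes(x: float, m: float, zeta: float, Theta):
    """Complex amplitudes T1..T4 at scattering azimuth(s) ``Theta``.

    T1 and T2 are the co-polar amplitudes (even in Theta), T3 and T4
    the cross-polar ones (odd in Theta).  For ``m == 1`` all four
    vanish (no optical contrast).
    """
    Theta = np.atleast_1d(np.asarray(Theta, dtype=float))
    if m == 1.0:
        z = np.zeros(Theta.shape, dtype=complex)
        return z, z.copy(), z.copy(), z.copy()
    aI, bI, aII, bII = cylinder_coefficients(x, m, zeta)
    n = np.arange(1, aI.size)
    cosn = np.cos(np.outer(n, Theta))
    sinn = np.sin(np.outer(n, Theta))
    T1 = bI[0] + 2.0 * np.einsum("n,nt->t", bI[1:], cosn)
    T2 = aII[0] + 2.0 * np.einsum("n,nt->t", aII[1:], cosn)
    T3 = -2j * np.einsum("n,nt->t", aI[1:], sinn)
    T4 = -2j * np.einsum("n,nt->t", bII[1:], sinn)
    return T1, T2, T3, T4


def cylinder_mueller(x: float, m: float, zeta: float, Theta) -> np.ndarray:
    """Unnormalized single-scattering Mueller matrices on the zeta-cone.

    Shape (len(Theta), 4, 4); acts on Stokes vectors referenced to the
    (parallel, perpendicular) basis of the incidence/scattering planes.
    """
    T1, T2, T3, T4 = cylinder_amplitudes(x, m, zeta, Theta)
    out = np.zeros((np.atleast_1d(T1).size, 4, 4))
    for i, (t1, t2, t3, t4) in enumerate(
        zip(np.atleast_1d(T1), np.atleast_1d(T2), np.atleast_1d(T3), np.atleast_1d(T4))
    ):
        out[i] = mueller_from_jones(np.array([[t1, t4], [t3, t2]]))
    return out


def cylinder_efficiencies(x: float, m: float, zeta: float) -> tuple[float, float]:
    """Scattering efficiencies (QI, QII) per unit length on the cone.

    Defined so that the azimuthal quadrature of the scattered intensity
    closes against the series sum:
    ``integral |T1|^2 + |T3|^2 dTheta = pi * x * QI`` (and likewise for
    case II with T2, T4).
    """
    aI, bI, aII, bII = cylinder_coefficients(x, m, zeta)
    qI = (2.0 / x) * (np.abs(bI[0]) ** 2 + 2.0 * np.sum(np.abs(bI[1:]) ** 2 + np.abs(aI[1:]) ** 2))
    qII = (2.0 / x) * (np.abs(aII[0]) ** 2 + 2.0 * np.sum(np.abs(aII[1:]) ** 2 + np.abs(bII[1:]) ** 2))
    return float(qI), float(qII)
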