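"""Mie theory for homogeneous spheres.

Scattering amplitudes S1, S2 and efficiencies from the partial-wave
series, with the logarithmic-derivative downward recurrence for the
internal coefficients.  The series is truncated at the standard
Wiscombe-type order ``ceil(x + 4 x^(1/3) + 2)``.

Amplitude convention: the 2x2 amplitude matrix ``diag(S2, S1)`` acts on
the (parallel, perpendicular) field components referenced to the
scattering plane; ``S1 = S2`` at exact forward scattering.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "mie_ab",
    "mie_amplitudes",
    "mie_efficiency",
    "mie_cross_section",
    "single_scatter_mueller",
    "mueller_from_jones",
    "series_order",
]

# Stokes <-> coherency change of basis: S = A c, c = (E1E1*, E1E2*, E2E1*, E2E2*)
_A = np.array(
    [
        [1, 0, 0, 1],
        [1, 0, 0, -1],
        [0, 1, 1, 0],
        [0, 1j, -1j, 0],
    ],
    dtype=complex,
)
_AINV = np.linalg.inv(_A)


def series_order(x: float) -> int:
    """Truncation order of the partial-wave series for size parameter x."""
    return int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))


def mie_ab(x: float, m: float) -> tuple[np.ndarray, np.ndarray]:
    """Mie coefficients a_n, b_n for n = 1..N.

    ``x`` is the (host-relative) size parameter 2*pi*R*n_host/lambda and
    ``m`` the relative refractive index of the sphere.  Uses downward
    recurrence for the logarithmic derivative D_n(mx) and upward
    recurrence for the Riccati-Bessel functions of ``x``.
    """
    if x <= 0.0:
        raise ValueError(f"size parameter must be positive, got {x}")
    n_stop = series_order(x)
    mx = m * x
    # downward recurrence for D_n(mx), started well above n_stop
    n_mx = int(max(n_stop, np.ceil(abs(mx)))) + 16
    D = np.zeros(n_mx + 1, dtype=complex)
    for n in range(n_mx, 0, -1):
        D[n - 1] = n / mx - 1.0 / (D[n] + n / mx)
    # Riccati-Bessel psi_n(x), chi_n(x) by upward recurrence
    ns = np.arange(1, n_stop + 1)
    psi = np.zeros(n_stop + 1)
    chi = np.zeros(n_stop + 1)
    psi_m1, psi_0 = np.cos(x), np.sin(x)  # psi_{-1}, psi_0
    chi_m1, chi_0 = -np.sin(x), np.cos(x)
    psi[0], chi[0] = psi_0, chi_0
    pm2, pm1 = psi_m1, psi_0
    cm2, cm1 = chi_m1, chi_0
    for n in range(1, n_stop + 1):
        pn = (2 * n - 1) / x * pm1 - pm2
        cn = (2 * n - 1) / x * cm1 - cm2
        psi[n], chi[n] = pn, cn
        pm2, pm1 = pm1, pn
        cm2, cm1 = cm1, cn
    xi = psi - 1j * chi
    Dn = D[1 : n_stop + 1]
    psi_n, psi_nm1 = psi[1:], psi[:-1]
    xi_n, xi_nm1 = xi[1:], xi[:-1]
    ta = Dn / m + ns / x
    tb = Dn * m + ns / x
    a = (ta * psi_n - psi_nm1) / (ta * xi_n - xi_nm1)
    b = (tb * psi_n - psi_nm1) / (tb * xi_n - xi_nm1)
    return a, b


def _pi_tau(theta: np.ndarray, n_stop: int) -> tuple[np.ndarray, np.ndarray]:
    """Angular functions pi_n, tau_n for n=1..n_stop; shape (n_stop, len(theta))."""
    mu = np.cos(np.atleast_1d(theta).astype(float))
    pi_arr = np.zeros((n_stop + 1, mu.size))
    tau = np.zeros((n_stop + 1, mu.size))
    pi_arr[1] = 1.0
    tau[1] = mu
    for n in range(2, n_stop + 1):
        pi_arr[n] = ((2 * n - 1) * mu * pi_arr[n - 1] - n * pi_arr[n - 2]) / (n - 1)
        tau[n] = n * mu * pi_arr[n] - (n + 1) * pi_arr[n - 1]
    return pi_arr[1:], tau[1:]


def mie_amplitudes(x: float, m: float, theta) -> tuple[np.ndarray, np.ndarray]:
    """Complex scattering amplitudes S1(theta), S2(theta).

    ``theta`` is the scattering angle in radians (scalar or array).
    For an optically matched sphere (``m == 1``) both amplitudes vanish.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    if m == 1.0:
        z = np.zeros(theta.shape, dtype=complex)
        return (z if theta.size > 1 else z[0], z.copy() if theta.size > 1 else z[0])
    a, b = mie_ab(x, m)
    n_stop = a.size
    pi_n, tau_n = _pi_tau(theta, n_stop)
    ns = np.arange(1, n_stop + 1)
    w = (2 * ns + 1) / (ns * (ns + 1))
    S1 = np.einsum("n,nt->t", w * a, pi_n) + np.einsum("n,nt->t", w * b, tau_n)
    S2 = np.einsum("n,nt->t", w * a, tau_n) + np.einsum("n,nt->t", w * b, pi_n)
    if S1.size == 1:
        return S1[0], S2[0]
    return S1, S2


def mie_efficiency(x: float, m: float) -> float:
    """Scattering efficiency Qsca = (2/x^2) sum (2n+1)(|a_n|^2+|b_n|^2)."""
    if m == 1.0:
        return 0.0
    a, b = mie_ab(x, m)
    ns = np.arange(1, a.size + 1)
    return float(2.0 / x**2 * np.sum((2 * ns + 1) * (np.abs(a) ** 2 + np.abs(b) ** 2)))


def mie_cross_section(x: float, m: float, wavelength_um: float, n_host: float) -> tuple[float, float]:
    """Scattering cross-section (um^2) and efficiency Qsca of a sphere.

    The geometric radius is recovered from the size parameter as
    ``R = x * lambda / (2 pi n_host)``.
    """
    q = mie_efficiency(x, m)
    radius = x * wavelength_um / (2.0 * np.pi * n_host)
    return q * np.pi * radius**2, q


def mueller_from_jones(J: np.ndarray) -> np.ndarray:
    """Mueller matrix of a deterministic 2x2 amplitude (Jones-like) matrix.

    ``J`` acts on the (parallel, perpendicular) field components of the
    local basis; the result acts on Stokes vectors in the same basis.
    """
    J = np.asarray(J, dtype=complex)
    M = _A @ np.kron(J, J.conj()) @ _AINV
    return np.real(M)


def single_scatter_mueller(x: float, m: float, theta) -> np.ndarray:
    """Single-scattering Mueller matrix (unnormalized) at angle(s) theta.

    Block structure with S22=S11, S44=S33, S43=-S34; built from
    |S1|^2, |S2|^2 and Re/Im(S2 S1*).  Shape (4,4) for scalar theta,
    else (len(theta), 4, 4).
    """
    S1, S2 = mie_amplitudes(x, m, theta)
    S1 = np.atleast_1d(S1)
    S2 = np.atleast_1d(S2)
    s11 = 0.5 * (np.abs(S2) ** 2 + np.abs(S1) ** 2)
    s12 = 0.5 * (np.abs(S2) ** 2 - np.abs(S1) ** 2)
    cross = S2 * np.conj(S1)
    s33 = np.real(cross)
    s34 = np.imag(cross)
    out = np.zeros((S1.size, 4, 4))
    out[:, 0, 0] = out[:, 1, 1] = s11
    out[:, 0, 1] = out[:, 1, 0] = s12
    out[:, 2, 2] = out[:, 3, 3] = s33
    out[:, 2, 3] = s34
    out[:, 3, 2] = -s34
    if out.shape[0] == 1 and np.isscalar(theta):
        return out[0]
    return out
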