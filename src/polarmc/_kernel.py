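"""Numba transport kernel and rejection samplers.

Everything here operates on plain float64 arrays so that the same
compiled routines serve both the public sampling API and the photon
transport loop.  Stokes vectors are referenced to a tracked local frame
``(v, w)`` orthogonal to the propagation direction ``u`` (meridian /
scattering-plane bookkeeping): after each scattering event the frame is
rotated so that ``v`` lies in the last scattering plane, which makes
the single-scattering Mueller matrix directly applicable and avoids a
second meridian rotation.

Sign conventions match :mod:`polarmc.mueller` exactly: rotating an
optical element by ``alpha`` is ``R(alpha) M R(-alpha)`` with the
block-rotation matrix of that module, and rotating the local frame by
``phi`` about ``u`` transforms the Stokes vector by ``R(-phi)``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# photon classification indices in the tally array
TALLY_DETECTED = 0
TALLY_UNDETECTED = 1
TALLY_REFLECTED = 2
TALLY_LOST = 3

ERR_OK = 0
ERR_ENVELOPE = 1

#: multiplicative safety factor applied to tabulated rejection envelopes
ENVELOPE_SAFETY = 1.05


@njit(cache=True)
def _rot_stokes(S, alpha):
    """In-place S <- R(alpha) S with the Eq.-style block rotation."""
    c = np.cos(2.0 * alpha)
    s = np.sin(2.0 * alpha)
    s1 = c * S[1] - s * S[2]
    s2 = s * S[1] + c * S[2]
    S[1] = s1
    S[2] = s2


@njit(cache=True)
def _apply_retarder(S, delta, beta):
    """In-place application of a linear retarder (retardance delta,
    fast axis at angle beta from the local v axis)."""
    _rot_stokes(S, -beta)
    c = np.cos(delta)
    s = np.sin(delta)
    s2 = c * S[2] + s * S[3]
    s3 = -s * S[2] + c * S[3]
    S[2] = s2
    S[3] = s3
    _rot_stokes(S, beta)


@njit(cache=True)
def _interp1(grid0, dgrid, arr, xval):
    """Linear interpolation on a uniform grid with edge clamping."""
    f = (xval - grid0) / dgrid
    n = arr.shape[0]
    if f <= 0.0:
        return arr[0]
    if f >= n - 1:
        return arr[n - 1]
    i = int(f)
    t = f - i
    return (1.0 - t) * arr[i] + t * arr[i + 1]


@njit(cache=True)
def _sample_sphere_angles(rng, q, uu, s11, s12, pmax, n_theta):
    """Rejection-sample (theta, phi) from the polarized Mie phase function.

    ``q``, ``uu`` are the normalized s1, s2 of the incident Stokes
    vector; ``s11``, ``s12`` are tabulated on a uniform theta grid over
    [0, pi] with ``n_theta`` points.  Returns (theta, phi, err).
    """
    dth = np.pi / (n_theta - 1)
    env = pmax * ENVELOPE_SAFETY
    for _ in range(10000):
        costh = 1.0 - 2.0 * rng.random()
        theta = np.arccos(costh)
        phi = 2.0 * np.pi * rng.random()
        a11 = _interp1(0.0, dth, s11, theta)
        a12 = _interp1(0.0, dth, s12, theta)
        p = a11 + a12 * (q * np.cos(2.0 * phi) + uu * np.sin(2.0 * phi))
        if p > env:
            return theta, phi, ERR_ENVELOPE
        if rng.random() * env < p:
            return theta, phi, ERR_OK
    return 0.0, 0.0, ERR_OK  # pragma: no cover - astronomically unlikely


@njit(cache=True)
def _cyl_row(zeta, zeta0, dzeta, nz):
    """Row index and weight for a cylinder-table lookup at angle zeta."""
    f = (zeta - zeta0) / dzeta
    if f <= 0.0:
        return 0, 0.0
    if f >= nz - 1:
        return nz - 2, 1.0
    i = int(f)
    return i, f - i


@njit(cache=True)
def _sample_cylinder_theta(rng, S, zeta, zeta0, dzeta, Mtab, env):
    """Rejection-sample the azimuth Theta on the zeta-cone.

    ``Mtab`` has shape (nz, nt, 4, 4) on uniform (zeta, Theta) grids
    (Theta over [0, 2 pi]); ``env`` is the per-row envelope of the
    polarized phase function.  Returns (Theta, err).
    """
    nz = Mtab.shape[0]
    nt = Mtab.shape[1]
    dth = 2.0 * np.pi / (nt - 1)
    iz, wz = _cyl_row(zeta, zeta0, dzeta, nz)
    e = env[iz]
    if env[iz + 1] > e:
        e = env[iz + 1]
    e *= ENVELOPE_SAFETY
    s0 = S[0]
    for _ in range(10000):
        th = 2.0 * np.pi * rng.random()
        ft = th / dth
        it = int(ft)
        if it >= nt - 1:
            it = nt - 2
        tt = ft - it
        p = 0.0
        for j in range(4):
            mj = (
                (1.0 - wz) * ((1.0 - tt) * Mtab[iz, it, 0, j] + tt * Mtab[iz, it + 1, 0, j])
                + wz * ((1.0 - tt) * Mtab[iz + 1, it, 0, j] + tt * Mtab[iz + 1, it + 1, 0, j])
            )
            p += mj * S[j] / s0
        if p > e:
            return th, ERR_ENVELOPE
        if rng.random() * e < p:
            return th, ERR_OK
    return 0.0, ERR_OK  # pragma: no cover


@njit(cache=True)
def _norm3(a):
    n = np.sqrt(a[0] ** 2 + a[1] ** 2 + a[2] ** 2)
    a[0] /= n
    a[1] /= n
    a[2] /= n


@njit(cache=True)
def _cross(a, b, out):
    out[0] = a[1] * b[2] - a[2] * b[1]
    out[1] = a[2] * b[0] - a[0] * b[2]
    out[2] = a[0] * b[1] - a[1] * b[0]


@njit(cache=True)
def _dot(a, b):
    return a[0] * b[0] + a[1] * b[1] + a[2] * b[2]


@njit(cache=True)
def _apply_cyl_extinction(S, u, v, w, axis, zeta0, dzeta, ext_par, ext_perp, mu_c, step, vt):
    """Polarized extinction correction for a suspension of aligned cylinders.

    Free paths are sampled at the unpolarized normal-incidence rate
    ``mu_c``; the true extinction rates for field components parallel
    and perpendicular to the (direction, axis) plane are
    ``mu_c * ext_par(zeta)`` and ``mu_c * ext_perp(zeta)``.  The
    residual is a linear diattenuator with axis along the transverse
    projection of the cylinder axis, applied over the segment length
    (the coherent differential phase is deliberately not applied: the
    host's intrinsic birefringence stands in for form birefringence in
    this model family).
    """
    ca = _dot(u, axis)
    if ca < 0.0:
        ca = -ca
    if ca > 1.0:
        ca = 1.0
    zeta = np.arccos(ca)
    if zeta < zeta0:
        zeta = zeta0
    nz = ext_par.shape[0]
    iz, wz = _cyl_row(zeta, zeta0, dzeta, nz)
    e1 = (1.0 - wz) * ext_par[iz] + wz * ext_par[iz + 1]
    e2 = (1.0 - wz) * ext_perp[iz] + wz * ext_perp[iz + 1]
    A = np.exp(-(e1 - 1.0) * mu_c * step)
    B = np.exp(-(e2 - 1.0) * mu_c * step)
    # transverse projection of the cylinder axis sets the diattenuator axis
    sign = 1.0 if _dot(u, axis) >= 0.0 else -1.0
    nvt = 0.0
    for k in range(3):
        vt[k] = sign * axis[k] - ca * u[k]
        nvt += vt[k] * vt[k]
    if nvt < 1.0e-18:
        return
    _norm3(vt)
    beta = np.arctan2(_dot(vt, w), _dot(vt, v))
    _rot_stokes(S, -beta)
    half_sum = 0.5 * (A + B)
    half_dif = 0.5 * (A - B)
    geo = np.sqrt(A * B)
    s0 = half_sum * S[0] + half_dif * S[1]
    s1 = half_dif * S[0] + half_sum * S[1]
    S[0] = s0
    S[1] = s1
    S[2] *= geo
    S[3] *= geo
    _rot_stokes(S, beta)


@njit(cache=True)
def _scatter_sphere(rng, u, v, w, S, s11t, s12t, s33t, s34t, pmax):
    """One sphere scattering event; updates u, v, w, S in place."""
    s0_old = S[0]
    q = S[1] / s0_old
    uu = S[2] / s0_old
    n_theta = s11t.shape[0]
    theta, phi, err = _sample_sphere_angles(rng, q, uu, s11t, s12t, pmax, n_theta)
    if err != ERR_OK:
        return err
    # rotate frame by phi about u; Stokes by R(-phi)
    cf = np.cos(phi)
    sf = np.sin(phi)
    v1x = cf * v[0] + sf * w[0]
    v1y = cf * v[1] + sf * w[1]
    v1z = cf * v[2] + sf * w[2]
    w1x = -sf * v[0] + cf * w[0]
    w1y = -sf * v[1] + cf * w[1]
    w1z = -sf * v[2] + cf * w[2]
    _rot_stokes(S, -phi)
    # apply the single-scattering Mueller block at theta
    dth = np.pi / (n_theta - 1)
    a11 = _interp1(0.0, dth, s11t, theta)
    a12 = _interp1(0.0, dth, s12t, theta)
    a33 = _interp1(0.0, dth, s33t, theta)
    a34 = _interp1(0.0, dth, s34t, theta)
    t0 = a11 * S[0] + a12 * S[1]
    t1 = a12 * S[0] + a11 * S[1]
    t2 = a33 * S[2] + a34 * S[3]
    t3 = -a34 * S[2] + a33 * S[3]
    if t0 <= 0.0:
        return ERR_ENVELOPE  # accepted density must be positive
    scale = s0_old / t0
    S[0] = s0_old
    S[1] = t1 * scale
    S[2] = t2 * scale
    S[3] = t3 * scale
    # deflect direction by theta in the scattering plane
    ct = np.cos(theta)
    st = np.sin(theta)
    ux = ct * u[0] + st * v1x
    uy = ct * u[1] + st * v1y
    uz = ct * u[2] + st * v1z
    vx = ct * v1x - st * u[0]
    vy = ct * v1y - st * u[1]
    vz = ct * v1z - st * u[2]
    u[0], u[1], u[2] = ux, uy, uz
    _norm3(u)
    # re-orthogonalize v against u
    d = _dot(np.array([vx, vy, vz]), u)
    v[0] = vx - d * u[0]
    v[1] = vy - d * u[1]
    v[2] = vz - d * u[2]
    _norm3(v)
    _cross(u, v, w)
    return ERR_OK


@njit(cache=True)
def _scatter_cylinder(rng, u, v, w, S, axis, zeta0, dzeta, Mtab, crow, env):
    """One cylinder scattering event; updates u, v, w, S in place.

    The exit direction stays exactly on the cone making the incidence
    angle with the cylinder axis.  The photon weight (s0) is multiplied
    by the ratio of the polarized to the unpolarized azimuth-integrated
    scattered power, which is the unbiased correction for sampling free
    paths with a polarization-averaged scattering coefficient.
    """
    ax = np.empty(3)
    ax[0], ax[1], ax[2] = axis[0], axis[1], axis[2]
    ca = _dot(u, ax)
    if ca < 0.0:
        ax[0], ax[1], ax[2] = -ax[0], -ax[1], -ax[2]
        ca = -ca
    if ca > 1.0:
        ca = 1.0
    sa = np.sqrt(1.0 - ca * ca)
    zeta = np.arccos(ca)
    if zeta < zeta0:
        zeta = zeta0
    # rotate the frame so v lies in the (u, axis) incidence plane
    vi = np.empty(3)
    if sa > 1.0e-9:
        for k in range(3):
            vi[k] = (ax[k] - ca * u[k]) / sa
    else:
        vi[0], vi[1], vi[2] = v[0], v[1], v[2]
    phi_r = np.arctan2(_dot(vi, w), _dot(vi, v))
    _rot_stokes(S, -phi_r)
    v[0], v[1], v[2] = vi[0], vi[1], vi[2]
    _cross(u, v, w)
    # sample the azimuth on the cone
    th, err = _sample_cylinder_theta(rng, S, zeta, zeta0, dzeta, Mtab, env)
    if err != ERR_OK:
        return err
    # polarized/unpolarized total-power ratio for the weight
    nz = Mtab.shape[0]
    iz, wz = _cyl_row(zeta, zeta0, dzeta, nz)
    c0 = (1.0 - wz) * crow[iz, 0] + wz * crow[iz + 1, 0]
    pol = c0 * S[0]
    for j in range(1, 4):
        cj = (1.0 - wz) * crow[iz, j] + wz * crow[iz + 1, j]
        pol += cj * S[j]
    # the sampled event rate is the unpolarized normal-incidence mu_c;
    # the true rate for this polarization and incidence angle is
    # proportional to pol, so the weight carries the ratio
    f = pol / (crow[nz - 1, 0] * S[0])
    if f < 1.0e-12:
        f = 1.0e-12
    # apply the full 4x4 tabulated Mueller matrix (bilinear)
    nt = Mtab.shape[1]
    dth = 2.0 * np.pi / (nt - 1)
    ft = th / dth
    it = int(ft)
    if it >= nt - 1:
        it = nt - 2
    tt = ft - it
    out = np.zeros(4)
    for i in range(4):
        acc = 0.0
        for j in range(4):
            mij = (
                (1.0 - wz) * ((1.0 - tt) * Mtab[iz, it, i, j] + tt * Mtab[iz, it + 1, i, j])
                + wz * ((1.0 - tt) * Mtab[iz + 1, it, i, j] + tt * Mtab[iz + 1, it + 1, i, j])
            )
            acc += mij * S[j]
        out[i] = acc
    if out[0] <= 0.0:
        return ERR_ENVELOPE
    target = S[0] * f
    scale = target / out[0]
    S[0] = target
    S[1] = out[1] * scale
    S[2] = out[2] * scale
    S[3] = out[3] * scale
    # new direction on the cone, azimuth th from the forward azimuth
    e1 = np.empty(3)
    if sa > 1.0e-9:
        for k in range(3):
            e1[k] = (u[k] - ca * ax[k]) / sa
    else:
        e1[0], e1[1], e1[2] = v[0], v[1], v[2]
    e2 = np.empty(3)
    _cross(ax, e1, e2)
    cth = np.cos(th)
    sth = np.sin(th)
    for k in range(3):
        u[k] = ca * ax[k] + sa * (cth * e1[k] + sth * e2[k])
    _norm3(u)
    # scattered parallel basis vector: in the (u', axis) plane
    ca2 = _dot(u, ax)
    nv = 0.0
    for k in range(3):
        v[k] = ax[k] - ca2 * u[k]
        nv += v[k] * v[k]
    if nv > 1.0e-18:
        _norm3(v)
    else:
        v[0], v[1], v[2] = e1[0], e1[1], e1[2]
    _cross(u, v, w)
    return ERR_OK


@njit(cache=True)
def _transport(
    rng,
    n_photons,
    S_in,
    d_um,
    mu_s,
    mu_c,
    wavelength_um,
    delta_n,
    n_o,
    optic_axis,
    cyl_axis,
    s11t,
    s12t,
    s33t,
    s34t,
    sph_pmax,
    zeta0,
    dzeta,
    Mtab,
    crow,
    env,
    ext_par,
    ext_perp,
    pixel_um,
    det_radius_um,
    accept_cos,
    lateral_half_um,
    max_events,
    img,
    counts,
    tallies,
):
    """Transport ``n_photons`` with input Stokes ``S_in`` through the slab.

    Accumulates detected Stokes vectors into ``img`` (shape
    (4, ny, nx)), per-pixel photon counts into ``counts``, and the
    four-way classification into ``tallies``.  Returns an error code
    (nonzero on a rejection-envelope violation).
    """
    ny = img.shape[1]
    nx = img.shape[2]
    half_x = 0.5 * nx * pixel_um
    half_y = 0.5 * ny * pixel_um
    mu_t = mu_s + mu_c
    two_pi = 2.0 * np.pi
    u = np.empty(3)
    v = np.empty(3)
    w = np.empty(3)
    S = np.empty(4)
    vt = np.empty(3)
    for _ in range(n_photons):
        x = 0.0
        y = 0.0
        z = 0.0
        u[0], u[1], u[2] = 0.0, 0.0, 1.0
        v[0], v[1], v[2] = 1.0, 0.0, 0.0
        w[0], w[1], w[2] = 0.0, 1.0, 0.0
        for k in range(4):
            S[k] = S_in[k]
        events = 0
        # outcome: 1 = exited top face, 2 = exited bottom face, 3 = lost
        outcome = 0
        while outcome == 0:
            if mu_t > 0.0:
                step = -np.log(1.0 - rng.random()) / mu_t
            else:
                step = 1.0e30
            # distance to a slab face along u
            if u[2] > 1.0e-12:
                t_b = (d_um - z) / u[2]
                top = True
            elif u[2] < -1.0e-12:
                t_b = -z / u[2]
                top = False
            else:
                t_b = 1.0e30
                top = False
            if step >= t_b:
                step = t_b
                leave = True
            else:
                leave = False
            # birefringent host acts as a continuous retarder per segment
            if delta_n > 0.0 and step > 0.0:
                cth = _dot(u, optic_axis)
                s2 = 1.0 - cth * cth
                if s2 > 1.0e-14:
                    inv_ne2 = cth * cth / (n_o * n_o) + s2 / ((n_o + delta_n) ** 2)
                    ne_eff = 1.0 / np.sqrt(inv_ne2)
                    delta = two_pi / wavelength_um * (ne_eff - n_o) * step
                    # fast-axis azimuth: transverse projection of the optic axis
                    nvt = 0.0
                    for k in range(3):
                        vt[k] = optic_axis[k] - cth * u[k]
                        nvt += vt[k] * vt[k]
                    if nvt > 1.0e-18:
                        _norm3(vt)
                        beta = np.arctan2(_dot(vt, w), _dot(vt, v))
                        _apply_retarder(S, delta, beta)
            if mu_c > 0.0 and step > 0.0:
                _apply_cyl_extinction(
                    S, u, v, w, cyl_axis, zeta0, dzeta, ext_par, ext_perp, mu_c, step, vt
                )
            x += step * u[0]
            y += step * u[1]
            z += step * u[2]
            if leave:
                outcome = 1 if top else 2
                break
            if x > lateral_half_um or x < -lateral_half_um or y > lateral_half_um or y < -lateral_half_um:
                outcome = 3
                break
            events += 1
            if events > max_events:
                outcome = 3
                break
            if mu_s > 0.0 and rng.random() * mu_t < mu_s:
                err = _scatter_sphere(rng, u, v, w, S, s11t, s12t, s33t, s34t, sph_pmax)
            else:
                err = _scatter_cylinder(rng, u, v, w, S, cyl_axis, zeta0, dzeta, Mtab, crow, env)
            if err != ERR_OK:
                return err
        if outcome == 2:
            tallies[TALLY_REFLECTED] += 1
            continue
        if outcome == 3:
            tallies[TALLY_LOST] += 1
            continue
        if u[2] < accept_cos:
            # outside the angular acceptance of the detection optics
            tallies[TALLY_UNDETECTED] += 1
            continue
        # laboratory-frame Stokes: project the transverse field onto the
        # detector (x, y) plane.  With J = [[v.x, w.x], [v.y, w.y]] the
        # coherency matrix maps as C -> J C J^T (J real), which gives the
        # closed form below; this is exactly x<->y mirror equivariant and
        # reduces to the identity at normal exit.
        j00 = v[0]
        j01 = w[0]
        j10 = v[1]
        j11 = w[1]
        r00 = 0.5 * (S[0] + S[1])
        r01 = 0.5 * S[2]
        r11 = 0.5 * (S[0] - S[1])
        rp00 = j00 * (j00 * r00 + j01 * r01) + j01 * (j00 * r01 + j01 * r11)
        rp01 = j10 * (j00 * r00 + j01 * r01) + j11 * (j00 * r01 + j01 * r11)
        rp11 = j10 * (j10 * r00 + j11 * r01) + j11 * (j10 * r01 + j11 * r11)
        detj = j00 * j11 - j01 * j10
        S[0] = rp00 + rp11
        S[1] = rp00 - rp11
        S[2] = 2.0 * rp01
        S[3] = detj * S[3]
        r = np.sqrt(x * x + y * y)
        if r <= det_radius_um:
            tallies[TALLY_DETECTED] += 1
        else:
            tallies[TALLY_UNDETECTED] += 1
        ix = int((x + half_x) / pixel_um)
        iy = int((y + half_y) / pixel_um)
        if 0 <= ix < nx and 0 <= iy < ny:
            for k in range(4):
                img[k, iy, ix] += S[k]
            counts[iy, ix] += 1
    return ERR_OK
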