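"""Stokes/Mueller algebra and closed-form optical elements.

Conventions used throughout the package
---------------------------------------
A Stokes vector is a length-4 float array ``(s0, s1, s2, s3)``:

* ``s0`` — total intensity (non-negative),
* ``s1`` — horizontal minus vertical linear polarization, with
  "horizontal" the laboratory X axis,
* ``s2`` — +45 deg minus −45 deg linear polarization,
* ``s3`` — right minus left circular polarization (right-circular
  positive; every rotation invariant computed here is insensitive to
  this handedness choice).

A Mueller matrix is a real 4x4 array; element ``m11`` (index ``[0, 0]``)
carries the total transmittance scale.  In-plane rotation of the sample
by azimuth ``alpha`` acts as ``M' = R(alpha) M R(-alpha)`` with the
block-rotation matrix ``R`` whose inner 2x2 block rotates ``(s1, s2)``
by ``2*alpha``.  Positive ``alpha`` rotates the sample counterclockwise
viewed against the beam; every derived quantity is pi-periodic in
``alpha``.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

__all__ = [
    "G_METRIC",
    "DegenerateMatrixError",
    "stokes",
    "is_physical_stokes",
    "rotation_matrix",
    "rotate_mueller",
    "normalize",
    "make_retarder",
    "make_diattenuator",
    "make_depolarizer",
    "random_physical_mueller",
]

#: Minkowski-like metric of Stokes space used by the G-symmetry split.
G_METRIC = np.diag([1.0, -1.0, -1.0, -1.0])


class DegenerateMatrixError(ValueError):
    """Raised for Mueller matrices with non-positive transmittance m11."""


def stokes(s0: float, s1: float = 0.0, s2: float = 0.0, s3: float = 0.0) -> np.ndarray:
    """Build a Stokes vector as a float array."""
    return np.array([s0, s1, s2, s3], dtype=float)


def is_physical_stokes(s: np.ndarray, tol: float = 1e-9) -> bool:
    """Check s0 >= 0 and s1^2 + s2^2 + s3^2 <= s0^2 within ``tol``."""
    s = np.asarray(s, dtype=float)
    return bool(s[0] >= -tol and s[1] ** 2 + s[2] ** 2 + s[3] ** 2 <= s[0] ** 2 + tol)


def rotation_matrix(alpha: float) -> np.ndarray:
    """Mueller rotation matrix R(alpha) for in-plane sample rotation.

    Entries: (2,2)=(3,3)=cos 2a, (2,3)=-sin 2a, (3,2)=sin 2a,
    (1,1)=(4,4)=1 (1-based indexing).  ``R(alpha) @ R(-alpha)`` is the
    identity, and ``R`` is pi-periodic in ``alpha``.
    """
    c, s = np.cos(2.0 * alpha), np.sin(2.0 * alpha)
    return np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, c, -s, 0.0],
            [0.0, s, c, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def rotate_mueller(M: np.ndarray, alpha: float) -> np.ndarray:
    """Return ``R(alpha) @ M @ R(-alpha)``, the rotated-sample matrix."""
    R = rotation_matrix(alpha)
    Rm = rotation_matrix(-alpha)
    return R @ np.asarray(M, dtype=float) @ Rm


def normalize(M: np.ndarray) -> np.ndarray:
    """Divide all 16 entries by m11 so the output has unit transmittance.

    Raises
    ------
    DegenerateMatrixError
        If ``m11 <= 0`` (no transmitted intensity to normalize by).
    """
    M = np.asarray(M, dtype=float)
    m11 = M[0, 0]
    if m11 <= 0.0:
        raise DegenerateMatrixError(f"cannot normalize Mueller matrix with m11={m11!r}")
    return M / m11


def make_retarder(delta: float, theta: float = 0.0) -> np.ndarray:
    """Linear retarder of retardance ``delta`` (rad), fast axis at ``theta``.

    At ``theta = 0`` the matrix is the identity on ``(s0, s1)`` and a
    ``delta`` rotation on ``(s2, s3)``; a general axis is obtained via
    :func:`rotate_mueller`.
    """
    c, s = np.cos(delta), np.sin(delta)
    base = np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, c, s],
            [0.0, 0.0, -s, c],
        ]
    )
    if theta == 0.0:
        return base
    return rotate_mueller(base, theta)


def make_diattenuator(d_lin: float, theta: float = 0.0) -> np.ndarray:
    """Linear diattenuator parameterized by its logarithmic coefficient.

    Built as ``expm(L)`` where the only nonzero entries of the generator
    ``L`` are ``L12 = L21 = d_lin``, rotated to azimuth ``theta``.  The
    total linear dichroism DT of the result equals ``|d_lin|`` exactly
    by construction (the decomposition works in the logarithmic domain,
    so parameterizing the fixture there keeps the recovery exact).
    """
    L = np.zeros((4, 4))
    L[0, 1] = L[1, 0] = d_lin
    if theta != 0.0:
        L = rotate_mueller(L, theta)
    return expm(L)


def make_depolarizer(a22: float, a33: float, a44: float) -> np.ndarray:
    """Diagonal depolarizer ``diag(1, exp(a22), exp(a33), exp(a44))``.

    The arguments are the diagonal depolarization coefficients of the
    logarithmic decomposition and must be <= 0 (a passive depolarizer
    cannot amplify any polarized component).
    """
    for name, a in (("a22", a22), ("a33", a33), ("a44", a44)):
        if a > 0.0:
            raise ValueError(f"depolarizer coefficient {name}={a} must be <= 0")
    return np.diag([1.0, np.exp(a22), np.exp(a33), np.exp(a44)])


def random_physical_mueller(seed, bound: float = 0.5) -> np.ndarray:
    """Reproducible random Mueller matrix with a principal logarithm.

    The matrix is the exponential of a random generator whose entries
    are uniform in ``[-bound, bound]``; bounding the generator keeps the
    matrix invertible and its eigenvalues away from the negative real
    axis, so the principal matrix logarithm is always defined.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    L = rng.uniform(-bound, bound, size=(4, 4))
    return expm(L)
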