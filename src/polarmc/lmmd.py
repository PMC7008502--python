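"""Logarithmic Mueller matrix decomposition (LMMD).

The matrix logarithm ``L = ln M`` of a (normalized) Mueller matrix is
split into a polarization part ``Lm`` (G-antisymmetric) and a
depolarization part ``Lu`` (G-symmetric), where ``G = diag(1,-1,-1,-1)``:

    Lm = (L - G L^T G) / 2,      Lu = (L + G L^T G) / 2.

``Lm`` houses the elementary retardance and dichroism coefficients,
``Lu`` the depolarization coefficients.  The decomposition reported
here is cumulative over the slab (not per-unit-thickness).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import scipy.linalg

from .mueller import G_METRIC

__all__ = [
    "LogDecomposition",
    "LmmdCoefficients",
    "DecompositionError",
    "SingularMatrixError",
    "BranchError",
    "matrix_log",
    "g_split",
    "coefficients",
]

#: warning threshold on the imaginary residue discarded when realifying L
IMAG_WARN = 1e-6


class DecompositionError(ValueError):
    """Eigendecomposition of the Mueller matrix failed."""


class SingularMatrixError(DecompositionError):
    """Mueller matrix is (numerically) singular; no logarithm exists."""


class BranchError(DecompositionError):
    """An eigenvalue lies on the closed negative real axis.

    The principal matrix logarithm is undefined there; physically this
    corresponds to a total retardance of pi or more, which this package
    does not attempt to unwrap.
    """


@dataclass(frozen=True)
class LogDecomposition:
    """Matrix logarithm of a Mueller matrix and its G-symmetry split."""

    L: np.ndarray
    Lm: np.ndarray
    Lu: np.ndarray
    #: max absolute imaginary part discarded when realifying L
    imag_residual: float

    def to_record(self) -> dict:
        """Flat JSON-ready record (16-element row-major arrays)."""
        return {
            "L": self.L.reshape(16),
            "Lm": self.Lm.reshape(16),
            "Lu": self.Lu.reshape(16),
            "imag_residual": self.imag_residual,
        }


@dataclass(frozen=True)
class LmmdCoefficients:
    """Elementary LMMD coefficients.

    ``LB``/``LBp`` are linear retardance in the 0-90 deg and +-45 deg
    frameworks (rad), ``CB`` circular retardance; ``LD``/``LDp``/``CD``
    the corresponding dichroism coefficients (dimensionless); ``a22``,
    ``a33``, ``a44`` the diagonal depolarization coefficients
    (dimensionless, typically <= 0).  Sign convention: a pure retarder
    with fast axis at 0 and retardance ``delta`` yields ``LB = +delta``.
    """

    LB: float
    LBp: float
    CB: float
    LD: float
    LDp: float
    CD: float
    a22: float
    a33: float
    a44: float

    def to_record(self) -> dict:
        return asdict(self)


def g_split(L: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a real 4x4 generator into (Lm, Lu).

    ``Lm = (L - G L^T G)/2`` is G-antisymmetric (polarization part),
    ``Lu = (L + G L^T G)/2`` is G-symmetric (depolarization part), and
    ``Lm + Lu = L`` exactly.  Applying the split to ``Lm`` again returns
    ``(Lm, 0)`` (idempotence).
    """
    L = np.asarray(L, dtype=float)
    GLG = G_METRIC @ L.T @ G_METRIC
    return (L - GLG) / 2.0, (L + GLG) / 2.0


def matrix_log(M: np.ndarray, cond_limit: float = 1e8) -> LogDecomposition:
    """Principal matrix logarithm of a normalized Mueller matrix.

    Computed through the complex eigendecomposition
    ``L = U ln(diag(w)) U^-1``; complex-conjugate eigenvalue pairs
    combine to a real ``L`` up to numerical noise, whose maximum
    magnitude is recorded as ``imag_residual`` rather than silently
    dropped.  Matrices with (numerically) repeated eigenvalues fall back
    to a Schur-based logarithm; the contract is ``expm(L) == M``, not
    the algorithm used.

    Raises
    ------
    SingularMatrixError
        If an eigenvalue is numerically zero.
    BranchError
        If an eigenvalue lies on the closed negative real axis (the
        principal branch is undefined; retardance >= pi is not
        representable).
    """
    M = np.asarray(M, dtype=float)
    if M.shape != (4, 4):
        raise ValueError(f"expected a 4x4 matrix, got shape {M.shape}")
    w, U = np.linalg.eig(M)
    if np.any(np.abs(w) < 1e-14):
        raise SingularMatrixError("Mueller matrix is singular; logarithm undefined")
    on_negative_axis = (w.real < 0.0) & (np.abs(w.imag) <= 1e-12 * np.abs(w.real))
    if np.any(on_negative_axis):
        raise BranchError(
            "eigenvalue on the negative real axis: principal logarithm "
            f"undefined (eigenvalues {w})"
        )
    try:
        condU = np.linalg.cond(U)
    except np.linalg.LinAlgError:  # pragma: no cover - pathological input
        condU = np.inf
    if not np.isfinite(condU) or condU > cond_limit:
        # near-defective eigenvector basis: Schur-based fallback
        Lc = scipy.linalg.logm(M)
    else:
        Lc = U @ np.diag(np.log(w)) @ np.linalg.inv(U)
    imag_residual = float(np.max(np.abs(np.imag(Lc))))
    if imag_residual > IMAG_WARN:
        warnings.warn(
            f"matrix logarithm discarded an imaginary residue of "
            f"{imag_residual:.2e} (noisy or marginally non-physical input)",
            stacklevel=2,
        )
    L = np.real(Lc)
    Lm, Lu = g_split(L)
    return LogDecomposition(L=L, Lm=Lm, Lu=Lu, imag_residual=imag_residual)


def coefficients(dec: LogDecomposition) -> LmmdCoefficients:
    """Extract the elementary LMMD coefficients from a decomposition.

    ``LD=Lm12, LDp=Lm13, CD=Lm14, CB=Lm23, LB=Lm34, LBp=Lm42`` and
    ``a22=Lu22, a33=Lu33, a44=Lu44`` (1-based element names).
    """
    Lm, Lu = dec.Lm, dec.Lu
    return LmmdCoefficients(
        LB=float(Lm[2, 3]),
        LBp=float(Lm[3, 1]),
        CB=float(Lm[1, 2]),
        LD=float(Lm[0, 1]),
        LDp=float(Lm[0, 2]),
        CD=float(Lm[0, 3]),
        a22=float(Lu[1, 1]),
        a33=float(Lu[2, 2]),
        a44=float(Lu[3, 3]),
    )
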