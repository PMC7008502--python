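"""Rotation invariants of the logarithmic Mueller matrix decomposition.

In-plane rotation of a sample transforms the matrix logarithm exactly
as it transforms the Mueller matrix itself, so rotation invariants of
``L`` take the same form as the classical Mueller matrix invariants.
The seven invariants implemented here are

* ``RT``  — total linear retardance, sqrt(Lm24^2 + Lm34^2)        [rad]
* ``DT``  — total linear dichroism,  sqrt(Lm12^2 + Lm13^2)        [-]
* ``RC``  — circular retardance,     (L23 - L32)/2                [rad]
* ``DC``  — circular dichroism,      (L14 + L41)/2                [-]
* ``aL``  — isotropic linear depolarization, (L22 + L33)/2        [-]
* ``a44`` — circular depolarization, L44                          [-]
* ``aLA`` — anisotropic linear depolarization,
            0.5*sqrt((Lu22 - Lu33)^2 + (Lu23 + Lu32)^2)           [-]

``RT``, ``DT`` and ``aLA`` are reported unsigned (square-root
definitions); the corner elements L11, L14, L41, L44 are themselves
rotation invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import lmmd
from .mueller import normalize

__all__ = [
    "InvariantSet",
    "total_linear_retardance",
    "total_linear_dichroism",
    "circular_birefringence",
    "circular_dichroism",
    "isotropic_linear_depolarization",
    "circular_depolarization",
    "anisotropic_linear_depolarization",
    "invariant_set",
    "invariants_from_log",
    "write_invariants_tsv",
    "FIELD_NAMES",
]

FIELD_NAMES = ("RT", "DT", "RC", "DC", "aL", "a44", "aLA")


@dataclass(frozen=True)
class InvariantSet:
    """The seven rotation invariants of one Mueller matrix."""

    RT: float
    DT: float
    RC: float
    DC: float
    aL: float
    a44: float
    aLA: float
    #: imaginary residue discarded when realifying L (0 for direct L input)
    imag_residual: float = 0.0

    def to_record(self) -> dict:
        return asdict(self)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in FIELD_NAMES])


def total_linear_retardance(L: np.ndarray) -> float:
    """RT = 0.5*sqrt((L24-L42)^2 + (L34-L43)^2) >= 0, in radians."""
    L = np.asarray(L, dtype=float)
    return 0.5 * float(np.hypot(L[1, 3] - L[3, 1], L[2, 3] - L[3, 2]))


def total_linear_dichroism(L: np.ndarray) -> float:
    """DT = 0.5*sqrt((L12+L21)^2 + (L13+L31)^2) >= 0, dimensionless."""
    L = np.asarray(L, dtype=float)
    return 0.5 * float(np.hypot(L[0, 1] + L[1, 0], L[0, 2] + L[2, 0]))


def circular_birefringence(L: np.ndarray) -> float:
    """RC = (L23 - L32)/2, in radians."""
    L = np.asarray(L, dtype=float)
    return float(L[1, 2] - L[2, 1]) / 2.0


def circular_dichroism(L: np.ndarray) -> float:
    """DC = (L14 + L41)/2, dimensionless."""
    L = np.asarray(L, dtype=float)
    return float(L[0, 3] + L[3, 0]) / 2.0


def isotropic_linear_depolarization(L: np.ndarray) -> float:
    """aL = (L22 + L33)/2 — the isotropic linear depolarization."""
    L = np.asarray(L, dtype=float)
    return float(L[1, 1] + L[2, 2]) / 2.0


def circular_depolarization(L: np.ndarray) -> float:
    """a44 = L44 — the circular depolarization coefficient."""
    return float(np.asarray(L, dtype=float)[3, 3])


def anisotropic_linear_depolarization(dec) -> float:
    """aLA = 0.5*sqrt((a22-a33)^2 + (Lu23+Lu32)^2) >= 0.

    Accepts a :class:`~polarmc.lmmd.LogDecomposition` or a raw ``Lu``
    matrix.  This is the logarithmic-domain analogue of the
    degree-of-anisotropy parameter of Mueller matrix transformation
    theory, and is the marker for scattering on aligned non-spherical
    structures (form birefringence).
    """
    Lu = dec.Lu if isinstance(dec, lmmd.LogDecomposition) else np.asarray(dec, dtype=float)
    return 0.5 * float(np.hypot(Lu[1, 1] - Lu[2, 2], Lu[1, 2] + Lu[2, 1]))


def invariants_from_log(dec: lmmd.LogDecomposition) -> InvariantSet:
    """Assemble the seven invariants from an existing decomposition."""
    L = dec.L
    return InvariantSet(
        RT=total_linear_retardance(L),
        DT=total_linear_dichroism(L),
        RC=circular_birefringence(L),
        DC=circular_dichroism(L),
        aL=isotropic_linear_depolarization(L),
        a44=circular_depolarization(L),
        aLA=anisotropic_linear_depolarization(dec),
        imag_residual=dec.imag_residual,
    )


def invariant_set(M: np.ndarray) -> InvariantSet:
    """Normalize ``M``, take the matrix logarithm and return all seven
    rotation invariants.  Propagates the decomposition errors of
    :func:`polarmc.lmmd.matrix_log`."""
    dec = lmmd.matrix_log(normalize(M))
    return invariants_from_log(dec)


def write_invariants_tsv(path, matrices, ids=None) -> None:
    """Batch-decompose matrices and write one TSV row per input.

    Columns: id, RT, DT, RC, DC, aL, a44, aLA, imag_residual.
    """
    matrices = list(matrices)
    if ids is None:
        ids = list(range(len(matrices)))
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(FIELD_NAMES) + "\timag_residual\n")
        for label, M in zip(ids, matrices):
            inv = invariant_set(M)
            vals = "\t".join(f"{getattr(inv, k):.9g}" for k in FIELD_NAMES)
            fh.write(f"{label}\t{vals}\t{inv.imag_residual:.3g}\n")
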