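"""Polarized Monte Carlo transport through a scattering birefringent slab.

The slab occupies ``0 <= z <= d`` (thickness in micrometers) and hosts
monodisperse spherical and/or infinitely long cylindrical scatterers in
an isotropic or uniaxial linearly birefringent medium whose optic axis
lies in the slab plane.  A pencil beam enters at the origin at normal
incidence; photons random-walk until they exit (transmitted,
reflected) or are lost at the lateral bounds / event cap, and every
launched photon is classified exactly once.

The transmission Mueller matrix is assembled from four separate
polarized runs with input Stokes vectors H=(1,1,0,0), V=(1,-1,0,0),
P=(1,0,1,0) and R=(1,0,0,1): columns c1=(H+V)/2, c2=(H-V)/2, c3=P-c1,
c4=R-c1.  Trajectories are not reused across input states because the
rejection sampler conditions the angular density on each photon's
actual polarization.

Boundaries are index matched (no Fresnel reflection or refraction) and
the host is non-absorbing.  The birefringent host acts as a continuous
linear retarder along each straight flight segment with the
direction-dependent extraordinary index; ray splitting and walk-off are
neglected, which is justified for the small index contrasts
(delta_n <= 0.009) this model targets.
"""

from __future__ import annotations


from dataclasses import dataclass, asdict, replace

import numpy as np

from . import _kernel
from .invariants import invariant_set
from .lmmd import g_split, matrix_log
from .mueller import normalize
from .sampling import (
    EnvelopeError,
    build_cylinder_tables,
    build_sphere_tables,
)

__all__ = [
    "ModelConfig",
    "PhotonState",
    "MuellerImage",
    "SimulationResult",
    "UnderSamplingError",
    "free_path",
    "choose_scatterer",
    "apply_birefringence",
    "scatter",
    "run_simulation",
    "spatial_average",
    "mc_standard_error",
    "INPUT_STATES",
]

#: the four input Stokes states used to assemble the Mueller matrix
INPUT_STATES = {
    "H": np.array([1.0, 1.0, 0.0, 0.0]),
    "V": np.array([1.0, -1.0, 0.0, 0.0]),
    "P": np.array([1.0, 0.0, 1.0, 0.0]),
    "R": np.array([1.0, 0.0, 0.0, 1.0]),
}

CM_TO_UM = 1.0e-4  # 1 cm^-1 = 1e-4 um^-1


class UnderSamplingError(RuntimeError):
    """No photon reached the detector; increase the photon budget."""


def _unit(vec) -> np.ndarray:
    v = np.asarray(vec, dtype=float)
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("axis vector must be nonzero")
    return v / n


@dataclass
class ModelConfig:
    """Full parameterization of one slab transmission experiment.

    Lengths in micrometers, scattering coefficients in cm^-1 (converted
    internally), refractive indices dimensionless.  The extraordinary
    index of the host is ``n_host + delta_n``; both the optic axis and
    the cylinder axis default to the laboratory X axis (in plane).
    """

    thickness_um: float
    wavelength_um: float = 0.533
    mu_s_cm: float = 0.0
    mu_c_cm: float = 0.0
    radius_sphere_um: float = 0.05
    radius_cyl_um: float = 0.05
    n_sphere: float = 1.45
    n_cyl: float = 1.45
    n_host: float = 1.33
    delta_n: float = 0.0
    optic_axis: tuple = (1.0, 0.0, 0.0)
    cylinder_axis: tuple = (1.0, 0.0, 0.0)
    n_photons: int = 100_000
    seed: int = 1
    detector_diameter_um: float = 600.0
    #: half-angle of the angular acceptance cone at the exit face, in
    #: degrees; None accepts all forward exit angles
    accept_half_angle_deg: float | None = None
    pixel_um: float = 10.0
    grid_half_um: float = 400.0
    lateral_half_um: float = 3000.0
    n_batches: int = 10
    max_events: int = 100_000

    def __post_init__(self):
        if self.thickness_um <= 0:
            raise ValueError("thickness_um must be positive")
        if self.wavelength_um <= 0:
            raise ValueError("wavelength_um must be positive")
        if self.mu_s_cm < 0 or self.mu_c_cm < 0:
            raise ValueError("scattering coefficients must be >= 0")
        if self.delta_n < 0:
            raise ValueError("delta_n must be >= 0")
        self.optic_axis = tuple(float(c) for c in _unit(self.optic_axis))
        self.cylinder_axis = tuple(float(c) for c in _unit(self.cylinder_axis))
        for name in ("optic_axis", "cylinder_axis"):
            if abs(getattr(self, name)[2]) > 1e-9:
                raise ValueError(f"{name} must lie in the slab plane (z component 0)")

    # -- derived quantities -------------------------------------------------
    @property
    def mu_s_um(self) -> float:
        return self.mu_s_cm * CM_TO_UM

    @property
    def mu_c_um(self) -> float:
        return self.mu_c_cm * CM_TO_UM

    @property
    def x_sphere(self) -> float:
        return 2.0 * np.pi * self.radius_sphere_um * self.n_host / self.wavelength_um

    @property
    def x_cyl(self) -> float:
        return 2.0 * np.pi * self.radius_cyl_um * self.n_host / self.wavelength_um

    @property
    def m_sphere(self) -> float:
        return self.n_sphere / self.n_host

    @property
    def m_cyl(self) -> float:
        return self.n_cyl / self.n_host

    def to_dict(self) -> dict:
        d = asdict(self)
        d["optic_axis"] = list(self.optic_axis)
        d["cylinder_axis"] = list(self.cylinder_axis)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)

    def with_(self, **overrides) -> "ModelConfig":
        return replace(self, **overrides)


@dataclass
class PhotonState:
    """State of one Monte Carlo photon (used by the step-level API)."""

    position: np.ndarray
    direction: np.ndarray
    stokes: np.ndarray
    frame_v: np.ndarray
    alive: bool = True

    @classmethod
    def launch(cls, stokes_in) -> "PhotonState":
        return cls(
            position=np.zeros(3),
            direction=np.array([0.0, 0.0, 1.0]),
            stokes=np.asarray(stokes_in, dtype=float).copy(),
            frame_v=np.array([1.0, 0.0, 0.0]),
        )

    @property
    def frame_w(self) -> np.ndarray:
        return np.cross(self.direction, self.frame_v)


@dataclass
class MuellerImage:
    """Spatially resolved accumulated Mueller matrix at the exit face.

    ``elements[i, j]`` is the accumulated (not normalized) element map;
    ``counts`` the per-pixel detected-photon count summed over the four
    input states; ``pixel_um`` the physical pitch.  Pixel centers run
    from ``-extent + pixel/2`` to ``extent - pixel/2`` in both axes.
    """

    elements: np.ndarray  # (4, 4, ny, nx)
    counts: np.ndarray  # (ny, nx)
    pixel_um: float

    @property
    def extent_um(self) -> float:
        return 0.5 * self.elements.shape[-1] * self.pixel_um


@dataclass
class SimulationResult:
    """Output of :func:`run_simulation`."""

    config: ModelConfig
    image: MuellerImage
    matrix: np.ndarray  # normalized 600-um averaged Mueller matrix
    #: unnormalized circle-summed element matrices per batch; their sum
    #: normalizes to ``matrix``
    batch_matrices: np.ndarray  # (n_batches, 4, 4)
    tallies: dict  # per input state: detected/undetected/reflected/lost
    seed: int

    def invariants(self):
        return invariant_set(self.matrix)

    def standard_errors(self) -> dict:
        return mc_standard_error(self.batch_matrices)


# ---------------------------------------------------------------------------
# step-level operations (thin wrappers over the compiled kernel pieces)
# ---------------------------------------------------------------------------

def free_path(rng, mu_t_cm: float) -> float:
    """Exponential free path in micrometers for total coefficient mu_t.

    ``s = -ln(U)/mu_t`` with U uniform on (0, 1].  A vanishing
    coefficient means a ballistic flight to the boundary (infinite
    path).
    """
    if mu_t_cm < 0:
        raise ValueError("mu_t must be >= 0")
    if mu_t_cm == 0.0:
        return np.inf
    return -np.log(1.0 - rng.random()) / (mu_t_cm * CM_TO_UM)


def choose_scatterer(rng, mu_s_cm: float, mu_c_cm: float) -> str:
    """Competing-interaction rule: 'sphere' with probability mu_s/(mu_s+mu_c)."""
    tot = mu_s_cm + mu_c_cm
    if tot <= 0.0:
        raise ValueError("at least one scattering coefficient must be positive")
    return "sphere" if rng.random() * tot < mu_s_cm else "cylinder"


def apply_birefringence(photon: PhotonState, s_um: float, config: ModelConfig) -> PhotonState:
    """Apply the host retarder accumulated over path length ``s_um``.

    The retardance is ``(2 pi / lambda) (n_e(theta_p) - n_o) s`` with
    ``theta_p`` the angle between the propagation direction and the
    optic axis and ``1/n_e(theta_p)^2 = cos^2/n_o^2 + sin^2/n_e^2``;
    the fast axis is the transverse projection of the optic axis.
    Propagation along the optic axis or ``delta_n = 0`` leaves the
    photon unchanged.
    """
    if config.delta_n <= 0.0 or s_um <= 0.0:
        return photon
    u = photon.direction
    axis = np.asarray(config.optic_axis)
    cth = float(np.dot(u, axis))
    s2 = 1.0 - cth * cth
    if s2 < 1e-14:
        return photon
    n_o = config.n_host
    n_e = n_o + config.delta_n
    ne_eff = 1.0 / np.sqrt(cth * cth / n_o**2 + s2 / n_e**2)
    delta = 2.0 * np.pi / config.wavelength_um * (ne_eff - n_o) * s_um
    t = axis - cth * u
    t /= np.linalg.norm(t)
    beta = float(np.arctan2(np.dot(t, photon.frame_w), np.dot(t, photon.frame_v)))
    _kernel._apply_retarder(photon.stokes, delta, beta)
    return photon


def scatter(photon: PhotonState, scatterer: str, rng, config: ModelConfig) -> PhotonState:
    """One scattering event on a sphere or cylinder; updates the photon.

    Uses the same compiled routines as the transport loop: direction,
    local frame and Stokes vector are all updated, with the sphere
    event preserving s0 and the cylinder event applying the polarized
    cross-section weight.
    """
    u = photon.direction.copy()
    v = photon.frame_v.copy()
    w = np.cross(u, v)
    S = photon.stokes
    if scatterer == "sphere":
        t = build_sphere_tables(config.x_sphere, config.m_sphere)
        err = _kernel._scatter_sphere(rng, u, v, w, S, t.s11, t.s12, t.s33, t.s34, t.pmax)
    elif scatterer == "cylinder":
        t = build_cylinder_tables(config.x_cyl, config.m_cyl)
        axis = np.asarray(config.cylinder_axis)
        err = _kernel._scatter_cylinder(
            rng, u, v, w, S, axis, t.zeta0, t.dzeta, t.mueller, t.crow, t.env
        )
    else:
        raise ValueError(f"unknown scatterer {scatterer!r}")
    if err != _kernel.ERR_OK:
        raise EnvelopeError("phase-function envelope violated during scattering")
    photon.direction = u
    photon.frame_v = v
    return photon


# ---------------------------------------------------------------------------
# full simulation
# ---------------------------------------------------------------------------

def _derive_seed(seed: int, state_idx: int, batch: int) -> int:
    return (seed * 1_000_003 + state_idx * 10_007 + batch * 101 + 12345) % (2**31)

_DUMMY_SPH = (np.ones(2), np.zeros(2), np.zeros(2), np.zeros(2), 1.0)
_DUMMY_CYL = (
    float(np.deg2rad(0.5)),
    1.0,
    np.zeros((2, 2, 4, 4)),
    np.ones((2, 4)),
    np.ones(2),
    np.ones(2),
    np.ones(2),
)


def run_simulation(config: ModelConfig, n_photons: int | None = None, seed: int | None = None) -> SimulationResult:
    """Run the four-input-state transmission simulation.

    Photons are split into ``config.n_batches`` independent batches per
    input state (separate seeded streams), so batch-level Mueller
    matrices and Monte Carlo standard errors come for free.  The result
    is deterministic given (config, seed).
    """
    if n_photons is not None:
        config = config.with_(n_photons=n_photons)
    if seed is not None:
        config = config.with_(seed=seed)
    nb = config.n_batches
    per_batch = config.n_photons // nb
    if per_batch < 1:
        raise ValueError("n_photons must be >= n_batches")
    nx = ny = int(round(2.0 * config.grid_half_um / config.pixel_um))
    if config.detector_diameter_um > 2.0 * config.grid_half_um:
        raise ValueError("detection circle does not fit inside the image grid")

    if config.mu_s_cm > 0.0:
        t = build_sphere_tables(config.x_sphere, config.m_sphere)
        sph = (t.s11, t.s12, t.s33, t.s34, t.pmax)
    else:
        sph = _DUMMY_SPH
    if config.mu_c_cm > 0.0:
        tc = build_cylinder_tables(config.x_cyl, config.m_cyl)
        cyl = (tc.zeta0, tc.dzeta, tc.mueller, tc.crow, tc.env, tc.ext_par, tc.ext_perp)
    else:
        cyl = _DUMMY_CYL

    optic_axis = np.asarray(config.optic_axis, dtype=float)
    cyl_axis = np.asarray(config.cylinder_axis, dtype=float)
    det_radius = 0.5 * config.detector_diameter_um
    if config.accept_half_angle_deg is None:
        accept_cos = -1.0
    else:
        accept_cos = float(np.cos(np.deg2rad(config.accept_half_angle_deg)))

    state_names = list(INPUT_STATES)
    # stokes_img[state, batch, comp, iy, ix]
    stokes_img = np.zeros((4, nb, 4, ny, nx))
    counts = np.zeros((ny, nx), dtype=np.int64)
    tallies = {}
    for si, name in enumerate(state_names):
        tal = np.zeros(4, dtype=np.int64)
        for b in range(nb):
            rng = np.random.default_rng(_derive_seed(config.seed, si, b))
            img = stokes_img[si, b]
            err = _kernel._transport(
                rng,
                per_batch,
                INPUT_STATES[name],
                float(config.thickness_um),
                config.mu_s_um,
                config.mu_c_um,
                config.wavelength_um,
                float(config.delta_n),
                float(config.n_host),
                optic_axis,
                cyl_axis,
                sph[0], sph[1], sph[2], sph[3], sph[4],
                cyl[0], cyl[1], cyl[2], cyl[3], cyl[4], cyl[5], cyl[6],
                float(config.pixel_um),
                det_radius,
                accept_cos,
                float(config.lateral_half_um),
                config.max_events,
                img,
                counts,
                tal,
            )
            if err != _kernel.ERR_OK:
                raise EnvelopeError(
                    "phase-function envelope violated; refine the angle grids"
                )
        tallies[name] = {
            "detected": int(tal[_kernel.TALLY_DETECTED]),
            "undetected": int(tal[_kernel.TALLY_UNDETECTED]),
            "reflected": int(tal[_kernel.TALLY_REFLECTED]),
            "lost": int(tal[_kernel.TALLY_LOST]),
            "launched": per_batch * nb,
        }

    # assemble per-pixel Mueller accumulators from the four state images
    total = stokes_img.sum(axis=1)  # (state, comp, ny, nx)
    elements = _assemble_mueller(total)
    image = MuellerImage(elements=elements, counts=counts, pixel_um=config.pixel_um)

    matrix = spatial_average(image, config.detector_diameter_um)
    mask = _circle_mask(ny, nx, config.pixel_um, config.detector_diameter_um)
    batch_matrices = np.empty((nb, 4, 4))
    for b in range(nb):
        el = _assemble_mueller(stokes_img[:, b])
        batch_matrices[b] = el[:, :, mask].sum(axis=-1)
    return SimulationResult(
        config=config,
        image=image,
        matrix=matrix,
        batch_matrices=batch_matrices,
        tallies=tallies,
        seed=config.seed,
    )


def _assemble_mueller(state_imgs: np.ndarray) -> np.ndarray:
    """Mueller element maps from H/V/P/R Stokes accumulators.

    ``state_imgs`` has shape (4 states, 4 components, ny, nx); returns
    (4, 4, ny, nx) with columns c1=(H+V)/2, c2=(H-V)/2, c3=P-c1,
    c4=R-c1.
    """
    H, V, P, R = state_imgs[0], state_imgs[1], state_imgs[2], state_imgs[3]
    c1 = 0.5 * (H + V)
    c2 = 0.5 * (H - V)
    c3 = P - c1
    c4 = R - c1
    return np.stack([c1, c2, c3, c4], axis=1)  # (comp_i, col_j, ny, nx)


def _circle_mask(ny: int, nx: int, pixel_um: float, diameter_um: float) -> np.ndarray:
    ys = (np.arange(ny) + 0.5) * pixel_um - 0.5 * ny * pixel_um
    xs = (np.arange(nx) + 0.5) * pixel_um - 0.5 * nx * pixel_um
    r2 = ys[:, None] ** 2 + xs[None, :] ** 2
    mask = r2 <= (0.5 * diameter_um) ** 2
    if not mask.any():
        # degenerate circle: round to the pixel containing the origin
        mask = np.zeros((ny, nx), dtype=bool)
        mask[ny // 2, nx // 2] = True
    return mask


def _average_elements(elements: np.ndarray, pixel_um: float, diameter_um: float) -> np.ndarray:
    ny, nx = elements.shape[-2:]
    mask = _circle_mask(ny, nx, pixel_um, diameter_um)
    summed = elements[:, :, mask].sum(axis=-1)
    if summed[0, 0] <= 0.0:
        raise UnderSamplingError(
            "no transmitted intensity inside the detection circle"
        )
    return normalize(summed)


def spatial_average(image: MuellerImage, diameter_um: float) -> np.ndarray:
    """Intensity-weighted average over the central detection circle.

    Sums the 16 accumulator maps over pixels whose centers lie within
    the circle (linear, so it commutes with any global scaling), then
    normalizes by m11.  Raises if the circle exceeds the grid or
    collects no intensity.
    """
    if diameter_um > 2.0 * image.extent_um:
        raise ValueError("averaging region extends beyond the image grid")
    return _average_elements(image.elements, image.pixel_um, diameter_um)


# ---------------------------------------------------------------------------
# Monte Carlo standard errors
# ---------------------------------------------------------------------------

def mc_standard_error(batch_matrices: np.ndarray) -> dict:
    """Per-invariant standard errors from independent batch accumulators.

    ``batch_matrices`` are the unnormalized circle-summed Mueller
    element matrices of >= 10 independent batches (equal photon
    budgets), as produced by :func:`run_simulation`.  The estimator is
    a leave-one-batch-out jackknife on the full-statistics matrix
    logarithm: each replicate drops one batch, renormalizes and
    decomposes, which keeps every decomposition at near-full photon
    count (individual small batches can stray across the principal
    branch cut when the retardance approaches pi; the jackknife
    replicates do not).

    Linear invariants (RC, DC, aL, a44) get the plain jackknife SE.
    The square-root invariants (RT, DT, aLA) are folded quantities,
    positively biased under noise, so their SEs are propagated from the
    signed components under the root: the delta method when the
    invariant is resolved from zero, and the conservative root-sum-
    square of the component SEs otherwise (a 3-sigma test against that
    bound has a chi-square false-positive rate of about e^-9).
    """
    batch_matrices = np.asarray(batch_matrices, dtype=float)
    nb = batch_matrices.shape[0]
    if nb < 10:
        raise ValueError(f"need >= 10 batches for standard errors, got {nb}")
    total = batch_matrices.sum(axis=0)
    logs = np.empty((nb, 4, 4))
    for b in range(nb):
        logs[b] = matrix_log(normalize(total - batch_matrices[b])).L
    Lms = np.empty((nb, 4, 4))
    Lus = np.empty((nb, 4, 4))
    for b in range(nb):
        Lms[b], Lus[b] = g_split(logs[b])

    jack = (nb - 1.0) / nb

    def se(values):
        return float(np.sqrt(jack * np.sum((values - np.mean(values)) ** 2)))

    def root_se(p_vals, q_vals):
        sp, sq = se(p_vals), se(q_vals)
        p, q = float(np.mean(p_vals)), float(np.mean(q_vals))
        bound = float(np.hypot(sp, sq))
        r = float(np.hypot(p, q))
        if r > 3.0 * bound:
            return float(np.sqrt((p * sp) ** 2 + (q * sq) ** 2) / r)
        return bound

    return {
        "RT": root_se(Lms[:, 1, 3], Lms[:, 2, 3]),
        "DT": root_se(Lms[:, 0, 1], Lms[:, 0, 2]),
        "RC": se((logs[:, 1, 2] - logs[:, 2, 1]) / 2.0),
        "DC": se((logs[:, 0, 3] + logs[:, 3, 0]) / 2.0),
        "aL": se((logs[:, 1, 1] + logs[:, 2, 2]) / 2.0),
        "a44": se(logs[:, 3, 3]),
        "aLA": root_se(
            (Lus[:, 1, 1] - Lus[:, 2, 2]) / 2.0,
            (Lus[:, 1, 2] + Lus[:, 2, 1]) / 2.0,
        ),
    }
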