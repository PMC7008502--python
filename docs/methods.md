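# Methods

`polarmc` couples a polarized Monte Carlo photon transport model of a
scattering slab to the logarithmic decomposition of Mueller matrices
and its rotation invariants. This note records the model, its
assumptions, the numerical choices, and what the synthetic experiments
do and do not establish.

## The logarithmic decomposition and its invariants

A transmission Mueller matrix `M` (normalized to `m11 = 1`) is
decomposed through its principal matrix logarithm `L = ln M`, computed
from the complex eigendecomposition `L = U ln(Λ) U⁻¹`. `L` splits into
a G-antisymmetric polarization part and a G-symmetric depolarization
part,

    Lm = (L − G Lᵀ G)/2,   Lu = (L + G Lᵀ G)/2,   G = diag(1, −1, −1, −1),

whose entries are the elementary coefficients: linear retardance
LB = Lm34 and LB′ = Lm42 in the 0–90° and ±45° frames, circular
retardance CB = Lm23, the dichroism coefficients LD, LD′, CD, and the
diagonal depolarization coefficients α22, α33, α44 (typically ≤ 0 for
passive media).

In-plane rotation of the sample by α acts on `M` (and identically on
`L`) as a similarity transform with the block rotation matrix with
entries cos 2α / ±sin 2α on the (s1, s2) block. Seven combinations of
the entries of `L` are invariant under this transform:

| invariant | definition | meaning | units |
|---|---|---|---|
| RT  | √(Lm24² + Lm34²) | total linear retardance | rad |
| DT  | √(Lm12² + Lm13²) | total linear dichroism | — |
| RC  | (L23 − L32)/2 | circular retardance | rad |
| DC  | (L14 + L41)/2 | circular dichroism | — |
| αL  | (L22 + L33)/2 | isotropic linear depolarization | — |
| α44 | L44 | circular depolarization | — |
| αLA | ½√((α22 − α33)² + (Lu23 + Lu32)²) | anisotropy of linear depolarization | — |

RT, DT and αLA are reported unsigned (square-root definitions). The
s3 handedness convention (right-circular positive) and the retardance
sign convention (a fast-axis-0 retarder of retardance δ gives
LB = +δ) do not affect any invariant.

**Branch handling.** Only the principal logarithm is used, so total
retardance is representable only below π. Eigenvalues on the closed
negative real axis raise an explicit `BranchError` instead of guessing
a branch. Near-defective eigenvector bases (condition number > 1e8)
fall back to a Schur-based logarithm; the contract is the round trip
`exp(L) = M` (1e−8), not the algorithm. The maximum imaginary part
discarded when realifying `L` is recorded as `imag_residual`, never
silently dropped.

## Single-scattering kernels

Spheres use the Mie partial-wave series (logarithmic-derivative
downward recurrence, truncation order ⌈x + 4x^(1/3) + 2⌉); cylinders
use the infinite-cylinder series at oblique incidence, with the four
complex amplitudes T1..T4 on the scattering cone that makes the
incidence angle ζ with the axis. Both are converted to Mueller form
through the exact coherency-matrix transform of the 2×2 amplitude
matrix. Internal checks: the Rayleigh dipole limits, a second
independent Mie series as cross-check, azimuthal energy closure of the
cylinder series (0.1%), and the optical theorem
Re T(0) = x·Q/2, which the non-absorbing series satisfies to machine
precision at every incidence angle.

Scattering angles are drawn by rejection from the *polarized* phase
function of the incident Stokes vector, using envelopes tabulated on
dense grids (721 points in θ or Θ; 91 incidence angles for cylinders)
with a 1.05 safety factor; an envelope violation is a hard error. The
photon carries a local (v, w) frame; after an event the frame is
rotated into the scattering plane so that the tabulated Mueller block
applies directly.

## Transport model

The slab occupies 0 ≤ z ≤ d (μm) with index-matched boundaries (no
Fresnel reflection; the modeled measurements exclude the glass slide),
infinite lateral extent (photons beyond a 3-mm half-width are dropped
and counted), and a pencil beam at normal incidence — translational
symmetry of the slab makes this equivalent to a uniform beam for the
spatially averaged matrix. The host is non-absorbing. Scattering
coefficients μs, μc (cm⁻¹) are inverse mean free paths specified
directly; number densities are never computed.

**Birefringent host.** Along each straight flight segment the host
acts as a continuous linear retarder with direction-dependent
extraordinary index, 1/n_e(θp)² = cos²θp/n_o² + sin²θp/n_e², fast axis
along the transverse projection of the (in-plane) optic axis. Ray
splitting, walk-off and direction-dependent refraction are neglected —
justified for Δn ≤ 0.009 at slab thicknesses of tens of μm. The
ballistic limit reproduces the closed-form slab retarder to
floating-point precision.

**Cylinder dichroism.** The configured μc is the unpolarized
normal-incidence coefficient. Free paths are sampled at that rate, and
the polarization and incidence-angle dependence of cylinder extinction
is restored by two unbiased corrections: (i) each segment applies the
residual dichroic extinction `exp(−(μ_j(ζ) − μc)s)` for the field
components parallel/perpendicular to the (direction, axis) plane, with
μ_j(ζ) from the tabulated polarized efficiencies (optical theorem);
(ii) each scattering event multiplies the weight by the ratio of the
polarized to the unpolarized azimuth-integrated scattered power. The
coherent differential *phase* of the forward amplitudes (form
birefringence) is deliberately not applied: in this model family the
host's intrinsic Δn stands in for form birefringence, and applying
both would double-count the effect.

**Detection.** Transmitted photons are accepted within an angular
cone (presets: 20° half-angle, NA ≈ 0.34, a typical
mid-magnification objective; the engine default accepts all angles)
and binned on a 10-μm grid. The detected Stokes vector is the Jones
projection of the transverse field onto the detector x–y plane —
exactly x↔y mirror-equivariant, which matters: anchoring the frame to
one lab axis instead injects a spurious polarizance of order 0.04 for
wide-angle collection. The Mueller matrix is assembled from four
separate runs with inputs H, V, P (+45°), R (right circular):
columns c1 = (H+V)/2, c2 = (H−V)/2, c3 = P−c1, c4 = R−c1. Trajectories
are not reused across inputs because the rejection sampler conditions
on the actual polarization. The averaged matrix sums the accumulators
over the central 600-μm circle and normalizes.

**Statistics.** Photons are split into ≥10 independently seeded
batches per input state. Standard errors of the invariants come from a
leave-one-batch-out jackknife on the *accumulator sums*: each replicate
decomposes a near-full-statistics matrix, which keeps the replicates
away from the branch cut where individual small batches would fail.
Square-root invariants (RT, DT, αLA) are folded quantities, positively
biased under noise; their SEs are propagated from the signed
components under the root (delta method when resolved from zero, the
conservative root-sum-square of component SEs otherwise, for which a
3σ exceedance has a chi-square tail probability ≈ e⁻⁹). "Consistent
with zero" tests compare the full-run value against 3 of these SEs.

## Dermal-layer models and study conditions

Presets (all at λ = 0.533 μm, n_scatterer = 1.45, n_host = 1.33,
μs = 1500 cm⁻¹, sphere radius 0.05 μm — subwavelength, Rayleigh
regime):

* **SC** — spheres + cylinders (Rc = 0.05 μm, axis X, μc = 1500 cm⁻¹),
  isotropic host;
* **SB** — spheres only, birefringent host Δn = 0.009, optic axis X;
* **SCB** — spheres + cylinders in the birefringent host,
  μc ∈ {500, 1000, 1500} cm⁻¹, Rc sweep {0.05, 0.5, 2} μm.

Thickness grids: SB sweeps 3–30 μm in 3-μm steps. With Δn = 0.009 the
cumulative retardance is 0.1061·d rad and crosses the π branch limit
of the principal logarithm at d ≈ 29.6 μm; the SB matrix stays
decomposable there (the wrapped point reads ≈ 3.08 rad), but the
cylinder-bearing slabs — whose polarized eigenvalues are further
crushed by dichroism and depolarization (moduli ~0.05 at d = 30,
optical thickness up to 9) — are not resolvable at tractable photon
budgets beyond ≈ 24 μm. The SC/SCB sweeps therefore stop at 21 μm,
where the αLA signatures are resolved at 5–12σ, and the μc/Rc
comparisons run at d = 21 μm. Slabs ≥ 21 μm carry 10× the baseline
photon budget (10⁵ per input state) because the polarized signal
decays exponentially with optical thickness.

## What the synthetic experiments show

The generator emulates the *model family*, not tissue: monodisperse
scatterers, perfectly aligned infinite cylinders, a homogeneous host,
no absorption, no interface roughness, no glass slide. Passing tests
establish that the transport and decomposition machinery reproduce the
discriminating signatures of the model classes — SB: linear RT growth,
quadratic depolarization growth, DT ≈ 0, αLA ≈ 0; SCB: additionally
DT > 0 growing with thickness and αLA > 0, increasing with cylinder
concentration and decreasing with cylinder radius; Rayleigh ordering
|α44| > |αL| for 0.05-μm spheres. They do not establish quantitative
agreement with any real tissue measurement, nor the absolute
magnitudes of depolarization, which depend on the (instrument-specific)
angular acceptance.

## Known limitations

* Retardance ≥ π is not representable (principal branch); the thickest
  SB slab sits just past the wrap and reads ≈ 2π − RT.
* The exact objective NA of the modeled instrument is unknown; 20° is
  a fixed, documented choice, and absolute depolarization levels scale
  with it.
* Near-axial propagation along a cylinder (ζ < 0.5°) is clamped to the
  smallest tabulated incidence angle.
* The event-rate correction references the normal-incidence μc; the
  residual ζ-dependence of the *sampled* (as opposed to weighted) rate
  is second order for near-normal transport but would bias strongly
  oblique geometries.
* Absorption, finite cylinders, size distributions, coated particles
  and reflection geometry are out of scope.
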