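# polarmc

Polarized Monte Carlo transport in scattering birefringent slabs, with
the logarithmic Mueller matrix decomposition (LMMD) and its rotation
invariants.

## The problem

Transmission Mueller microscopy of thin histological cuts measures a
4×4 Mueller matrix per pixel. Interpreting those matrices — telling
scattering by round cells from scattering by aligned collagen fibers,
or form birefringence from intrinsic birefringence — requires both a
decomposition that separates the elementary optical effects and a
forward model that predicts what each candidate microstructure would
produce. `polarmc` provides both for slab models of the dermal layer:
monodisperse spheres and/or infinitely long aligned cylinders embedded
in an isotropic or uniaxial linearly birefringent host.

The decomposition works in the logarithmic domain: `L = ln M` is split
into a polarization part `Lm = (L − G Lᵀ G)/2` and a depolarization
part `Lu = (L + G Lᵀ G)/2` with `G = diag(1, −1, −1, −1)`. Because an
in-plane rotation of the sample transforms `L` exactly as it
transforms `M`, seven rotation-invariant parameters can be read off
`L`:

* `RT = √(Lm24² + Lm34²)` — total linear retardance (rad)
* `DT = √(Lm12² + Lm13²)` — total linear dichroism
* `RC = (L23 − L32)/2`, `DC = (L14 + L41)/2` — circular retardance / dichroism
* `αL = (L22 + L33)/2`, `α44 = L44` — isotropic linear and circular depolarization
* `αLA = ½√((α22 − α33)² + (Lu23 + Lu32)²)` — anisotropy of linear
  depolarization, the marker for aligned fibrous scatterers

These remove the nuisance dependence on how the sample happened to be
oriented under the microscope.

The Monte Carlo engine tracks Stokes vectors photon by photon: Mie
scattering for spheres, the oblique-incidence infinite-cylinder
amplitude series for fibers, rejection sampling of scattering angles
from the polarized phase function, a continuous retarder model of the
birefringent host, and per-segment dichroic extinction for the aligned
cylinders. Transmission Mueller matrices are assembled from four
polarized runs, imaged at the exit face, and averaged over a central
600-μm circle.

## Worked example

`python examples/03_sb_vs_scb.py` simulates a 9-μm dermal slab with
the SB model (spheres in a birefringent host) and the SCB model
(spheres + aligned cylinders in the same host) and prints:

```
SB: RT=0.958 rad  DT=0.0016(+-0.0059)  aL=-0.047  a44=-0.077  aLA=0.0004(+-0.0044)
SCB: RT=0.992 rad  DT=0.3254(+-0.0117)  aL=-0.280  a44=-0.367  aLA=0.0791(+-0.0078)
```

Both models produce the same linear retardance (set by the host
birefringence, Δn = 0.009) and Rayleigh-ordered depolarization
(|α44| > |αL|). But only the SCB model shows linear dichroism
(DT = 0.33 ± 0.01) and anisotropic linear depolarization
(αLA = 0.079 ± 0.008); for SB both are statistically zero. That pair
of observables is therefore the fingerprint of aligned fibrous
microstructure — the basis for discriminating the optical model of the
dermal layer.

The other examples demonstrate rotation invariance of the
decomposition (`01`), the exact ballistic birefringent-slab limit
(`02`), and the single-scattering building blocks (`04`).

A thin CLI mirrors the library: `polarmc simulate`, `polarmc sweep`,
`polarmc report`, `polarmc presets`, `polarmc phasefunc`.

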