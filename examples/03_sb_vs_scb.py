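"""Dermal-layer model discrimination at one thickness (small budget).

Simulates the SB (spheres in birefringent host) and SCB (spheres +
aligned cylinders in birefringent host) models of a 9-um dermal slab
and prints the invariants: only the SCB model shows linear dichroism
(DT) and anisotropic linear depolarization (aLA).
"""

from polarmc import make_preset, run_simulation

for name in ("SB", "SCB"):
    cfg = make_preset(name, thickness_um=9.0)
    res = run_simulation(cfg, n_photons=50_000, seed=7)
    inv = res.invariants()
    se = res.standard_errors()
    print(f"{name}: RT={inv.RT:.3f} rad  DT={inv.DT:.4f}(+-{se['DT']:.4f})  "
          f"aL={inv.aL:.3f}  a44={inv.a44:.3f}  aLA={inv.aLA:.4f}(+-{se['aLA']:.4f})")

print()
print("SB: DT and aLA are consistent with zero — isotropic spheres in a")
print("birefringent host produce retardance and depolarization but no")
print("dichroism or depolarization anisotropy.  SCB: the aligned")
print("cylinders add both, which is the fingerprint of fibrous")
print("(collagen-like) microstructure.")
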