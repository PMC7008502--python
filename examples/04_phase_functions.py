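"""Single-scattering building blocks: phase functions and cross-sections.

Prints the Mie efficiency of the dermal-model sphere, the polarized
cylinder efficiencies, and a coarse dump of the sphere phase function.
"""

import numpy as np

from polarmc.cylinder import cylinder_efficiencies
from polarmc.mie import mie_cross_section, single_scatter_mueller

lam, nh = 0.533, 1.33
m = 1.45 / nh

for radius in (0.05, 0.25):
    x = 2 * np.pi * radius * nh / lam
    sigma, q = mie_cross_section(x, m, lam, nh)
    print(f"sphere R={radius} um: size parameter x={x:.3f}, Qsca={q:.3e}, "
          f"sigma={sigma:.3e} um^2")

x = 2 * np.pi * 0.05 * nh / lam
qI, qII = cylinder_efficiencies(x, m, np.pi / 2)
print(f"cylinder R=0.05 um at normal incidence: QI={qI:.3e} (E parallel to axis), "
      f"QII={qII:.3e}; ratio {qI / qII:.2f}")
print("the strong case-I/case-II asymmetry of thin cylinders is the origin")
print("of the dichroism of fibrous media")
print()
print("sphere phase function (unpolarized), theta vs relative intensity:")
theta = np.linspace(0.0, np.pi, 7)
s11 = single_scatter_mueller(x, m, theta)[:, 0, 0]
for t, s in zip(theta, s11 / s11[0]):
    print(f"  {np.degrees(t):5.0f} deg  {s:.3f}")
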