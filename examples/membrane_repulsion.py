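"""Hydration and electrostatic repulsion between vesicle and membrane.

Prints the two repulsion energies in units of kT across the first
nanometres of gap and the resulting Boltzmann equilibrium density of an
untethered vesicle.
"""

import numpy as np

from svtether import EnergeticsConfig, boltzmann_distance_pdf
from svtether.energetics import K_B, electrostatic_energy, hydration_energy

cfg = EnergeticsConfig()
kT = K_B * cfg.T

print(f"{'d (nm)':>7s} {'E_hyd/kT':>10s} {'E_el/kT':>10s}")
for d in (0.0, 1.0, 2.0, 3.0, 5.0, 10.0):
    print(f"{d:7.1f} {hydration_energy(d, cfg) / kT:10.3g} "
          f"{electrostatic_energy(d, cfg) / kT:10.3g}")

grid = np.linspace(0.0, 100.0, 10001)
pdf = boltzmann_distance_pdf(cfg, grid)
p2 = pdf.density[np.searchsorted(grid, 2.0)]
p10 = pdf.density[np.searchsorted(grid, 10.0)]
print()
print(f"equilibrium density at 2 nm is {p2 / p10:.1%} of the density at 10 nm:")
print("the combined repulsion effectively keeps the bare vesicle beyond ~2 nm.")
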