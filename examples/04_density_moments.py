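"""Dipole and quadrupole diagnostics of a valence density.

Builds an analytically known test case — a Gaussian electron cloud displaced
from its compensating nucleus — and checks the printed moments against the
closed form mu = q*d.
"""

import numpy as np

from deltaxc import AtomicSystem, DensityField, cube_grid, density_moments
from deltaxc.units import DEBYE_PER_EBOHR

q, d, sigma = 2.0, 0.8, 0.6
grid = cube_grid((0, 0, 1.0), 14.0, 48)
rho = DensityField(grid, q * np.exp(
    -((grid.points - [0, 0, d]) ** 2).sum(axis=1) / (2 * sigma ** 2))
    / (2 * np.pi * sigma ** 2) ** 1.5)
system = AtomicSystem(["X"], [[0.0, 0.0, 0.0]], valence_charges={"X": q})

m = density_moments(rho, system)
print(f"dipole (D):        {m.dipole.round(6)}")
print(f"closed form (D):   [0, 0, {-q * d * DEBYE_PER_EBOHR:.6f}]")
print(f"Q_T (D*A):         {m.q_t:.6f}")
print(f"<r^2> (D*A):       {m.r2:.4f}")
# The dipole matches q*d (electrons carry charge -1); Q_T summarizes the
# traceless quadrupole tensor rotation-invariantly; <r^2> is the spread of
# the electronic charge about the origin.
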