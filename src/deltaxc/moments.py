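"""Multipole diagnostics of valence densities.

Dipole and quadrupole moments summarize a density distribution in an
experimentally accessible, basis-independent way.  Conventions:

* electrons carry charge -1, nuclei carry their valence charge at the
  nuclear position (a valence-only description);
* the traceless quadrupole tensor follows the Buckingham convention
  Theta_ij = 1/2 * sum_q q * (3 x_i x_j - r^2 delta_ij);
* Q_T = 1/2 (q_max - q_min) of Theta's eigenvalues -- a rotational
  invariant scalar;
* the valence spread <r^2> is the electronic-charge-weighted second moment
  -int r^2 rho d^3r (negative by the electron sign convention).

Dipoles are reported in Debye, quadrupoles and <r^2> in Debye * Angstrom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .density import DensityField
from .system import AtomicSystem
from .units import DEBYE_ANGSTROM_PER_EBOHR2, DEBYE_PER_EBOHR


@dataclass
class Moments:
    dipole: np.ndarray        # (3,) Debye
    quadrupole: np.ndarray    # (3, 3) traceless, Debye*Angstrom
    q_t: float                # Debye*Angstrom
    r2: float                 # Debye*Angstrom
    origin: np.ndarray        # (3,) Bohr


def density_moments(density: DensityField, system: AtomicSystem | None = None,
                    origin=(0.0, 0.0, 0.0)) -> Moments:
    """Dipole, traceless quadrupole, Q_T and <r^2> of a valence density.

    Nuclear point charges (species valence at R_I) are included when a
    ``system`` is supplied.  For a non-neutral total charge the dipole is
    origin-dependent; a warning records the origin used and the value is
    still returned.
    """
    origin = np.asarray(origin, dtype=float)
    g = density.grid
    r = g.points - origin
    w_rho = g.weights * density.values

    n_elec = w_rho.sum()
    n_nuc = 0.0
    dip = -(w_rho @ r)
    r2n = r ** 2
    quad_e = -0.5 * (3.0 * (r.T * w_rho) @ r
                     - np.eye(3) * (w_rho @ r2n.sum(axis=1)))
    quad = quad_e
    if system is not None:
        q_nuc = np.array([system.valence(s) for s in system.species])
        rn = system.positions - origin
        n_nuc = q_nuc.sum()
        dip = dip + q_nuc @ rn
        quad = quad + 0.5 * (3.0 * (rn.T * q_nuc) @ rn
                             - np.eye(3) * (q_nuc @ (rn ** 2).sum(axis=1)))
    net = n_nuc - n_elec
    if abs(net) > 1e-6:
        warnings.warn(
            f"system carries net charge {net:+.3e} e; dipole depends on the "
            f"origin ({origin.tolist()} Bohr)", stacklevel=2)

    evals = np.linalg.eigvalsh(quad)
    q_t = 0.5 * (evals[-1] - evals[0])
    r2 = -(w_rho @ r2n.sum(axis=1))
    return Moments(dipole=dip * DEBYE_PER_EBOHR,
                   quadrupole=quad * DEBYE_ANGSTROM_PER_EBOHR2,
                   q_t=float(q_t * DEBYE_ANGSTROM_PER_EBOHR2),
                   r2=float(r2 * DEBYE_ANGSTROM_PER_EBOHR2),
                   origin=origin)
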