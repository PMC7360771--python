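"""A minimal 3-D self-consistent solver for model systems.

The solver exists so the potential pathway — density, projection, network
gradient, potential assembly, new density — can be exercised end to end
without a production electronic-structure code.  It solves a single-particle
problem on a uniform cube grid:

    H[rho] = -1/2 Laplacian + V_ext + V_base[rho] (+ V_ML[rho]),

with a 7-point finite-difference Laplacian (Dirichlet boundaries), Gaussian
attractive wells as the external potential, and a local density-power
baseline functional

    E_base_fn[rho] = A * int rho^p,    V_base = A * p * rho^(p-1),

whose functional derivative is analytic.  The lowest ``n_elec`` orbitals are
singly occupied; the density is fixed-point iterated under linear mixing.

Total energies follow the usual double-counting correction:
E = sum eps_occ - int V_scf rho + E_base_fn[rho] (+ E_ML[rho]), where V_scf
collects every density-dependent potential entering the Hamiltonian.

No claim of chemical realism is made; the model is a stand-in host for the
machine-learned correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .basis import ProjectionOperator, build_projector
from .density import DensityField
from .grids import Grid, cube_grid
from .model import EnergyModel, ml_potential
from .system import AtomicSystem, BasisSpec


class SCFConvergenceError(RuntimeError):
    def __init__(self, message: str, residuals: list[float]):
        hint = ""
        if len(residuals) > 4 and residuals[-1] > residuals[-3]:
            hint = ("; the residual is oscillating - try a smaller mixing "
                    "coefficient")
        super().__init__(message + hint)
        self.residuals = residuals


@dataclass
class BaselineFunctional:
    """Local density-power functional A * int rho^p with analytic derivative."""

    A: float = 0.3
    p: float = 4.0 / 3.0

    def energy(self, grid: Grid, rho: np.ndarray) -> float:
        return self.A * grid.integrate(np.maximum(rho, 0.0) ** self.p)

    def potential(self, rho: np.ndarray) -> np.ndarray:
        return self.A * self.p * np.maximum(rho, 0.0) ** (self.p - 1.0)


@dataclass
class ToySystem:
    """Gaussian-well model system living on a cube grid."""

    system: AtomicSystem          # well centers double as atom positions
    depths: np.ndarray            # Hartree, > 0 (attractive)
    widths: np.ndarray            # Bohr
    n_elec: int
    grid: Grid
    baseline: BaselineFunctional = field(default_factory=BaselineFunctional)

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float).ravel()
        self.widths = np.asarray(self.widths, dtype=float).ravel()
        if self.n_elec <= 0:
            raise ValueError("electron count must be positive")
        if np.any(self.depths < 0) or np.any(self.widths <= 0):
            raise ValueError("well depths must be >= 0 and widths > 0")

    def external_potential(self) -> np.ndarray:
        v = np.zeros(self.grid.npoints)
        for pos, d, s in zip(self.system.positions, self.depths, self.widths):
            r2 = ((self.grid.points - pos) ** 2).sum(axis=1)
            v -= d * np.exp(-r2 / (2.0 * s ** 2))
        return v


@dataclass
class SCFResult:
    density: DensityField
    energy: float
    orbital_energies: np.ndarray
    orbitals: np.ndarray
    residuals: list[float]
    e_ml: float = 0.0


def _laplacian(shape, h: float) -> sp.spmatrix:
    def lap1d(n):
        return sp.diags([np.ones(n - 1), -2.0 * np.ones(n), np.ones(n - 1)],
                        [-1, 0, 1]) / h ** 2
    nx, ny, nz = shape
    return sp.kronsum(sp.kronsum(lap1d(nz), lap1d(ny)), lap1d(nx))


def _solve_orbitals(lap, v_eff: np.ndarray, n_elec: int, v0=None):
    H = -0.5 * lap + sp.diags(v_eff)
    if v0 is None:
        v0 = np.ones(v_eff.shape[0])
    eps, phi = spla.eigsh(H, k=n_elec, which="SA", v0=v0)
    order = np.argsort(eps)
    return eps[order], phi[:, order]


def _density_from_orbitals(phi: np.ndarray, weights: np.ndarray) -> np.ndarray:
    # orbitals are grid vectors; normalize under the quadrature measure
    norms = (phi ** 2 * weights[:, None]).sum(axis=0)
    return (phi ** 2 / norms).sum(axis=1)


def _run_scf(toy: ToySystem, extra_potential, extra_energy,
             mixing: float, tol: float, max_iter: int) -> SCFResult:
    """Generic SCF loop; ``extra_potential(rho) -> (values, energy_fn)``.

    ``extra_potential`` returns the density-dependent potential beyond
    V_ext + V_base evaluated at the current density; ``extra_energy(rho)``
    its energy functional at the converged density.
    """
    grid = toy.grid
    if grid.meta.get("shape") is None:
        raise ValueError("toy SCF requires a uniform cube grid")
    h_axes = grid.meta["axes"]
    h = float(h_axes[0, 0])
    if not np.allclose(h_axes, np.eye(3) * h):
        raise ValueError("toy SCF requires an isotropic cube grid")
    lap = _laplacian(grid.meta["shape"], h)
    v_ext = toy.external_potential()

    rho = np.zeros(grid.npoints)
    residuals: list[float] = []
    v0 = None
    for it in range(max_iter):
        v_scf = toy.baseline.potential(rho)
        v_extra = extra_potential(rho)
        v_eff = v_ext + v_scf + v_extra
        eps, phi = _solve_orbitals(lap, v_eff, toy.n_elec, v0)
        v0 = phi[:, 0]
        rho_out = _density_from_orbitals(phi, grid.weights)
        if np.any(~np.isfinite(rho_out)):
            raise SCFConvergenceError(
                f"non-finite density at iteration {it}", residuals)
        residual = grid.integrate(np.abs(rho_out - rho))
        residuals.append(float(residual))
        rho = rho + mixing * (rho_out - rho) if it > 0 else rho_out
        if residual < tol and it > 0:
            # energy at the converged density, with the double-counting
            # correction for every density-dependent potential in H
            v_scf = toy.baseline.potential(rho)
            v_extra = extra_potential(rho)
            eps, phi = _solve_orbitals(lap, v_ext + v_scf + v_extra,
                                       toy.n_elec, v0)
            density = DensityField(grid, rho, kind="full")
            e_band = float(eps[:toy.n_elec].sum())
            e_dc = grid.integrate((v_scf + v_extra) * rho)
            e_ml = extra_energy(rho)
            energy = (e_band - e_dc + toy.baseline.energy(grid, rho) + e_ml)
            return SCFResult(density, energy, eps, phi, residuals, e_ml=e_ml)
    raise SCFConvergenceError(
        f"SCF did not reach residual {tol:g} within {max_iter} iterations "
        f"(last residual {residuals[-1]:.3e})", residuals)


def solve_baseline(toy: ToySystem, mixing: float = 0.3, tol: float = 1e-8,
                   max_iter: int = 200) -> SCFResult:
    """Self-consistent solution with the baseline functional only."""
    zero = np.zeros(toy.grid.npoints)
    return _run_scf(toy, lambda rho: zero, lambda rho: 0.0,
                    mixing, tol, max_iter)


def solve_nxc(toy: ToySystem, model: EnergyModel, spec: BasisSpec,
              projector: ProjectionOperator | None = None,
              mixing: float = 0.3, tol: float = 1e-8,
              max_iter: int = 200) -> SCFResult:
    """Self-consistent solution with the ML correction in the loop.

    The ML potential is re-assembled from the current density every cycle;
    at convergence the density is a fixed point of V_base + V_ML.
    """
    if projector is None:
        projector = build_projector(toy.system, spec, toy.grid)

    def extra_potential(rho: np.ndarray) -> np.ndarray:
        field = DensityField(toy.grid, rho, kind="full")
        _, pot = ml_potential(model, projector, field)
        return pot.values

    def extra_energy(rho: np.ndarray) -> float:
        field = DensityField(toy.grid, rho, kind="full")
        e, _ = ml_potential(model, projector, field)
        return e

    return _run_scf(toy, extra_potential, extra_energy, mixing, tol, max_iter)


def solve_reference(toy: ToySystem, potential_fn, energy_fn,
                    mixing: float = 0.3, tol: float = 1e-8,
                    max_iter: int = 200) -> SCFResult:
    """Self-consistent solution with an arbitrary extra density functional.

    Used to manufacture reference energies from a known analytic target
    functional (``potential_fn(rho) -> values``, ``energy_fn(rho) ->
    Hartree``).
    """
    return _run_scf(toy, potential_fn, energy_fn, mixing, tol, max_iter)


def fixed_point_residual(toy: ToySystem, model: EnergyModel | None,
                         spec: BasisSpec | None, result: SCFResult) -> float:
    """Re-diagonalize at the converged density; integrated density change.

    A converged self-consistent density should reproduce itself: this is the
    defining property the ML potential must not break.
    """
    grid = toy.grid
    h = float(grid.meta["axes"][0, 0])
    lap = _laplacian(grid.meta["shape"], h)
    rho = result.density.values
    v_eff = toy.external_potential() + toy.baseline.potential(rho)
    if model is not None:
        projector = build_projector(toy.system, spec, grid)
        _, pot = ml_potential(model, projector, result.density)
        v_eff = v_eff + pot.values
    eps, phi = _solve_orbitals(lap, v_eff, toy.n_elec, rho)
    rho_new = _density_from_orbitals(phi, grid.weights)
    return float(grid.integrate(np.abs(rho_new - rho)))
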