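"""Atom-centered basis functions and density projection.

The density is represented by projecting it onto an atom-centered basis

    psi_nlm(r) = Y_lm(theta, phi) * zeta_n(r),

where Y_lm are orthonormal real spherical harmonics and zeta_n are
orthogonalized radial polynomials with compact support

    zeta~_n(r) = (1/N) * r^2 * (r_o - r)^(n+2)   for r < r_o, else 0,

with inner cutoff fixed at zero.  N normalizes each raw function to unit L2
norm under the measure r^2 dr, and a symmetric (Loewdin) transformation
S^(-1/2) orthogonalizes the set; the transformation is deterministic and
independent of basis order.

Projection coefficients (the model's descriptors) are quadrature integrals

    c_nlm^I = sum_k w_k * rho(r_k) * psi_nlm(r_k - R_I),

evaluated with the minimum-image convention when the grid is periodic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, sph_harm_y, sph_harm_y_all

from .density import DensityField
from .grids import Grid
from .system import AtomicSystem, BasisSpec


# ---------------------------------------------------------------------------
# radial functions
# ---------------------------------------------------------------------------

def radial_norm(n: int, r_o: float) -> float:
    """L2 normalization constant of the raw radial function.

    Closed form via the Euler beta integral:
    int_0^{r_o} r^6 (r_o - r)^(2n+4) dr = r_o^(2n+11) * B(7, 2n+5).
    """
    if n < 1:
        raise ValueError("radial index n must be >= 1")
    if r_o <= 0:
        raise ValueError("cutoff r_o must be positive")
    log_i = (2 * n + 11) * np.log(r_o) + betaln(7, 2 * n + 5)
    return float(np.exp(0.5 * log_i))


def radial_raw(n: int, r, r_o: float, normalization: float | None = None):
    """Raw (unorthogonalized) radial basis function zeta~_n(r).

    Compactly supported on [0, r_o]; vanishes at both endpoints through the
    r^2 prefactor and the (r_o - r)^(n+2) tail.  ``normalization`` defaults
    to the unit-L2-norm constant.
    """
    if n < 1:
        raise ValueError("radial index n must be >= 1")
    if r_o <= 0:
        raise ValueError("cutoff r_o must be positive")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius must be non-negative")
    N = radial_norm(n, r_o) if normalization is None else float(normalization)
    inside = r < r_o
    out = np.zeros_like(r)
    rr = r[inside]
    out[inside] = (rr ** 2) * (r_o - rr) ** (n + 2) / N
    return out if out.ndim else float(out)


def radial_quadrature(r_o: float, npts: int):
    """Gauss-Legendre rule on [0, r_o] (nodes, weights)."""
    x, w = np.polynomial.legendre.leggauss(npts)
    return 0.5 * r_o * (x + 1.0), 0.5 * r_o * w


def raw_radial_overlap(n_max: int, r_o: float, quadrature=None) -> np.ndarray:
    """Overlap matrix of normalized raw radial functions under r^2 dr."""
    if quadrature is None:
        # degree of the integrand is 2*(n_max+2)+6; this rule is exact
        quadrature = radial_quadrature(r_o, 2 * (n_max + 2) + 8)
    r, w = quadrature
    Z = np.stack([radial_raw(n, r, r_o) for n in range(1, n_max + 1)])
    return (Z * (w * r ** 2)) @ Z.T


def orthogonalize_radial(n_max: int, r_o: float, quadrature=None,
                         cond_limit: float = 1e12) -> np.ndarray:
    """Loewdin orthogonalization matrix M with zeta_n = sum_k M_nk zeta~_k.

    M = S^(-1/2) for the raw overlap S; symmetric, hence independent of how
    the raw functions are ordered, and deterministic for a given basis.
    """
    S = raw_radial_overlap(n_max, r_o, quadrature)
    evals, evecs = np.linalg.eigh(S)
    cond = evals[-1] / evals[0] if evals[0] > 0 else np.inf
    if evals[0] <= 0 or cond > cond_limit:
        raise np.linalg.LinAlgError(
            f"raw radial overlap numerically singular "
            f"(condition number {cond:.3e}); reduce n_max or refine the "
            f"quadrature")
    return (evecs / np.sqrt(evals)) @ evecs.T


# ---------------------------------------------------------------------------
# real spherical harmonics
# ---------------------------------------------------------------------------

def real_sph_harm(l: int, m: int, directions: np.ndarray):
    """Orthonormal real spherical harmonic Y_lm evaluated at unit vectors.

    Convention: Condon-Shortley-phase-free real harmonics,
    m = 0 -> Y_l0; m > 0 -> sqrt(2) * (-1)^m * Re(Y_lm);
    m < 0 -> sqrt(2) * (-1)^m * Im(Y_l|m|).  The set is orthonormal on the
    unit sphere.  Directions at the origin (zero vector) evaluate along +z.
    """
    if abs(m) > l:
        raise ValueError(f"|m| = {abs(m)} exceeds l = {l}")
    d = np.asarray(directions, dtype=float)
    scalar = d.ndim == 1
    d = d.reshape(-1, 3)
    norm = np.linalg.norm(d, axis=1)
    safe = np.where(norm > 0, norm, 1.0)
    unit = d / safe[:, None]
    unit[norm == 0] = (0.0, 0.0, 1.0)
    theta = np.arccos(np.clip(unit[:, 2], -1.0, 1.0))
    phi = np.arctan2(unit[:, 1], unit[:, 0])
    out = _real_sph_harm_angles(l, m, theta, phi)
    return float(out[0]) if scalar else out


def _real_sph_harm_angles(l: int, m: int, theta, phi):
    if m == 0:
        return sph_harm_y(l, 0, theta, phi).real
    if m > 0:
        return np.sqrt(2.0) * (-1.0) ** m * sph_harm_y(l, m, theta, phi).real
    return np.sqrt(2.0) * (-1.0) ** m * sph_harm_y(l, -m, theta, phi).imag


# ---------------------------------------------------------------------------
# projector
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BasisIndex:
    """Composite index beta <-> (atom, n, l, m)."""

    atom: int
    species: str
    n: int
    l: int
    m: int


@dataclass
class ProjectionOperator:
    """Tabulated orthonormal basis functions psi_beta on a grid.

    Shared by density projection (c_beta = <psi_beta | rho>) and potential
    assembly (V = sum_beta w_beta psi_beta); the index map fixes the
    canonical ordering (atom, n ascending, l ascending, m = -l..l).
    """

    system: AtomicSystem
    spec: BasisSpec
    grid: Grid
    values: np.ndarray          # (n_beta, n_points)
    index: list[BasisIndex]
    ortho: dict[str, np.ndarray]  # per-species Loewdin matrices

    @property
    def n_beta(self) -> int:
        return self.values.shape[0]

    @property
    def basis_hash(self) -> str:
        return self.spec.content_hash()

    def atom_slice(self, atom: int) -> slice:
        idx = [i for i, b in enumerate(self.index) if b.atom == atom]
        return slice(idx[0], idx[-1] + 1)

    def gram(self, atom: int) -> np.ndarray:
        """Per-atom overlap matrix of tabulated basis functions."""
        sl = self.atom_slice(atom)
        block = self.values[sl]
        return (block * self.grid.weights) @ block.T


def _tabulate_atom(grid: Grid, center, sb, M: np.ndarray) -> np.ndarray:
    """Tabulate one atom's orthonormal psi_nlm on the grid."""
    disp = grid.displacements(center)
    r = np.linalg.norm(disp, axis=1)
    inside = r < sb.r_o
    n_funcs = sb.n_max * (sb.l_max + 1) ** 2
    out = np.zeros((n_funcs, grid.npoints))
    if not np.any(inside):
        return out
    d_in = disp[inside]
    r_in = r[inside]
    raw = np.stack([radial_raw(n, r_in, sb.r_o)
                    for n in range(1, sb.n_max + 1)])
    zeta = M @ raw                                    # orthonormal radials
    # convert to angles once; r > 0 inside except possibly the center,
    # where the r^2 radial prefactor kills the (arbitrary) direction
    safe = np.where(r_in > 0, r_in, 1.0)
    unit = d_in / safe[:, None]
    unit[r_in == 0] = (0.0, 0.0, 1.0)
    theta = np.arccos(np.clip(unit[:, 2], -1.0, 1.0))
    phi = np.arctan2(unit[:, 1], unit[:, 0])
    allY = sph_harm_y_all(sb.l_max, sb.l_max, theta, phi)
    sqrt2 = np.sqrt(2.0)
    Y = {}
    for l in range(sb.l_max + 1):
        Y[(l, 0)] = allY[l, 0].real
        for m in range(1, l + 1):
            sign = (-1.0) ** m
            Y[(l, m)] = sqrt2 * sign * allY[l, m].real
            Y[(l, -m)] = sqrt2 * sign * allY[l, m].imag
    block = np.empty((n_funcs, r_in.shape[0]))
    row = 0
    for n in range(sb.n_max):
        for l in range(sb.l_max + 1):
            for m in range(-l, l + 1):
                block[row] = zeta[n] * Y[(l, m)]
                row += 1
    out[:, inside] = block
    return out


def build_projector(system: AtomicSystem, spec: BasisSpec,
                    grid: Grid) -> ProjectionOperator:
    """Tabulate every atom's basis on the grid and build the index map."""
    if grid.periodic:
        min_dim = np.linalg.norm(grid.cell, axis=1).min()
        if 2 * spec.max_cutoff >= min_dim:
            raise ValueError(
                f"cutoff sphere diameter {2 * spec.max_cutoff:.3f} Bohr "
                f"exceeds the shortest cell vector {min_dim:.3f} Bohr; "
                f"minimum-image projection is ambiguous")
    ortho = {s: orthogonalize_radial(sb.n_max, sb.r_o)
             for s, sb in spec.species.items()
             if s in system.species}
    blocks, index = [], []
    for a, (sym, pos) in enumerate(zip(system.species, system.positions)):
        sb = spec[sym]
        blocks.append(_tabulate_atom(grid, pos, sb, ortho[sym]))
        for n in range(1, sb.n_max + 1):
            for l in range(sb.l_max + 1):
                for m in range(-l, l + 1):
                    index.append(BasisIndex(a, sym, n, l, m))
    return ProjectionOperator(system, spec, grid, np.vstack(blocks), index,
                              ortho)


def project_density(projector: ProjectionOperator,
                    density: DensityField) -> np.ndarray:
    """Projection coefficients c_beta = sum_k w_k rho_k psi_beta(r_k)."""
    if density.grid.npoints != projector.grid.npoints:
        raise ValueError("density and projector grids differ")
    return projector.values @ (projector.grid.weights * density.values)


# ---------------------------------------------------------------------------
# atomic reference density
# ---------------------------------------------------------------------------

def atomic_reference_density(system: AtomicSystem, spec: BasisSpec,
                             grid: Grid) -> DensityField:
    """Superposition of spherical atomic profiles carrying valence charges.

    Each atom contributes the normalized n=1, l=0 raw radial profile (which
    is positive everywhere inside the cutoff), scaled so its integral equals
    the species' valence-electron count.
    """
    values = np.zeros(grid.npoints)
    for sym, pos in zip(system.species, system.positions):
        sb = spec[sym]
        q = system.valence(sym)
        # int zeta~_1(r) r^2 dr = r_o^8 B(5, 4) / N_1  (closed form)
        log_i = 8 * np.log(sb.r_o) + betaln(5, 4)
        radial_int = np.exp(log_i) / radial_norm(1, sb.r_o)
        amplitude = q / (4 * np.pi * radial_int)
        disp = grid.displacements(pos)
        r = np.linalg.norm(disp, axis=1)
        values += amplitude * radial_raw(1, r, sb.r_o)
    return DensityField(grid, values, kind="atomic")
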