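"""Rotation/reflection invariants of projection coefficients.

The raw projection coefficients c_nlm transform covariantly under rotations
of the density and geometry (each m-block mixes under a Wigner matrix).  The
diagonal power spectrum

    d_nl = sum_{m=-l}^{l} c_nlm^2

is invariant under all rotations and reflections, and is what the atomic
networks consume.  The backward transformation of energy derivatives is the
chain rule  dE/dc_nlm = 2 * (dE/dd_nl) * c_nlm,  which is what makes the
machine-learned potential assemblable in the original basis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import BasisIndex, ProjectionOperator


@dataclass
class DescriptorSet:
    """Per-atom projection coefficients and their rotational invariants.

    ``coeffs[a]`` is atom ``a``'s c_nlm block in canonical (n, l, m) order;
    ``invariants[a]`` the d_nl block in (n, l) order.  The species list and
    basis hash travel along so models can verify compatibility.
    """

    species: list[str]
    coeffs: list[np.ndarray]
    invariants: list[np.ndarray]
    nl_shapes: list[list[tuple[int, int]]]
    basis_hash: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def natoms(self) -> int:
        return len(self.species)

    def stacked_invariants(self, species: str) -> np.ndarray:
        """(n_atoms_of_species, n_features) matrix of d_nl blocks."""
        rows = [self.invariants[a] for a in range(self.natoms)
                if self.species[a] == species]
        return np.stack(rows) if rows else np.empty((0, 0))


def _nl_layout(index: list[BasisIndex], atom: int):
    """(n, l) blocks of one atom in canonical order, with m-multiplicities."""
    layout = []
    for b in index:
        if b.atom != atom:
            continue
        if not layout or layout[-1] != (b.n, b.l):
            layout.append((b.n, b.l))
    return layout


def symmetrize_block(c_block: np.ndarray,
                     nl_layout: list[tuple[int, int]]) -> np.ndarray:
    """Power spectrum of one atom's coefficient block.

    ``c_block`` holds c_nlm in canonical order; each (n, l) contributes one
    invariant summing the squares of its 2l+1 entries.
    """
    expected = sum(2 * l + 1 for _, l in nl_layout)
    if c_block.shape[0] != expected:
        raise ValueError(
            f"coefficient block has {c_block.shape[0]} entries, layout "
            f"requires {expected} (incomplete m-block?)")
    out = np.empty(len(nl_layout))
    pos = 0
    for i, (_, l) in enumerate(nl_layout):
        width = 2 * l + 1
        out[i] = np.sum(c_block[pos:pos + width] ** 2)
        pos += width
    return out


def chain_rule_block(dE_dd: np.ndarray, c_block: np.ndarray,
                     nl_layout: list[tuple[int, int]]) -> np.ndarray:
    """Back-transform dE/dd_nl to dE/dc_nlm = 2 * dE/dd_nl * c_nlm."""
    if dE_dd.shape[0] != len(nl_layout):
        raise ValueError("gradient/layout shape mismatch")
    expected = sum(2 * l + 1 for _, l in nl_layout)
    if c_block.shape[0] != expected:
        raise ValueError("coefficient/layout shape mismatch")
    out = np.empty_like(c_block)
    pos = 0
    for i, (_, l) in enumerate(nl_layout):
        width = 2 * l + 1
        out[pos:pos + width] = 2.0 * dE_dd[i] * c_block[pos:pos + width]
        pos += width
    return out


def symmetrize(projector: ProjectionOperator,
               coefficients: np.ndarray) -> DescriptorSet:
    """Split a flat c_beta vector per atom and compute all invariants."""
    coefficients = np.asarray(coefficients, dtype=float).ravel()
    if coefficients.shape[0] != projector.n_beta:
        raise ValueError("coefficient vector does not match projector size")
    species, coeffs, invars, layouts = [], [], [], []
    for a in range(projector.system.natoms):
        sl = projector.atom_slice(a)
        layout = _nl_layout(projector.index, a)
        block = coefficients[sl]
        species.append(projector.system.species[a])
        coeffs.append(block)
        invars.append(symmetrize_block(block, layout))
        layouts.append(layout)
    return DescriptorSet(species, coeffs, invars, layouts,
                         basis_hash=projector.basis_hash)


def chain_rule_back(descriptors: DescriptorSet,
                    dE_dd: list[np.ndarray]) -> np.ndarray:
    """Flat dE/dc_beta vector from per-atom dE/dd_nl blocks."""
    if len(dE_dd) != descriptors.natoms:
        raise ValueError("per-atom gradient count mismatch")
    parts = [chain_rule_block(np.asarray(g, dtype=float),
                              descriptors.coeffs[a],
                              descriptors.nl_shapes[a])
             for a, g in enumerate(dE_dd)]
    return np.concatenate(parts)
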