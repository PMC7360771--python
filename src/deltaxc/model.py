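"""The machine-learned energy functional and its potential.

An :class:`EnergyModel` couples a per-species preprocessing pipeline
(variance mask, standardization, principal-axis truncation) to a per-species
atomic network.  The energy is a sum of atomic contributions

    E_ML[rho] = sum_I eps_{species(I)}(d_I),

so reordering same-species atoms cannot change it.  Because the projection
coefficients are linear functionals of the density, the functional derivative
of E_ML is a finite linear combination of the basis functions,

    V_ML(r) = sum_beta (dE_ML/dc_beta) psi_beta(r),

with the coefficients obtained by exact backpropagation through the network,
the pipeline, and the power-spectrum symmetrization.  Models trained on the
neutral difference density delta-rho carry a flag; the potential assembly is
unchanged because delta-rho differs from rho by a density-independent field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import ProjectionOperator, project_density
from .density import DensityField, delta_density
from .basis import atomic_reference_density
from .grids import Grid
from .network import AtomicNetwork
from .symmetry import DescriptorSet, chain_rule_back, symmetrize


class CoverageError(KeyError):
    """A descriptor species is not covered by the model."""


class IntegrityError(ValueError):
    """Model and descriptors were produced with different bases."""


@dataclass
class Pipeline:
    """Affine preprocessing of raw invariants for one species.

    x = P^T ((d[mask] - mean) / scale), where P holds the retained principal
    axes as columns.  Being affine, its exact input-Jacobian is available in
    closed form for the potential path.
    """

    mask: np.ndarray          # (n_raw,) bool
    mean: np.ndarray          # (n_kept,)
    scale: np.ndarray         # (n_kept,)
    components: np.ndarray    # (n_kept, n_out) principal axes as columns

    @property
    def n_raw(self) -> int:
        return self.mask.shape[0]

    @property
    def n_out(self) -> int:
        return self.components.shape[1]

    def transform(self, D: np.ndarray) -> np.ndarray:
        D = np.atleast_2d(D)
        if D.shape[1] != self.n_raw:
            raise IntegrityError(
                f"feature dimension {D.shape[1]} does not match pipeline "
                f"({self.n_raw})")
        return ((D[:, self.mask] - self.mean) / self.scale) @ self.components

    def backward(self, G: np.ndarray) -> np.ndarray:
        """Pull gradients w.r.t. pipeline outputs back to raw invariants."""
        G = np.atleast_2d(G)
        out = np.zeros((G.shape[0], self.n_raw))
        out[:, self.mask] = (G @ self.components.T) / self.scale
        return out

    @classmethod
    def identity(cls, n: int) -> "Pipeline":
        return cls(np.ones(n, dtype=bool), np.zeros(n), np.ones(n), np.eye(n))


@dataclass
class EnergyModel:
    """Preprocessing pipelines + atomic networks for each species."""

    pipelines: dict[str, Pipeline]
    networks: dict[str, AtomicNetwork]
    basis_hash: str = ""
    use_delta: bool = True
    meta: dict = field(default_factory=dict)

    @property
    def species(self) -> list[str]:
        return sorted(self.networks)

    def _check(self, descriptors: DescriptorSet) -> None:
        missing = set(descriptors.species) - set(self.networks)
        if missing:
            raise CoverageError(
                f"model does not cover species {sorted(missing)}")
        if self.basis_hash and descriptors.basis_hash and \
                self.basis_hash != descriptors.basis_hash:
            raise IntegrityError(
                "descriptor basis hash does not match the model's "
                f"({descriptors.basis_hash} != {self.basis_hash})")

    def energy(self, descriptors: DescriptorSet) -> float:
        """E_ML as the sum of atomic network outputs, Hartree."""
        self._check(descriptors)
        total = 0.0
        for sym in sorted(set(descriptors.species)):
            D = descriptors.stacked_invariants(sym)
            X = self.pipelines[sym].transform(D)
            total += float(self.networks[sym].predict(X).sum())
        return total

    def gradient(self, descriptors: DescriptorSet) -> list[np.ndarray]:
        """Exact dE_ML/dd_nl per atom, back through the pipeline."""
        self._check(descriptors)
        out: list[np.ndarray] = [None] * descriptors.natoms
        for sym in sorted(set(descriptors.species)):
            atoms = [a for a in range(descriptors.natoms)
                     if descriptors.species[a] == sym]
            D = np.stack([descriptors.invariants[a] for a in atoms])
            pipe = self.pipelines[sym]
            G = self.networks[sym].grad_input(pipe.transform(D))
            raw = pipe.backward(G)
            for row, a in enumerate(atoms):
                out[a] = raw[row]
        return out


@dataclass
class PotentialField:
    """V_ML tabulated on a grid together with its basis coefficients."""

    grid: Grid
    values: np.ndarray
    coefficients: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.shape[0] != self.grid.npoints:
            raise ValueError("potential values do not match grid size")


def descriptors_from_density(projector: ProjectionOperator,
                             density: DensityField,
                             use_delta: bool = False) -> DescriptorSet:
    """Project (optionally neutralized) density and symmetrize."""
    if use_delta and density.kind == "full":
        rho_atm = atomic_reference_density(projector.system, projector.spec,
                                           projector.grid)
        density = delta_density(density, rho_atm)
    c = project_density(projector, density)
    return symmetrize(projector, c)


def model_energy(model: EnergyModel, descriptors: DescriptorSet) -> float:
    return model.energy(descriptors)


def model_gradient(model: EnergyModel,
                   descriptors: DescriptorSet) -> list[np.ndarray]:
    return model.gradient(descriptors)


def assemble_potential(dE_dc: np.ndarray,
                       projector: ProjectionOperator) -> PotentialField:
    """V_ML = sum_beta (dE/dc_beta) psi_beta on the projector's grid."""
    dE_dc = np.asarray(dE_dc, dtype=float).ravel()
    if dE_dc.shape[0] != projector.n_beta:
        raise IntegrityError(
            f"coefficient vector length {dE_dc.shape[0]} does not match "
            f"projector ({projector.n_beta})")
    values = dE_dc @ projector.values
    return PotentialField(projector.grid, values, coefficients=dE_dc)


def ml_potential(model: EnergyModel, projector: ProjectionOperator,
                 density: DensityField) -> tuple[float, PotentialField]:
    """Energy and potential of the ML correction at the given density."""
    desc = descriptors_from_density(projector, density, model.use_delta)
    energy = model.energy(desc)
    dE_dd = model.gradient(desc)
    dE_dc = chain_rule_back(desc, dE_dd)
    return energy, assemble_potential(dE_dc, projector)


def compose_nxc(E_base: float, V_base, E_ml: float,
                V_ml: PotentialField) -> tuple[float, PotentialField]:
    """Additive composition with the baseline functional.

    In the null limit (zero correction) the composed functional reproduces
    the baseline exactly.
    """
    base_vals = V_base.values if isinstance(V_base, PotentialField) \
        else np.asarray(V_base, dtype=float).ravel()
    if base_vals.shape[0] != V_ml.grid.npoints:
        raise ValueError("baseline and ML potentials live on different grids")
    return E_base + E_ml, PotentialField(V_ml.grid, base_vals + V_ml.values)
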