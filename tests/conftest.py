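"""Shared fixtures: a small synthetic study world.

Everything is generated programmatically; the expensive pieces (projectors,
small datasets) are session-scoped so the suite builds them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from deltaxc.basis import build_projector
from deltaxc.model import descriptors_from_density
from deltaxc.synth import SyntheticSpec, generate_dataset
from deltaxc.system import AtomicSystem, BasisSpec


@pytest.fixture(scope="session")
def synth_spec() -> SyntheticSpec:
    """The seeded study conditions used throughout the suite."""
    return SyntheticSpec(seed=11)


@pytest.fixture(scope="session")
def basis(synth_spec) -> BasisSpec:
    return synth_spec.basis()


@pytest.fixture(scope="session")
def water_like(synth_spec) -> AtomicSystem:
    """The undeformed bent three-atom base geometry."""
    return AtomicSystem(list(synth_spec.species), synth_spec.base_positions)


@pytest.fixture(scope="session")
def projector(water_like, basis, synth_spec):
    return build_projector(water_like, basis, synth_spec.grid_for(water_like))


@pytest.fixture(scope="session")
def small_dataset(synth_spec, basis):
    """30 samples with descriptors; enough for unit-level training checks."""
    samples, _ = generate_dataset(synth_spec, 30)
    factory = lambda sysm, g: build_projector(sysm, basis, g)  # noqa: E731
    desc = [descriptors_from_density(factory(s.system, s.density.grid),
                                     s.density, use_delta=True)
            for s in samples]
    targets = np.array([s.target for s in samples])
    return samples, desc, targets


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random proper rotation."""
    Q, R = np.linalg.qr(rng.normal(size=(3, 3)))
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1.0
    return Q
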