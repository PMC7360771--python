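"""Energy functional, exact gradients, potential assembly, and moments."""

import numpy as np
import pytest

from deltaxc.basis import build_projector, project_density
from deltaxc.density import DensityField
from deltaxc.grids import cube_grid
from deltaxc.model import (CoverageError, EnergyModel, IntegrityError,
                           Pipeline, assemble_potential, compose_nxc,
                           descriptors_from_density, ml_potential,
                           model_energy, model_gradient)
from deltaxc.moments import density_moments
from deltaxc.network import AtomicNetwork
from deltaxc.symmetry import chain_rule_back, symmetrize
from deltaxc.synth import density_params, evaluate_density
from deltaxc.system import AtomicSystem, BasisSpec
from deltaxc.units import DEBYE_PER_EBOHR

from conftest import random_rotation


def _random_model(rng, n_in, species, hidden=(6,), basis_hash=""):
    nets, pipes = {}, {}
    for sym in species:
        nets[sym] = AtomicNetwork(n_in, list(hidden), rng)
        pipes[sym] = Pipeline.identity(n_in)
    return EnergyModel(pipelines=pipes, networks=nets, basis_hash=basis_hash,
                       use_delta=False)


@pytest.fixture()
def descriptors(projector, synth_spec, water_like):
    rho = evaluate_density(water_like, density_params(synth_spec, 0),
                           projector.grid)
    return descriptors_from_density(projector, rho, use_delta=False)


class TestEnergy:
    def test_zero_head_gives_zero_energy(self, descriptors):
        rng = np.random.default_rng(0)
        model = _random_model(rng, 12, {"O", "H"})
        for net in model.networks.values():
            net.weights[-1][:] = 0.0
            net.biases[-1][:] = 0.0
        assert model_energy(model, descriptors) == 0.0

    def test_additivity_over_identical_atoms(self):
        sys2 = AtomicSystem(["H", "H"], [[0.0, 0, 0], [5.0, 0, 0]])
        spec = BasisSpec.uniform(["H"], 3, 1, 1.5)
        from deltaxc.grids import union_descriptor_grid
        g2 = union_descriptor_grid(sys2.positions, 1.5)
        proj2 = build_projector(sys2, spec, g2)
        s = 0.2
        one = np.exp(-((g2.points) ** 2).sum(axis=1) / (2 * s * s))
        two = np.exp(-((g2.points - [5.0, 0, 0]) ** 2).sum(axis=1)
                     / (2 * s * s))
        rho2 = DensityField(g2, one + two)
        ds2 = descriptors_from_density(proj2, rho2, use_delta=False)

        sys1 = AtomicSystem(["H"], [[0.0, 0, 0]])
        g1 = union_descriptor_grid(sys1.positions, 1.5)
        proj1 = build_projector(sys1, spec, g1)
        rho1 = DensityField(g1, np.exp(-((g1.points) ** 2).sum(axis=1)
                                       / (2 * s * s)))
        ds1 = descriptors_from_density(proj1, rho1, use_delta=False)

        model = _random_model(np.random.default_rng(1), 6, {"H"})
        assert model_energy(model, ds2) == pytest.approx(
            2 * model_energy(model, ds1), rel=1e-10)

    def test_permutation_invariance(self, projector, synth_spec, water_like,
                                    basis, descriptors):
        model = _random_model(np.random.default_rng(2), 12, {"O", "H"})
        e0 = model_energy(model, descriptors)
        # swap the two light atoms (geometry and density together)
        perm = [0, 2, 1]
        sys_p = AtomicSystem([water_like.species[i] for i in perm],
                             water_like.positions[perm])
        params = density_params(synth_spec, 0)
        from deltaxc.synth import GaussianParams
        params_p = GaussianParams(params.sigmas[perm],
                                  params.rotations[perm],
                                  params.weights[perm])
        grid = synth_spec.grid_for(sys_p)
        proj_p = build_projector(sys_p, basis, grid)
        rho_p = evaluate_density(sys_p, params_p, grid)
        ds_p = descriptors_from_density(proj_p, rho_p, use_delta=False)
        e1 = model_energy(model, ds_p)
        assert e1 == pytest.approx(e0, rel=1e-12)

    def test_rotational_invariance(self, synth_spec, basis, water_like,
                                   descriptors):
        model = _random_model(np.random.default_rng(3), 12, {"O", "H"})
        e0 = model_energy(model, descriptors)
        R = random_rotation(np.random.default_rng(17))
        from deltaxc.synth import rotate_params
        sys_r = water_like.rotated(R)
        params_r = rotate_params(density_params(synth_spec, 0), R)
        grid = synth_spec.grid_for(sys_r)
        proj_r = build_projector(sys_r, basis, grid)
        rho_r = evaluate_density(sys_r, params_r, grid)
        e1 = model_energy(model, descriptors_from_density(
            proj_r, rho_r, use_delta=False))
        assert e1 == pytest.approx(e0, rel=1e-6)

    def test_unknown_species_raises(self, descriptors):
        model = _random_model(np.random.default_rng(0), 12, {"O"})
        with pytest.raises(CoverageError):
            model_energy(model, descriptors)

    def test_basis_hash_mismatch_raises(self, descriptors):
        model = _random_model(np.random.default_rng(0), 12, {"O", "H"},
                              basis_hash="deadbeef")
        with pytest.raises(IntegrityError):
            model_energy(model, descriptors)


class TestGradient:
    def test_constant_model_zero_gradient(self, descriptors):
        model = _random_model(np.random.default_rng(4), 12, {"O", "H"})
        for net in model.networks.values():
            net.weights[-1][:] = 0.0
            net.biases[-1][:] = 42.0
        for g in model_gradient(model, descriptors):
            assert np.all(g == 0.0)

    def test_linear_model_gradient_is_coefficients(self, descriptors):
        # E = sum_nl a_nl d_nl through an identity pipeline
        rng = np.random.default_rng(5)
        a = rng.normal(size=12)
        model = _random_model(rng, 12, {"O", "H"}, hidden=())
        for net in model.networks.values():
            net.weights[-1][:] = a
            net.biases[-1][:] = 0.0
        for g in model_gradient(model, descriptors):
            assert np.allclose(g, a, rtol=1e-14)

    def test_matches_finite_differences(self, descriptors):
        model = _random_model(np.random.default_rng(6), 12, {"O", "H"},
                              hidden=(5, 4))
        grads = model_gradient(model, descriptors)
        h = 1e-5
        for a in (0, 1):
            for j in (0, 3, 11):
                dp = [inv.copy() for inv in descriptors.invariants]
                dm = [inv.copy() for inv in descriptors.invariants]
                dp[a][j] += h
                dm[a][j] -= h
                from dataclasses import replace
                ep = model.energy(replace(descriptors, invariants=dp))
                em = model.energy(replace(descriptors, invariants=dm))
                fd = (ep - em) / (2 * h)
                assert grads[a][j] == pytest.approx(fd, rel=1e-6, abs=1e-10)

    def test_gradient_through_fitted_pipeline(self, small_dataset):
        # masking + scaling + PCA truncation must be differentiated exactly
        from deltaxc.training import TrainingConfig, train_once
        samples, desc, targets = small_dataset
        cfg = TrainingConfig(hidden=(4,), max_epochs=50, gamma=0.95, seed=0)
        model, _ = train_once(desc, targets, cfg)
        grads = model.gradient(desc[0])
        h = 1e-6
        from dataclasses import replace
        for a, j in [(0, 0), (1, 5), (2, 11)]:
            dp = [inv.copy() for inv in desc[0].invariants]
            dm = [inv.copy() for inv in desc[0].invariants]
            dp[a][j] += h
            dm[a][j] -= h
            fd = (model.energy(replace(desc[0], invariants=dp))
                  - model.energy(replace(desc[0], invariants=dm))) / (2 * h)
            assert grads[a][j] == pytest.approx(fd, rel=5e-5, abs=1e-9)


class TestPotential:
    def test_zero_derivatives_zero_potential(self, projector):
        pot = assemble_potential(np.zeros(projector.n_beta), projector)
        assert np.all(pot.values == 0.0)

    def test_single_basis_function(self, projector):
        w = np.zeros(projector.n_beta)
        w[17] = -0.37
        pot = assemble_potential(w, projector)
        assert np.allclose(pot.values, -0.37 * projector.values[17],
                           rtol=1e-14)

    def test_tabulation_matches_coefficients(self, projector):
        rng = np.random.default_rng(7)
        w = rng.normal(size=projector.n_beta)
        pot = assemble_potential(w, projector)
        expect = w @ projector.values
        assert np.allclose(pot.values, expect, rtol=1e-10)

    def test_size_mismatch_raises(self, projector):
        with pytest.raises(IntegrityError):
            assemble_potential(np.zeros(projector.n_beta - 1), projector)

    def test_support_confined_to_cutoff_spheres(self, water_like, basis):
        g = cube_grid(water_like.positions.mean(axis=0), 12.0, 20)
        proj = build_projector(water_like, basis, g)
        rng = np.random.default_rng(8)
        pot = assemble_potential(rng.normal(size=proj.n_beta), proj)
        outside = np.ones(g.npoints, dtype=bool)
        for sym, pos in zip(water_like.species, water_like.positions):
            outside &= np.linalg.norm(g.points - pos, axis=1) >= \
                basis[sym].r_o
        assert outside.any()
        assert np.all(pot.values[outside] == 0.0)

    @pytest.mark.parametrize("shape_seed", [0, 1, 2])
    def test_directional_derivative_order(self, projector, synth_spec,
                                          water_like, shape_seed):
        """E_ML[rho + eps*drho] - E_ML[rho] = eps * int V_ML drho + O(eps^2);
        the remainder must shrink quadratically in eps."""
        rho = evaluate_density(water_like, density_params(synth_spec, 0),
                               projector.grid)
        model = _random_model(np.random.default_rng(9), 12, {"O", "H"},
                              hidden=(6,))
        e0, pot = ml_potential(model, projector, rho)
        # smooth perturbation confined to the heavy atom's cutoff sphere
        rng = np.random.default_rng(shape_seed)
        d = np.linalg.norm(projector.grid.points - water_like.positions[0],
                           axis=1)
        r_o = synth_spec.r_o
        envelope = np.where(d < r_o, (r_o ** 2 - d ** 2) ** 2, 0.0)
        coeffs = rng.normal(size=3)
        drho = envelope * (coeffs[0]
                           + coeffs[1] * projector.grid.points[:, 0]
                           + coeffs[2] * d)
        linear = projector.grid.integrate(pot.values * drho)
        remainders = []
        for eps in (1e-3, 1e-4):
            rho_eps = DensityField(projector.grid,
                                   rho.values + eps * drho)
            e_eps = model.energy(descriptors_from_density(
                projector, rho_eps, use_delta=False))
            remainders.append(abs(e_eps - e0 - eps * linear))
        order = np.log10(remainders[0] / remainders[1])
        assert order >= 1.9


class TestComposition:
    def test_null_correction_reproduces_baseline(self, projector):
        v_base = np.sin(projector.grid.points[:, 0])
        zero = assemble_potential(np.zeros(projector.n_beta), projector)
        e, v = compose_nxc(-12.5, v_base, 0.0, zero)
        assert e == -12.5
        assert np.array_equal(v.values, v_base)

    def test_additivity_of_halves(self, projector):
        rng = np.random.default_rng(10)
        w = rng.normal(size=projector.n_beta)
        v_base = rng.normal(size=projector.grid.npoints)
        full = assemble_potential(w, projector)
        half = assemble_potential(0.5 * w, projector)
        e1, v1 = compose_nxc(1.0, v_base, 2.0, full)
        e2a, v2a = compose_nxc(1.0, v_base, 1.0, half)
        e2, v2 = compose_nxc(e2a, v2a, 1.0, half)
        assert e2 == pytest.approx(e1, rel=1e-14)
        assert np.allclose(v2.values, v1.values, rtol=1e-12)

    def test_grid_mismatch(self, projector):
        zero = assemble_potential(np.zeros(projector.n_beta), projector)
        with pytest.raises(ValueError, match="grid"):
            compose_nxc(0.0, np.zeros(7), 0.0, zero)


class TestMoments:
    def test_symmetric_density_zero_dipole_and_qt(self):
        g = cube_grid((0, 0, 0), 12.0, 40)
        s = 0.8
        rho = DensityField(g, 6.0 * np.exp(
            -(g.points ** 2).sum(axis=1) / (2 * s * s))
            / (2 * np.pi * s * s) ** 1.5)
        sysm = AtomicSystem(["O"], [[0.0, 0.0, 0.0]])
        m = density_moments(rho, sysm)
        assert np.abs(m.dipole).max() < 1e-6
        assert abs(m.q_t) < 1e-6

    def test_displaced_gaussian_dipole_closed_form(self):
        # electron Gaussian (charge q) at z = d, nucleus charge q at origin:
        # dipole = q*d along -z (electrons negative), |mu| = q*d in e*Bohr
        g = cube_grid((0, 0, 1.0), 14.0, 48)
        q, d, s = 2.0, 0.8, 0.6
        rho = DensityField(g, q * np.exp(
            -((g.points - [0, 0, d]) ** 2).sum(axis=1) / (2 * s * s))
            / (2 * np.pi * s * s) ** 1.5)
        sysm = AtomicSystem(["X"], [[0.0, 0.0, 0.0]],
                            valence_charges={"X": q})
        m = density_moments(rho, sysm)
        assert m.dipole[2] == pytest.approx(-q * d * DEBYE_PER_EBOHR,
                                            rel=1e-6)
        assert abs(m.dipole[0]) < 1e-8 and abs(m.dipole[1]) < 1e-8

    def test_qt_rotation_invariant(self):
        rng = np.random.default_rng(11)
        R = random_rotation(rng)
        s = np.array([0.5, 0.7, 1.1])

        def make(Rot):
            g = cube_grid((0, 0, 0), 16.0, 56)
            d = g.points @ Rot
            rho = 4.0 * np.exp(-0.5 * (d ** 2 / s ** 2).sum(axis=1)) \
                / ((2 * np.pi) ** 1.5 * s.prod())
            sysm = AtomicSystem(["X"], [[0.0, 0.0, 0.0]],
                                valence_charges={"X": 4.0})
            return density_moments(DensityField(g, rho), sysm)

        m0 = make(np.eye(3))
        m1 = make(R)
        assert m1.q_t == pytest.approx(m0.q_t, abs=1e-8)

    def test_charged_system_warns_but_returns(self):
        g = cube_grid((0, 0, 0), 10.0, 24)
        s = 0.7
        rho = DensityField(g, np.exp(-(g.points ** 2).sum(axis=1)
                                     / (2 * s * s))
                           / (2 * np.pi * s * s) ** 1.5)
        with pytest.warns(UserWarning, match="net charge"):
            m = density_moments(rho, None, origin=(0.5, 0, 0))
        assert np.isfinite(m.dipole).all()
        assert np.allclose(m.origin, [0.5, 0, 0])


class TestSerialization:
    def test_round_trip_energies_identical(self, small_dataset, tmp_path,
                                           basis):
        from deltaxc.io import load_model, save_model
        from deltaxc.training import TrainingConfig, train_once
        samples, desc, targets = small_dataset
        cfg = TrainingConfig(hidden=(5,), max_epochs=60, gamma=0.98, seed=1)
        model, _ = train_once(desc, targets, cfg,
                              basis_hash=basis.content_hash())
        path = tmp_path / "model.h5"
        save_model(path, model, config_hash_="abc123")
        loaded = load_model(path)
        assert loaded.basis_hash == model.basis_hash
        assert loaded.use_delta == model.use_delta
        assert loaded.meta["config_hash"] == "abc123"
        for ds in desc:
            e0, e1 = model.energy(ds), loaded.energy(ds)
            assert abs(e1 - e0) <= 1e-15 * max(1.0, abs(e0))
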