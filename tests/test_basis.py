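"""Radial basis, spherical harmonics, projector, and projection identities."""

import numpy as np
import pytest
from scipy.special import betaln

from deltaxc.basis import (atomic_reference_density, build_projector,
                           orthogonalize_radial, project_density, radial_norm,
                           radial_raw, raw_radial_overlap, real_sph_harm)
from deltaxc.density import DensityField, delta_density
from deltaxc.grids import angular_rule, uniform_grid, union_descriptor_grid
from deltaxc.synth import density_params, evaluate_density
from deltaxc.system import AtomicSystem, BasisSpec


# ---------------------------------------------------------------------------
# radial functions
# ---------------------------------------------------------------------------

class TestRadial:
    def test_boundary_values_are_exactly_zero(self):
        assert radial_raw(1, 2.5, 2.5, normalization=1.0) == 0.0
        assert radial_raw(1, 0.0, 2.5, normalization=1.0) == 0.0
        assert radial_raw(3, 5.0, 2.5, normalization=1.0) == 0.0  # beyond r_o

    def test_printed_formula_value(self):
        # (1/N) r^2 (r_o - r)^(n+2) at n=2, r=1, r_o=2, N=1
        assert radial_raw(2, 1.0, 2.0, normalization=1.0) == pytest.approx(1.0)

    def test_continuity_at_cutoff(self):
        eps = 1e-9
        assert radial_raw(1, 2.5 - eps, 2.5) < 1e-20

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            radial_raw(1, -0.1, 2.0)
        with pytest.raises(ValueError):
            radial_raw(1, 0.5, -2.0)
        with pytest.raises(ValueError):
            radial_raw(0, 0.5, 2.0)

    def test_default_normalization_is_unit_l2(self):
        r_o = 1.7
        r, w = np.polynomial.legendre.leggauss(60)
        r = 0.5 * r_o * (r + 1.0)
        w = 0.5 * r_o * w
        for n in (1, 2, 5):
            z = radial_raw(n, r, r_o)
            assert (z ** 2 * r ** 2) @ w == pytest.approx(1.0, abs=1e-12)


class TestOrthogonalization:
    def test_single_function_is_normalization(self):
        M = orthogonalize_radial(1, 2.0)
        # raw functions are already unit-norm, so the 1x1 matrix is 1
        assert M.shape == (1, 1)
        assert M[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_loewdin_whitens_raw_overlap(self):
        for n_max, r_o in [(3, 1.5), (5, 2.5)]:
            M = orthogonalize_radial(n_max, r_o)
            S = raw_radial_overlap(n_max, r_o)
            assert np.abs(M @ S @ M.T - np.eye(n_max)).max() < 1e-10

    def test_overlap_matches_beta_integral_oracle(self):
        # independent closed form: int_0^R r^6 (R-r)^(k+n+4) dr
        #                          = R^(k+n+11) * B(7, k+n+5)
        n_max, r_o = 4, 2.2
        S = raw_radial_overlap(n_max, r_o)
        for k in range(1, n_max + 1):
            for n in range(1, n_max + 1):
                log_i = (k + n + 11) * np.log(r_o) + betaln(7, k + n + 5)
                expect = np.exp(log_i) / (radial_norm(k, r_o)
                                          * radial_norm(n, r_o))
                assert S[k - 1, n - 1] == pytest.approx(expect, rel=1e-12)

    def test_high_order_quadrature_oracle(self):
        M = orthogonalize_radial(5, 2.5)
        r, w = np.polynomial.legendre.leggauss(200)   # overkill rule
        r = 0.5 * 2.5 * (r + 1.0)
        w = 0.5 * 2.5 * w
        Z = M @ np.stack([radial_raw(n, r, 2.5) for n in range(1, 6)])
        G = (Z * (w * r ** 2)) @ Z.T
        assert np.abs(G - np.eye(5)).max() < 1e-10

    def test_conditioning_error(self):
        with pytest.raises(np.linalg.LinAlgError, match="condition"):
            orthogonalize_radial(12, 2.0, cond_limit=1e6)


# ---------------------------------------------------------------------------
# real spherical harmonics
# ---------------------------------------------------------------------------

class TestHarmonics:
    def test_constant_harmonic(self):
        assert real_sph_harm(0, 0, np.array([0.3, -0.4, 0.5])) == \
            pytest.approx(1.0 / np.sqrt(4 * np.pi))

    def test_l1_m0_along_z(self):
        assert real_sph_harm(1, 0, np.array([0.0, 0.0, 1.0])) == \
            pytest.approx(np.sqrt(3 / (4 * np.pi)))

    def test_gram_matrix_identity_to_l4(self):
        dirs, w = angular_rule(12, 25)
        Y = np.array([real_sph_harm(l, m, dirs)
                      for l in range(5) for m in range(-l, l + 1)])
        G = (Y * w) @ Y.T
        assert np.abs(G - np.eye(25)).max() < 1e-10

    def test_domain_error(self):
        with pytest.raises(ValueError):
            real_sph_harm(1, 2, np.array([0.0, 0.0, 1.0]))


# ---------------------------------------------------------------------------
# projector
# ---------------------------------------------------------------------------

class TestProjector:
    def test_function_count(self):
        sys1 = AtomicSystem(["O"], [[0.0, 0.0, 0.0]])
        spec = BasisSpec.uniform(["O"], 2, 1, 1.0)
        g = union_descriptor_grid(sys1.positions, 1.0)
        proj = build_projector(sys1, spec, g)
        assert proj.n_beta == 2 * (1 + 3)

    def test_canonical_index_order(self, projector):
        first = [(b.n, b.l, b.m) for b in projector.index[:9]]
        assert first == [(1, 0, 0), (1, 1, -1), (1, 1, 0), (1, 1, 1),
                         (1, 2, -2), (1, 2, -1), (1, 2, 0), (1, 2, 1),
                         (1, 2, 2)]

    def test_per_atom_orthonormality(self, projector):
        for a in range(projector.system.natoms):
            G = projector.gram(a)
            assert np.abs(G - np.eye(G.shape[0])).max() < 1e-6

    def test_compact_support(self, projector):
        r_o = projector.spec["O"].r_o
        sl = projector.atom_slice(0)
        d = np.linalg.norm(projector.grid.points
                           - projector.system.positions[0], axis=1)
        outside = d >= r_o
        assert np.all(projector.values[sl][:, outside] == 0.0)

    def test_translational_covariance(self, water_like, basis, synth_spec):
        shift = np.array([1.3, -0.7, 2.1])
        g = synth_spec.grid_for(water_like)
        p0 = build_projector(water_like, basis, g)
        p1 = build_projector(water_like.translated(shift), basis,
                             g.translated(shift))
        assert np.abs(p0.values - p1.values).max() < 1e-10

    def test_periodic_minimum_image_wraps(self):
        # atom near the cell face: its cutoff sphere wraps around
        L, n = 6.0, 54
        sys1 = AtomicSystem(["O"], [[0.05, 3.0, 3.0]])
        spec = BasisSpec.uniform(["O"], 2, 1, 1.3)
        h = L / n
        gper = uniform_grid((h / 2, h / 2, h / 2), np.eye(3) * h, (n, n, n),
                            periodic=True)
        proj = build_projector(sys1, spec, gper)
        # aperiodic oracle: same atom centered in an uncut box
        sys2 = AtomicSystem(["O"], [[3.0, 3.0, 3.0]])
        gape = uniform_grid((h / 2, h / 2, h / 2), np.eye(3) * h, (n, n, n))
        oracle = build_projector(sys2, spec, gape)
        assert proj.gram(0)[0, 0] == pytest.approx(oracle.gram(0)[0, 0],
                                                   abs=1e-4)
        assert proj.gram(0)[0, 0] == pytest.approx(1.0, abs=1e-3)

    def test_cutoff_exceeding_half_cell_is_ambiguous(self):
        sys1 = AtomicSystem(["O"], [[0.0, 0.0, 0.0]])
        spec = BasisSpec.uniform(["O"], 1, 0, 3.5)
        g = uniform_grid((0, 0, 0), np.eye(3) * 0.5, (12, 12, 12),
                         periodic=True)
        with pytest.raises(ValueError, match="minimum-image"):
            build_projector(sys1, spec, g)


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

class TestProjection:
    def test_zero_density(self, projector):
        rho = DensityField(projector.grid,
                           np.zeros(projector.grid.npoints), kind="neutral")
        assert np.all(project_density(projector, rho) == 0.0)

    def test_recovers_known_coefficients(self, projector):
        rho = DensityField(projector.grid,
                           0.7 * projector.values[3]
                           + 0.2 * projector.values[40], kind="neutral")
        c = project_density(projector, rho)
        assert c[3] == pytest.approx(0.7, abs=1e-6)
        assert c[40] == pytest.approx(0.2, abs=1e-6)
        others = np.delete(c, [3, 40])
        assert np.abs(others).max() < 1e-6

    def test_linearity_exact(self, projector, synth_spec, water_like):
        rho1 = evaluate_density(water_like,
                                density_params(synth_spec, 0),
                                projector.grid)
        rho2 = evaluate_density(water_like,
                                density_params(synth_spec, 1),
                                projector.grid)
        mix = DensityField(projector.grid,
                           0.25 * rho1.values + 2.0 * rho2.values)
        c = project_density(projector, mix)
        expect = (0.25 * project_density(projector, rho1)
                  + 2.0 * project_density(projector, rho2))
        assert np.allclose(c, expect, rtol=0, atol=1e-13)

    def test_locality_outside_cutoffs(self, water_like, basis):
        # a cube grid has points outside every cutoff sphere; perturbing the
        # density there must change no coefficient
        from deltaxc.grids import cube_grid
        g = cube_grid(water_like.positions.mean(axis=0), 12.0, 24)
        proj = build_projector(water_like, basis, g)
        rng = np.random.default_rng(4)
        rho = DensityField(g, rng.random(g.npoints))
        c0 = project_density(proj, rho)
        outside = np.ones(g.npoints, dtype=bool)
        for sym, pos in zip(water_like.species, water_like.positions):
            d = np.linalg.norm(g.points - pos, axis=1)
            outside &= d >= basis[sym].r_o
        assert outside.any()
        vals = rho.values.copy()
        vals[outside] += 37.0
        c1 = project_density(proj, DensityField(g, vals))
        assert np.array_equal(c0, c1)

    def test_grid_mismatch_raises(self, projector):
        small = union_descriptor_grid(np.zeros((1, 3)), 1.0)
        rho = DensityField(small, np.zeros(small.npoints))
        with pytest.raises(ValueError, match="grid"):
            project_density(projector, rho)


# ---------------------------------------------------------------------------
# atomic reference density / delta density
# ---------------------------------------------------------------------------

class TestAtomicReference:
    def test_single_atom_integral(self):
        sys1 = AtomicSystem(["O"], [[0.0, 0.0, 0.0]])
        spec = BasisSpec.uniform(["O"], 3, 1, 1.4)
        g = union_descriptor_grid(sys1.positions, 1.4)
        ratm = atomic_reference_density(sys1, spec, g)
        assert ratm.nelec == pytest.approx(6.0, rel=1e-10)

    def test_each_sphere_holds_its_valence(self):
        sys2 = AtomicSystem(["H", "H"], [[0.0, 0, 0], [8.0, 0, 0]])
        spec = BasisSpec.uniform(["H"], 2, 0, 1.2)
        g = union_descriptor_grid(sys2.positions, 1.2)
        ratm = atomic_reference_density(sys2, spec, g)
        in_first = np.linalg.norm(g.points, axis=1) < 1.2
        q0 = (g.weights * ratm.values)[in_first].sum()
        assert q0 == pytest.approx(1.0, rel=1e-10)

    def test_water_like_total(self, water_like, basis, synth_spec):
        g = synth_spec.grid_for(water_like)
        ratm = atomic_reference_density(water_like, basis, g)
        assert ratm.nelec == pytest.approx(8.0, rel=1e-6)

    def test_missing_valence_charge(self):
        sys1 = AtomicSystem(["Q?"], [[0.0, 0.0, 0.0]])
        spec = BasisSpec.uniform(["Q?"], 1, 0, 1.0)
        g = union_descriptor_grid(sys1.positions, 1.0)
        with pytest.raises(KeyError, match="valence"):
            atomic_reference_density(sys1, spec, g)


class TestDeltaDensity:
    def test_identical_fields_give_zero(self, water_like, basis, synth_spec):
        g = synth_spec.grid_for(water_like)
        ratm = atomic_reference_density(water_like, basis, g)
        rho = DensityField(g, ratm.values.copy(), kind="full")
        d = delta_density(rho, ratm)
        assert np.all(d.values == 0.0)
        assert d.kind == "neutral"

    def test_integral_is_difference_of_charges(self, water_like, basis,
                                               synth_spec):
        g = synth_spec.grid_for(water_like)
        ratm = atomic_reference_density(water_like, basis, g)
        rho = evaluate_density(water_like, density_params(synth_spec, 3), g)
        d = delta_density(rho, ratm)
        assert d.nelec == pytest.approx(rho.nelec - 8.0, abs=1e-10)

    def test_deformed_molecule_neutral(self, synth_spec, basis):
        from deltaxc.synth import generate_system
        sysm = generate_system(synth_spec, 7)
        g = synth_spec.grid_for(sysm)
        rho = evaluate_density(sysm, density_params(synth_spec, 7), g)
        ratm = atomic_reference_density(sysm, basis, g)
        d = delta_density(rho, ratm)
        assert abs(d.nelec) < 1e-6
        d.validate()

    def test_kind_contract(self, water_like, basis, synth_spec):
        g = synth_spec.grid_for(water_like)
        ratm = atomic_reference_density(water_like, basis, g)
        with pytest.raises(ValueError, match="full"):
            delta_density(ratm, ratm)
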