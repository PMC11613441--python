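import numpy as np
import pytest

from hhpf.field import (
    DensityGrid,
    EnergyFunctionalParams,
    FieldForceProvider,
    Mesh,
    MeshResolutionWarning,
    apply_filter,
    assign_density,
    field_energy,
    two_particle_scan,
    analytic_scan_reference,
)
from hhpf.potentials import GaussianFilterSpec

from conftest import make_gas


class Pts:
    def __init__(self, positions):
        self.positions = np.atleast_2d(positions)


PARAMS = EnergyFunctionalParams(coeff=1.0)


class TestMesh:
    def test_counts_rounded_and_spacing_recomputed(self):
        m = Mesh((1.0, 1.0, 1.3), 0.11)
        assert m.counts == (9, 9, 12)
        np.testing.assert_allclose(m.spacing, [1 / 9, 1 / 9, 1.3 / 12])

    def test_minimum_counts(self):
        assert Mesh((0.1, 0.1, 0.1), 0.2).counts == (4, 4, 4)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            Mesh((1, 1, 1), 0.1, window="spline")


class TestAssignment:
    def test_particle_on_node_gets_full_weight(self):
        m = Mesh((1.0, 1.0, 1.0), 0.125)
        g = assign_density(Pts([[0.25, 0.5, 0.375]]), m)
        phi = g.phi * m.cell_volume
        assert phi[2, 4, 3] == pytest.approx(1.0)
        assert phi.sum() == pytest.approx(1.0)

    def test_cell_center_spreads_eighth_weights(self):
        m = Mesh((1.0, 1.0, 1.0), 0.125)
        g = assign_density(Pts([[0.25 + 0.0625, 0.5 + 0.0625, 0.375 + 0.0625]]), m)
        w = g.phi * m.cell_volume
        nz = w[w > 0]
        assert len(nz) == 8
        np.testing.assert_allclose(nz, 0.125)

    def test_number_conservation_random_gas(self):
        sys_ = make_gas(100, 2.0, seed=4)
        m = Mesh((2.0, 2.0, 2.0), 0.1)
        g = assign_density(sys_, m)
        assert g.particle_number == pytest.approx(100.0, rel=1e-10)

    def test_nearest_node_window(self):
        m = Mesh((1.0, 1.0, 1.0), 0.125, window="nearest-node")
        g = assign_density(Pts([[0.26, 0.51, 0.34]]), m)
        w = g.phi * m.cell_volume
        assert (w > 0).sum() == 1
        assert w.max() == pytest.approx(1.0)


class TestFilter:
    def test_constant_field_is_eigenfunction(self):
        m = Mesh((1.0, 1.0, 1.0), 1 / 16)
        filt = GaussianFilterSpec(((0.7, 0.2), (0.4, 0.3)))
        g = DensityGrid(m, np.full(m.counts, 3.1))
        apply_filter(g, filt)
        np.testing.assert_allclose(g.phi_filtered, 3.1 * 1.1, rtol=1e-12)

    def test_matches_real_space_periodic_convolution(self):
        # independent oracle: dense circular convolution with the sampled,
        # image-summed kernel
        m = Mesh((1.0, 1.0, 1.0), 1 / 16)
        filt = GaussianFilterSpec(((1.0, 0.18),))
        rng = np.random.default_rng(8)
        g = DensityGrid(m, rng.uniform(0.0, 2.0, m.counts))
        apply_filter(g, filt)

        # image-summed sampled kernel, then dense O(M^2) circular convolution
        n = 16
        off = np.arange(n) / n

        def axis_imgs(k):
            return off[k] + np.array([-2.0, -1.0, 0.0, 1.0, 2.0])

        kern = np.zeros((n, n, n))
        for i in range(n):
            xi = axis_imgs(i)
            for j in range(n):
                yj = axis_imgs(j)
                for k in range(n):
                    zk = axis_imgs(k)
                    d = np.sqrt(xi[:, None, None] ** 2
                                + yj[None, :, None] ** 2
                                + zk[None, None, :] ** 2)
                    kern[i, j, k] = filt.real_space(d).sum()
        idx = np.arange(n)
        phi_flat = g.phi.reshape(-1)
        coords = np.stack(np.meshgrid(idx, idx, idx, indexing="ij"),
                          axis=-1).reshape(-1, 3)
        out = np.empty(len(coords))
        for row, c in enumerate(coords):
            shifted = kern[tuple(((c[None, :] - coords) % n).T)]
            out[row] = m.cell_volume * float(phi_flat @ shifted)
        np.testing.assert_allclose(g.phi_filtered, out.reshape(m.counts),
                                   rtol=0, atol=1e-10)

    def test_linearity_in_filter_terms(self):
        m = Mesh((1.0, 1.0, 1.0), 1 / 12)
        rng = np.random.default_rng(9)
        phi = rng.uniform(0.0, 1.0, m.counts)
        two = GaussianFilterSpec(((0.8, 0.15), (-0.3, 0.25)))
        fa = apply_filter(DensityGrid(m, phi.copy()),
                          GaussianFilterSpec(((0.8, 0.15),))).phi_filtered
        fb = apply_filter(DensityGrid(m, phi.copy()),
                          GaussianFilterSpec(((-0.3, 0.25),))).phi_filtered
        fab = apply_filter(DensityGrid(m, phi.copy()), two).phi_filtered
        np.testing.assert_allclose(fab, fa + fb, atol=1e-12)

    def test_unresolvable_filter_warns(self):
        m = Mesh((1.0, 1.0, 1.0), 0.2)
        g = DensityGrid(m, np.zeros(m.counts))
        with pytest.warns(MeshResolutionWarning):
            apply_filter(g, GaussianFilterSpec(((1.0, 0.05),)))


class TestEnergy:
    def test_empty_system_zero_energy(self):
        m = Mesh((1.0, 1.0, 1.0), 0.1)
        g = DensityGrid(m, np.zeros(m.counts))
        apply_filter(g, GaussianFilterSpec(((1.0, 0.2),)))
        assert field_energy(g, PARAMS) == 0.0

    def test_quadratic_homogeneity(self):
        # doubling the density quadruples the quadratic functional
        m = Mesh((1.0, 1.0, 1.0), 0.1)
        rng = np.random.default_rng(3)
        phi = rng.uniform(0.0, 1.0, m.counts)
        e1 = field_energy(apply_filter(DensityGrid(m, phi),
                                       GaussianFilterSpec(((1.0, 0.2),))),
                          PARAMS)
        e2 = field_energy(apply_filter(DensityGrid(m, 2 * phi),
                                       GaussianFilterSpec(((1.0, 0.2),))),
                          PARAMS)
        assert e2 == pytest.approx(4 * e1, rel=1e-12)

    def test_provider_energy_matches_grid_quadrature_for_two_particles(self):
        # provider subtracts the self-energy; the grid route keeps it
        filt = GaussianFilterSpec(((1.0, 0.2),))
        m = Mesh((2.0, 2.0, 2.0), 0.05)
        prov = FieldForceProvider(m, filt, PARAMS)
        sys_ = Pts([[0.5, 1.0, 1.0], [1.2, 1.0, 1.0]])
        grid = apply_filter(assign_density(sys_, m), filt)
        raw = field_energy(grid, PARAMS)
        # on-node particles: self-energy equals the k-space autocorrelation at 0
        e_pair = prov.energy(sys_)
        assert raw - e_pair == pytest.approx(2 * 0.5 * prov._self_kernel[0, 0]
                                             / m.cell_volume * (
                                                 1.0), rel=1e-9)


class TestForces:
    def test_net_force_vanishes_spectral(self):
        sys_ = make_gas(20, 1.0, seed=5)
        filt = GaussianFilterSpec(((1.0, 0.12), (-0.4, 0.2)))
        prov = FieldForceProvider(Mesh((1.0, 1.0, 1.0), 1 / 32), filt, PARAMS)
        _, f = prov.energy_forces(sys_)
        assert np.abs(f.sum(axis=0)).max() <= 1e-8 * np.abs(f).max()

    def test_gradient_formulation_matches_finite_differences(self):
        rng = np.random.default_rng(12)
        filt = GaussianFilterSpec(((1.0, 0.25), (-0.4, 0.32)))
        prov = FieldForceProvider(Mesh((1.0, 1.0, 1.0), 1 / 64), filt, PARAMS,
                                  formulation="gradient")
        pos = rng.uniform(0, 1.0, (10, 3))
        e0, f0 = prov.energy_forces(Pts(pos))
        step = 1e-6
        fmax = np.abs(f0).max()
        for i in range(10):
            for d in range(3):
                pp, pm = pos.copy(), pos.copy()
                pp[i, d] += step
                pm[i, d] -= step
                fd = -(prov.energy(Pts(pp)) - prov.energy(Pts(pm))) / (2 * step)
                assert abs(fd - f0[i, d]) <= 1e-4 * fmax

    def test_formulations_agree_to_discretization_order(self):
        rng = np.random.default_rng(13)
        filt = GaussianFilterSpec(((1.0, 0.25), (-0.4, 0.32)))
        pos = rng.uniform(0, 1.0, (10, 3))
        devs = []
        for n in (32, 64):
            mesh = Mesh((1.0, 1.0, 1.0), 1 / n)
            fs = FieldForceProvider(mesh, filt, PARAMS)
            fg = FieldForceProvider(mesh, filt, PARAMS, "gradient")
            _, a = fs.energy_forces(Pts(pos))
            _, b = fg.energy_forces(Pts(pos))
            devs.append(np.abs(a - b).max() / np.abs(a).max())
        assert devs[1] < 0.7 * devs[0]  # shrinks with h
        assert devs[1] < 0.05

    def test_distant_particles_feel_no_force(self):
        filt = GaussianFilterSpec(((1.0, 0.1),))
        L = 4.0
        prov = FieldForceProvider(Mesh((L, L, L), 0.05), filt, PARAMS)
        far = Pts([[1.0, 2.0, 2.0], [3.0, 2.0, 2.0]])  # 10 sigma apart
        near = Pts([[1.9, 2.0, 2.0], [2.1, 2.0, 2.0]])
        _, f_far = prov.energy_forces(far)
        _, f_near = prov.energy_forces(near)
        assert np.abs(f_far).max() < 1e-10 * np.abs(f_near).max()


class TestScan:
    def test_large_separation_asymptote(self, two_gauss_filter):
        # > 10x the largest effective Gaussian width: tail below 1e-8 kJ/mol
        r = np.array([2.24])
        tab = two_particle_scan(two_gauss_filter, PARAMS, 0.04, r,
                                box_edge=5.6)
        assert abs(tab["delta_W"].iloc[0]) < 1e-8

    def test_on_grid_fine_mesh_matches_expansion(self, two_gauss_filter):
        r = np.arange(2, 13) * 0.08
        tab = two_particle_scan(two_gauss_filter, PARAMS, 0.04, r, "on-grid")
        ref = analytic_scan_reference(two_gauss_filter, PARAMS,
                                      tab["r"].to_numpy())
        well = np.abs(ref).max()
        assert np.abs(tab["delta_W"].to_numpy() - ref).max() <= 0.02 * well

    def test_off_grid_deviation_grows_with_h(self, two_gauss_filter):
        r = np.arange(2, 13) * 0.08
        devs = []
        for h in (0.04, 0.08):
            tab = two_particle_scan(two_gauss_filter, PARAMS, h, r,
                                    "off-grid-offset", box_edge=3.2)
            ref = analytic_scan_reference(two_gauss_filter, PARAMS,
                                          tab["r"].to_numpy())
            devs.append(np.abs(tab["delta_W"].to_numpy() - ref).max())
        assert devs[1] > devs[0]

    def test_separation_beyond_half_box_rejected(self, two_gauss_filter):
        with pytest.raises(ValueError):
            two_particle_scan(two_gauss_filter, PARAMS, 0.05, [2.0],
                              box_edge=3.0)
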