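"""RDF normalization, PMF inversion, angular distributions, three-body maps."""

import numpy as np
import pytest

from nncg.config_io import PeriodicConfiguration
from nncg.descriptors import DescriptorSpec
from nncg.mc_sampler import ThermoState
from nncg.network import NetworkParams
from nncg.structure_analysis import (
    PMFTable,
    RDFCurve,
    RDFGrid,
    angle_histogram,
    angular_distribution,
    pmf_from_rdf,
    pmf_total_energy,
    rdf,
    three_body_map,
)

THERMO = ThermoState(95.0)


class TestRDF:
    def test_single_pair_normalization(self):
        """Two particles 5 A apart in a 20 A box: one bin at the
        hand-evaluated value 1 / (4 pi r^2 dr / V)."""
        cfg = PeriodicConfiguration(
            [[0.0, 0, 0], [5.0, 0, 0]], [20.0, 20.0, 20.0]
        )
        grid = RDFGrid(r_max=10.0, n_bins=100)  # dr = 0.1
        curve = rdf([cfg], grid)
        nz = np.nonzero(curve.g)[0]
        assert list(nz) == [50]
        r_c = grid.centers[50]
        expected = 1.0 / (4 * np.pi * r_c**2 * 0.1 / 20.0**3)
        assert curve.g[50] == pytest.approx(expected, rel=1e-12)

    def test_ideal_gas_is_flat(self):
        r = np.random.default_rng(0)
        frames = [
            PeriodicConfiguration(r.uniform(0, 20, (60, 3)), [20.0] * 3)
            for _ in range(400)
        ]
        grid = RDFGrid(r_max=10.0, n_bins=25)
        curve = rdf(frames, grid)
        # per-bin 3-sigma band from Poisson counting statistics
        expect = grid.ideal_counts(60, 20.0**3) * len(frames)
        sigma = 3 * np.sqrt(expect) / expect
        sel = grid.centers > 2.0
        assert np.all(np.abs(curve.g[sel] - 1.0) < sigma[sel])

    def test_empty_frame_list_rejected(self):
        with pytest.raises(ValueError):
            rdf([], RDFGrid(5.0, 10))

    def test_range_check(self):
        cfg = PeriodicConfiguration([[0, 0, 0], [1, 1, 1.0]], [10.0] * 3)
        with pytest.raises(ValueError, match="half the smallest box"):
            rdf([cfg], RDFGrid(8.0, 10))


class TestPMF:
    def test_flat_rdf_gives_zero_pmf(self):
        grid = RDFGrid(5.0, 10)
        table = pmf_from_rdf(RDFCurve(grid, np.ones(10)), THERMO)
        np.testing.assert_array_equal(table.values, 0.0)

    def test_boltzmann_inversion_identity(self):
        grid = RDFGrid(10.0, 50)
        r = grid.centers
        u = 4 * 0.5 * ((3.4 / r) ** 12 - (3.4 / r) ** 6)
        u = np.clip(u, None, 30.0)  # keep g representable
        curve = RDFCurve(grid, np.exp(-u))
        table = pmf_from_rdf(curve, THERMO)
        np.testing.assert_allclose(table.values, u, atol=1e-12)

    def test_core_extrapolation_hand_case(self):
        """5-bin curve with two empty core bins: V is linear below alpha_0
        with per-bin slope dV = V(a0) - V(a0+1)."""
        grid = RDFGrid(5.0, 5)
        g = np.array([0.0, 0.0, 0.5, 1.5, 1.0])
        table = pmf_from_rdf(RDFCurve(grid, g), THERMO)
        v2 = -np.log(0.5)
        v3 = -np.log(1.5)
        dv = v2 - v3
        assert table.core_index == 2
        assert table.core_slope == pytest.approx(dv)
        assert table.values[1] == pytest.approx(v2 + dv)
        assert table.values[0] == pytest.approx(v2 + 2 * dv)
        assert np.all(np.isfinite(table.values))

    def test_all_zero_rdf_rejected(self):
        with pytest.raises(ValueError):
            pmf_from_rdf(RDFCurve(RDFGrid(5.0, 5), np.zeros(5)), THERMO)


class TestPMFTotalEnergy:
    def _table(self):
        grid = RDFGrid(5.0, 10)
        return PMFTable(grid, np.linspace(3.0, -0.5, 10), 0, 1.0)

    def test_two_particles_one_bin(self):
        table = self._table()
        cfg = PeriodicConfiguration(
            [[0.0, 0, 0], [2.25, 0, 0]], [20.0] * 3
        )
        # r = 2.25 -> bin 4
        assert pmf_total_energy(cfg, table) == pytest.approx(table.values[4])

    def test_equilateral_triplet(self):
        table = self._table()
        a = 3.0
        cfg = PeriodicConfiguration(
            [[0, 0, 0.0], [a, 0, 0], [a / 2, a * np.sqrt(3) / 2, 0]],
            [30.0] * 3,
        )
        assert pmf_total_energy(cfg, table) == pytest.approx(
            3 * table.values[6]
        )

    def test_matches_brute_force(self, rng):
        table = self._table()
        pos = rng.uniform(0, 15, (20, 3))
        cfg = PeriodicConfiguration(pos, [15.0] * 3)
        expected = 0.0
        for i in range(20):
            for j in range(i + 1, 20):
                d = pos[j] - pos[i]
                d -= 15.0 * np.round(d / 15.0)
                r = np.linalg.norm(d)
                b = int(r / 0.5)
                if b < 10:
                    expected += table.values[b]
        assert pmf_total_energy(cfg, table) == pytest.approx(expected, rel=1e-12)

    def test_pairs_beyond_grid_contribute_zero(self):
        table = self._table()
        cfg = PeriodicConfiguration([[0, 0, 0], [8.0, 0, 0.0]], [20.0] * 3)
        assert pmf_total_energy(cfg, table) == 0.0


class TestAngularDistribution:
    def test_uniform_angles_give_flat_curve(self, rng):
        angles = rng.uniform(0, 180, 200_000)
        curve = angle_histogram(angles, 30)
        assert np.all(np.abs(curve - 1.0) < 0.05)
        # per-bin probabilities sum to 1 before the x n_bins convention
        assert curve.sum() / 30 == pytest.approx(1.0)

    def test_single_equilateral_triplet(self):
        a = 3.0
        cfg = PeriodicConfiguration(
            [[0, 0, 0.0], [a, 0, 0], [a / 2, a * np.sqrt(3) / 2, 0]],
            [30.0] * 3,
        )
        # 8 bins of 22.5 deg put 60 deg mid-bin (away from edge round-off)
        centers, curve = angular_distribution([cfg], r_shell=4.0, n_bins=8)
        bin60 = int(60.0 / 22.5)
        assert curve[bin60] == pytest.approx(8.0)
        assert curve.sum() == pytest.approx(8.0)

    def test_ideal_gas_matches_sine_density(self):
        r = np.random.default_rng(2)
        frames = [
            PeriodicConfiguration(r.uniform(0, 24, (80, 3)), [24.0] * 3)
            for _ in range(60)
        ]
        n_bins = 18
        centers, curve = angular_distribution(frames, r_shell=6.2, n_bins=n_bins)
        edges = np.linspace(0, np.pi, n_bins + 1)
        p = (np.cos(edges[:-1]) - np.cos(edges[1:])) / 2
        expected = p * n_bins
        # random-direction neighbors: angle density ~ sin(theta)/2
        assert np.sqrt(np.mean((curve - expected) ** 2)) < 0.12

    def test_no_triplets_rejected(self):
        cfg = PeriodicConfiguration([[0, 0, 0], [20.0, 20, 20.0]], [50.0] * 3)
        with pytest.raises(ValueError, match="no triplets"):
            angular_distribution([cfg], r_shell=3.0, n_bins=10)


class TestThreeBodyMap:
    def test_linear_model_has_no_three_body_component(self, rng):
        """Site energies of a linear net are sums over pair terms, so the
        pair energies cancel exactly in dE3."""
        spec = DescriptorSpec.set1(r_c=10.0)
        params = NetworkParams((8, 1), rng.standard_normal(8))
        for r12 in (3.4, 4.5, 6.3):
            _, _, de3 = three_body_map(
                spec, params, r12=r12, half_extent=6.0, n_grid=9
            )
            np.testing.assert_allclose(de3, 0.0, atol=1e-10)

    def test_far_third_particle_contributes_nothing(self, rng):
        spec = DescriptorSpec.set1(r_c=8.0)
        params = NetworkParams.create(8, (10,), rng)
        xs, ys, de3 = three_body_map(
            spec, params, r12=3.4, half_extent=12.0, n_grid=13
        )
        far = np.add.outer(ys**2, xs**2) > (8.0 + 3.4) ** 2  # beyond both cutoffs
        assert np.all(np.abs(de3[far]) < 1e-10)

    def test_hand_computed_nonlinear_value(self):
        """One grid point of a toy ReLU model against a pencil-and-paper
        forward pass through the dE3 definition."""
        from nncg.descriptors import g2_matrix
        from nncg.network import total_energy

        spec = DescriptorSpec([0.0], [0.0], r_c=10.0)  # smooth coordination
        # 1 input -> 1 hidden (ReLU, weight 1) -> output weight 1: E_n = G_n
        # squared? no: E_n = ReLU(G_n) = G_n (G >= 0): linear in G but the
        # *pairwise* cancellation still holds only for linear nets; use a
        # genuinely nonlinear weight: hidden weight 1, output -2, second
        # hidden path makes E_n = -2*G_n ... instead take output quadratic
        # surrogate: hidden weights (1, -1) -> output (1, 1):
        # E_n = ReLU(G_n) + ReLU(-G_n) = G_n for G_n >= 0 -> still linear.
        # A single ReLU net over nonnegative inputs is linear per site, but
        # NOT a linear *model* in the Eq-13 sense unless weights are shared
        # pairwise; dE3 cancels anyway.  Verify that explicitly:
        params = NetworkParams((1, 2, 1), [1.0, -1.0, 1.0, 1.0])
        box = np.full(3, 60.0)
        c = 30.0
        p1 = np.array([c - 1.7, c, 0.0])
        p2 = np.array([c + 1.7, c, 0.0])
        p3 = np.array([c, c + 2.0, 0.0])

        def e(pts):
            cfg = PeriodicConfiguration(np.vstack(pts), box)
            return total_energy(
                g2_matrix(cfg, spec, allow_small_box=True), params
            ).total

        de3 = e([p1, p2, p3]) - e([p1, p2]) - e([p1, p3]) - e([p2, p3])
        assert de3 == pytest.approx(0.0, abs=1e-12)

        # breaking positivity of the hidden preactivation makes it genuinely
        # nonlinear: hidden weight -1 gates G; E_n = ReLU(3 - ...) needs a
        # bias, impossible here, so use two inputs with opposite signs.
        spec2 = DescriptorSpec([0.0, 4.0], [0.0, 3.4], r_c=10.0)
        params2 = NetworkParams((2, 1, 1), [1.0, -2.0, 1.0])
        def e2(pts):
            cfg = PeriodicConfiguration(np.vstack(pts), box)
            from nncg.descriptors import g2_matrix as gm
            from nncg.network import total_energy as te
            return te(gm(cfg, spec2, allow_small_box=True), params2).total
        de3b = e2([p1, p2, p3]) - e2([p1, p2]) - e2([p1, p3]) - e2([p2, p3])
        # hand value: compute directly from the definition with explicit
        # G2 sums (independent arithmetic below)
        def g2pair(r):
            fc = 0.5 * (np.cos(np.pi * r / 10.0) + 1) if r < 10 else 0.0
            return np.array([np.exp(0.0) * fc, np.exp(-4 * (r - 3.4) ** 2) * fc])
        r12 = np.linalg.norm(p1 - p2)
        r13 = np.linalg.norm(p1 - p3)
        r23 = np.linalg.norm(p2 - p3)
        def site_e(gsum):
            return max(gsum @ np.array([1.0, -2.0]), 0.0) * 1.0
        e123 = (
            site_e(g2pair(r12) + g2pair(r13))
            + site_e(g2pair(r12) + g2pair(r23))
            + site_e(g2pair(r13) + g2pair(r23))
        )
        epair = lambda r: 2 * site_e(g2pair(r))
        expected = e123 - epair(r12) - epair(r13) - epair(r23)
        assert de3b == pytest.approx(expected, abs=1e-12)
        assert abs(expected) > 1e-6  # the toy model is genuinely three-body


class TestRoundTrips:
    def test_rdf_rotation_invariance(self, rng):
        cluster = rng.uniform(-5, 5, (25, 3))
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("xyz", [1.0, 0.3, -0.7]).as_matrix()
        box = [200.0] * 3
        grid = RDFGrid(12.0, 60)
        a = rdf([PeriodicConfiguration(cluster + 100, box)], grid)
        b = rdf([PeriodicConfiguration(cluster @ rot.T + 100, box)], grid)
        np.testing.assert_array_equal(a.g, b.g)
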