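"""Loss, fluctuation gradients, AMSGrad, pretraining, and the training loop."""

import numpy as np
import pytest

from nncg.config_io import PeriodicConfiguration, RunConfig
from nncg.descriptors import DescriptorSpec
from nncg.mc_sampler import (
    NetworkPotential,
    SamplingAccumulators,
    ThermoState,
    run_sampling,
)
from nncg.network import NetworkParams
from nncg.structure_analysis import RDFCurve, RDFGrid, PMFTable
from nncg.training import (
    OptimizerState,
    ReferenceSystem,
    amsgrad_step,
    loss_gradient,
    pretrain,
    rdf_loss,
    train,
)

THERMO = ThermoState(95.0)


def make_acc(grid, g, dEdw, cross):
    return SamplingAccumulators(
        r_centers=grid.centers,
        mean_g=g,
        n_samples=100,
        acceptance_ratio=0.5,
        final_max_disp=0.3,
        final_config=PeriodicConfiguration(np.zeros((2, 3)), [10.0] * 3),
        mean_hist=g,
        norm=np.ones(grid.n_bins),
        mean_dEdw=dEdw,
        cross_g_dEdw=cross,
    )


class TestRdfLoss:
    def test_identical_curves_zero(self):
        grid = RDFGrid(5.0, 20)
        g = np.random.default_rng(0).uniform(0, 2, 20)
        assert rdf_loss(RDFCurve(grid, g), RDFCurve(grid, g)) == 0.0

    def test_constant_offset(self):
        grid = RDFGrid(5.0, 20)
        a = RDFCurve(grid, np.ones(20))
        b = RDFCurve(grid, np.ones(20) * 1.3)
        assert rdf_loss(a, b) == pytest.approx(20 * 0.3**2)

    def test_hand_summed_four_bins(self):
        grid = RDFGrid(2.0, 4)
        a = RDFCurve(grid, np.array([0.0, 0.5, 1.5, 1.0]))
        b = RDFCurve(grid, np.array([0.1, 0.2, 1.0, 1.1]))
        expected = 0.01 + 0.09 + 0.25 + 0.01
        assert rdf_loss(a, b) == pytest.approx(expected)

    def test_grid_mismatch_rejected(self):
        a = RDFCurve(RDFGrid(5.0, 20), np.ones(20))
        b = RDFCurve(RDFGrid(5.0, 25), np.ones(25))
        with pytest.raises(ValueError, match="grid"):
            rdf_loss(a, b)


class TestLossGradient:
    def test_zero_residual_zero_gradient(self):
        grid = RDFGrid(5.0, 10)
        g = np.linspace(0, 2, 10)
        acc = make_acc(grid, g, np.array([0.5, -1.0]),
                       np.outer(g, [0.5, -1.0]) + 0.1)
        grad = loss_gradient(acc, RDFCurve(grid, g), THERMO)
        np.testing.assert_allclose(grad, 0.0, atol=1e-14)

    def test_constant_dEdw_component_has_zero_covariance(self):
        """A weight with sample-independent dE/dw has zero gradient: its
        cross term factorizes exactly."""
        grid = RDFGrid(5.0, 10)
        g = np.linspace(0.1, 2, 10)
        dEdw = np.array([3.0])
        cross = np.outer(g, dEdw)  # <g * c> = <g> * c for constant c
        acc = make_acc(grid, g, dEdw, cross)
        ref = RDFCurve(grid, g + 0.3)
        grad = loss_gradient(acc, ref, THERMO)
        np.testing.assert_allclose(grad, 0.0, atol=1e-12)

    def test_matches_finite_differences_of_resampled_averages(self, gradient_check):
        """Fluctuation-formula d<g>/dw vs central differences over
        independently re-sampled runs (4-weight linear model, 20 sites):
        >= 95% of populated (bin, weight) cells agree within 3 combined
        standard errors."""
        frac, _ = gradient_check
        assert frac >= 0.95


class TestAmsgrad:
    def test_zero_gradient_no_change(self, rng):
        params = NetworkParams((4, 1), rng.standard_normal(4))
        state = OptimizerState(lr=0.1)
        out = amsgrad_step(state, np.zeros(4), params)
        np.testing.assert_array_equal(out.weights, params.weights)

    def test_first_step_hand_computed(self):
        """One step from zero state with constant gradient g, default betas."""
        lr, b1, b2, eps = 0.01, 0.9, 0.999, 1e-8
        g = np.array([0.3, -2.0])
        params = NetworkParams((2, 1), np.array([1.0, 1.0]))
        state = OptimizerState(lr=lr, beta1=b1, beta2=b2, eps=eps)
        out = amsgrad_step(state, g, params)
        m_hat = (1 - b1) * g / (1 - b1)
        v_hat_c = (1 - b2) * g**2 / (1 - b2)
        expected = 1.0 - lr * m_hat / (np.sqrt(v_hat_c) + eps)
        np.testing.assert_allclose(out.weights, expected, atol=1e-12)

    def test_second_moment_max_never_decreases(self, rng):
        params = NetworkParams((5, 1), rng.standard_normal(5))
        state = OptimizerState(lr=0.01)
        prev = np.zeros(5)
        for _ in range(100):
            params = amsgrad_step(state, rng.standard_normal(5) * 3, params)
            assert np.all(state.v_hat >= prev - 1e-18)
            prev = state.v_hat.copy()

    def test_nonfinite_gradient_rejected(self, rng):
        params = NetworkParams((2, 1), np.ones(2))
        with pytest.raises(ValueError, match="non-finite"):
            amsgrad_step(OptimizerState(), np.array([1.0, np.nan]), params)


class TestPretrain:
    def _toy_system(self, n=40, box=14.0, seed=0):
        rng = np.random.default_rng(seed)
        frames = [
            PeriodicConfiguration(rng.uniform(0, box, (n, 3)), [box] * 3)
            for _ in range(10)
        ]
        grid = RDFGrid(6.0, 30)
        g = np.clip(np.exp(-((grid.centers - 3.8) ** 2)) + 0.8, 0.01, None)
        g[grid.centers < 2.5] = 0.0
        return ReferenceSystem("toy", RDFCurve(grid, g), frames, THERMO)

    def test_isolated_displacement_loss_is_network_term_only(self):
        """Move a site isolated beyond r_c: dE_PMF = 0, loss = (dE_NN)^2."""
        spec = DescriptorSpec([0.5], [2.0], r_c=4.0)
        box = 40.0
        pos = np.vstack([[20.0, 20, 20], np.random.default_rng(2).uniform(0, 8, (6, 3))])
        frames = [PeriodicConfiguration(pos, [box] * 3)]
        grid = RDFGrid(4.0, 8)
        g = np.array([0.0, 0.0, 0.5, 1.2, 1.0, 1.0, 1.0, 1.0])
        system = ReferenceSystem("iso", RDFCurve(grid, g), frames, THERMO)
        params = NetworkParams((1, 1), np.array([2.0]))

        from nncg.descriptors import g2_delta, g2_matrix
        from nncg.network import total_energy
        from nncg.structure_analysis import pmf_from_rdf

        pmf = pmf_from_rdf(system.reference_rdf, THERMO)
        pot = pmf.as_pair_potential()
        new_pos = np.array([21.0, 20.0, 20.0])
        assert pot.delta_energy(frames[0], 0, new_pos) == 0.0
        cache = g2_matrix(frames[0], spec, allow_small_box=True)
        upd, rows, _ = g2_delta(frames[0], 0, pos[0], new_pos, spec, cache)
        de_nn = (
            total_energy(upd[rows], params).total
            - total_energy(cache[rows], params).total
        )
        assert de_nn == 0.0  # still isolated: zero row before and after

    def test_pretraining_reduces_running_loss(self, lj_system):
        """2000 PMF-matching steps cut the running-mean loss well below the
        first 50 steps on the LJ reference (>= 5x; the per-move squared
        residual has an irreducible discretization floor)."""
        spec = DescriptorSpec.set1(r_c=8.5)
        params = NetworkParams.create(8, (), np.random.default_rng(0))
        res = pretrain(
            [lj_system], spec, params, n_steps=2000,
            optimizer=OptimizerState.for_pretraining(), seed=3,
        )
        first = res.loss_history[:50].mean()
        last = res.loss_history[-200:].mean()
        assert last * 5 <= first

    def test_empty_systems_rejected(self):
        with pytest.raises(ValueError):
            pretrain([], DescriptorSpec.set1(), NetworkParams((8, 1), np.zeros(8)))


class TestTrainLoop:
    def test_multi_system_total_is_sum_of_per_system(self):
        from nncg.training import LossReport

        rep = LossReport(0, {"a": 0.5, "b": 1.25, "c": 0.0})
        assert rep.total == 0.5 + 1.25
        assert rep.mean == pytest.approx(rep.total / 3)

    def test_determinism_identical_seeds_identical_histories(self, lj_system):
        spec = DescriptorSpec.set1(r_c=8.5)
        params = NetworkParams((8, 1), np.linspace(1.0, -0.5, 8) * 2)
        run = RunConfig(
            n_steps=60_000, n_equil=20_000, temperature=95.0,
            rdf_r_max=8.5, rdf_n_bins=170,
        )
        a = train([lj_system], spec, params, run, 2,
                  optimizer=OptimizerState.for_rdf_training(), master_seed=5)
        b = train([lj_system], spec, params, run, 2,
                  optimizer=OptimizerState.for_rdf_training(), master_seed=5)
        assert [h.total for h in a.history] == [h.total for h in b.history]
        np.testing.assert_array_equal(a.params.weights, b.params.weights)

    def test_self_consistent_reference_is_a_fixed_point(self, lj_bundle):
        """Training against an RDF generated by the model's own weights:
        loss stays at the sampling-noise floor and weights barely move."""
        spec = DescriptorSpec.set1(r_c=8.5)
        w = np.array([20.0, -1.0, -4.0, -2.0, -1.0, -0.4, -0.1, 0.2])
        params = NetworkParams((8, 1), w)
        run = RunConfig(
            n_steps=300_000, n_equil=100_000, temperature=95.0,
            rdf_r_max=8.5, rdf_n_bins=170,
        )
        ref_acc = run_sampling(
            lj_bundle.frames[0], NetworkPotential(spec, params), run, seed=77
        )
        system = ReferenceSystem(
            "self", RDFCurve(lj_bundle.rdf.grid, ref_acc.mean_g),
            lj_bundle.frames, THERMO,
        )
        # noise floor: an independent re-sample of the same weights
        floor_acc = run_sampling(
            lj_bundle.frames[1], NetworkPotential(spec, params), run, seed=78
        )
        floor = rdf_loss(
            RDFCurve(system.reference_rdf.grid, floor_acc.mean_g),
            system.reference_rdf,
        )
        st = train([system], spec, params, run, 3,
                   optimizer=OptimizerState(lr=0.03, beta1=0.5, beta2=0.99),
                   master_seed=8)
        for h in st.history:
            assert h.total < 10 * floor
        assert np.max(np.abs(st.params.weights - w)) < 0.2
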