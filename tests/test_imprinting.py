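"""Unit and property tests for the imprinting-kinetics forward simulator."""

import math

import numpy as np
import pytest

from decaycoupling.imprinting import (
    ConstantProfile,
    GeneKineticParams,
    ImprintingModel,
    ImprintingModelParams,
    ModelState,
    PulseProfile,
    StepProfile,
    machinery_shares,
)


def make_model(n=1, D=0.0, k_U=0.1, beta=0.0, q_affinity=0.7, **params):
    genes = [
        GeneKineticParams(f"g{i}", beta_basal=beta, affinity=q_affinity)
        for i in range(n)
    ]
    return ImprintingModel(genes, ImprintingModelParams(D=D, k_U=k_U, **params))


class TestMachineryShares:
    @pytest.mark.parametrize(
        "I,U,expected",
        [
            ([3.0, 3.0], [7.0, 7.0], [0.5, 0.5]),        # equal fractions
            ([8.0, 2.0], [2.0, 8.0], [0.8, 0.2]),        # normalized by hand
            ([0.0, 0.0], [0.0, 0.0], [0.0, 0.0]),        # all pools empty
        ],
    )
    def test_shares_normalize_imprinted_fractions(self, I, U, expected):
        s = machinery_shares(ModelState(0.0, np.array(I), np.array(U)))
        np.testing.assert_allclose(s, expected)
        assert s.sum() in (0.0, pytest.approx(1.0))

    def test_empty_genome_gives_empty_vector(self):
        s = machinery_shares(ModelState(0.0, np.array([]), np.array([])))
        assert s.size == 0


class TestStep:
    def test_pure_exponential_loss_without_machinery(self):
        # D = 0, beta = 0: I(t) = 100 * exp(-k_U t), closed form
        model = make_model(D=0.0, k_U=0.1, dt=0.002)
        state = ModelState(0.0, np.array([100.0]), np.array([0.0]))
        for _ in range(int(10 / 0.002)):
            state = model.step(state)
        assert state.I[0] == pytest.approx(100 * math.exp(-1.0), rel=1e-3)

    def test_steady_state_is_a_fixed_point(self):
        # capacity-limited single gene: I* = (q beta - D)/k_U, U* = (1-q)beta/k_U
        beta, k_U, D = 5.0, 0.05, 0.3
        model = make_model(D=D, k_U=k_U, beta=beta, lambda_max=10.0,
                           stress_onset=np.inf)
        q = model.imprinting_probability(0.0)[0]
        I_star = (q * beta - D) / k_U
        U_star = (1 - q) * beta / k_U
        assert I_star > 0 and D < 10.0 * I_star  # capacity term is the min
        state = ModelState(0.0, np.array([I_star]), np.array([U_star]))
        out = model.step(state)
        np.testing.assert_allclose(out.I, state.I, rtol=1e-12)
        np.testing.assert_allclose(out.U, state.U, rtol=1e-12)

    def test_identical_genes_have_identical_trajectories(self):
        genes = [
            GeneKineticParams(g, beta_basal=2.0, stress_class="induced",
                              phi=PulseProfile(8.0), affinity=0.8)
            for g in ("a", "b")
        ]
        model = ImprintingModel(genes, ImprintingModelParams(D=1.0))
        state = ModelState(0.0, np.array([5.0, 5.0]), np.array([40.0, 40.0]))
        for _ in range(200):
            state = model.step(state)
            assert state.I[0] == state.I[1]
            assert state.U[0] == state.U[1]

    def test_negative_pool_is_clipped_with_warning(self, caplog):
        model = make_model(D=0.0, k_U=0.5, dt=10.0)  # dt far beyond stability
        state = ModelState(0.0, np.array([1.0]), np.array([1.0]))
        with caplog.at_level("WARNING"):
            out = model.step(state)
        assert np.all(out.I >= 0) and np.all(out.U >= 0)
        assert any("clipping" in r.message for r in caplog.records)

    def test_machinery_flux_never_exceeds_pool_capacity(self):
        # conservation: sum_i min(D s_i, lambda I_i) <= D and sum s_i = 1
        rng = np.random.default_rng(0)
        genes = [
            GeneKineticParams(f"g{i}", beta_basal=float(b), affinity=float(a))
            for i, (b, a) in enumerate(zip(rng.uniform(0.5, 4, 30),
                                           rng.uniform(0.4, 1.0, 30)))
        ]
        params = ImprintingModelParams(D=3.0)
        model = ImprintingModel(genes, params)
        state = model.steady_state()
        for _ in range(100):
            s = machinery_shares(state)
            assert s.sum() == pytest.approx(1.0)
            flux = np.minimum(params.D * s, params.lambda_max * state.I)
            assert flux.sum() <= params.D + 1e-12
            state = model.step(state)


class TestImprintedFractionDynamics:
    def _trajectory_f(self, phi, minutes=40.0):
        genes = [GeneKineticParams("g", beta_basal=2.0, stress_class="induced",
                                   phi=phi, affinity=0.8)]
        model = ImprintingModel(genes, ImprintingModelParams(D=0.5))
        state = model.steady_state()
        fs = [state.imprinted_fraction[0]]
        for i in range(int(minutes / model.params.dt)):
            state.t = i * model.params.dt
            state = model.step(state)
            fs.append(state.imprinted_fraction[0])
        return np.array(fs)

    def test_induced_gene_fraction_rises_monotonically_after_stress(self):
        f = self._trajectory_f(StepProfile(8.0))
        assert np.all(np.diff(f) >= -1e-12)
        assert f[-1] > f[0]

    def test_fully_repressed_gene_fraction_decays(self):
        f = self._trajectory_f(StepProfile(0.0))
        assert np.all(np.diff(f) <= 1e-12)
        assert f[-1] < f[0]


class TestScenarios:
    def test_sample_time_beyond_horizon_raises(self):
        model = make_model(beta=1.0)
        with pytest.raises(ValueError, match="t_end"):
            model.run_scenario("reference_decay", sample_times=[0, 500])

    def test_unknown_scenario_rejected(self):
        model = make_model(beta=1.0)
        with pytest.raises(ValueError, match="scenario"):
            model.run_scenario("decay_without_a_name")

    def test_machinery_off_gives_uniform_first_order_half_life(self):
        # D = 0, k_U = 0.0693 -> every true half-life = ln2/0.0693 ~ 10 min
        genes = [
            GeneKineticParams("a", 1.0, "induced", PulseProfile(8.0), 0.9),
            GeneKineticParams("b", 3.0, "repressed", PulseProfile(0.125), 0.5),
        ]
        model = ImprintingModel(genes, ImprintingModelParams(D=0.0, k_U=0.0693))
        for scenario in ("reference_decay", "stress_decay"):
            res = model.run_scenario(scenario)
            np.testing.assert_allclose(
                res.true_halflife, math.log(2) / 0.0693, rtol=2e-3
            )

    def test_default_sample_times_follow_experiment_type(self):
        model = make_model(beta=1.0, q_affinity=0.5)
        decay = model.run_scenario("reference_decay")
        abundance = model.run_scenario("stress_abundance")
        np.testing.assert_array_equal(decay.sample_times,
                                      [0, 5, 10, 20, 30, 40, 50])
        np.testing.assert_array_equal(abundance.sample_times,
                                      [0, 5, 10, 15, 25, 35, 45])

    def test_stress_decay_clock_restarts_at_arrest(self):
        # with no stress response and no machinery, stress_decay equals
        # reference_decay except for the 7-minute pre-arrest segment at
        # steady state -> identical sampled counts
        genes = [GeneKineticParams("g", beta_basal=2.0, phi=ConstantProfile())]
        model = ImprintingModel(genes, ImprintingModelParams(D=0.0, p_stress=0.3))
        ref = model.run_scenario("reference_decay")
        stress = model.run_scenario("stress_decay")
        np.testing.assert_allclose(ref.counts, stress.counts, rtol=1e-9)

    def test_step_size_convergence(self):
        # halving the integration error: dt/10 changes trajectories < 0.5%
        def run(dt):
            genes = [
                GeneKineticParams(f"g{i}", beta_basal=b, stress_class=c,
                                  phi=p, affinity=a)
                for i, (b, c, p, a) in enumerate([
                    (1.0, "induced", PulseProfile(8.0), 0.9),
                    (2.0, "neutral", ConstantProfile(), 0.6),
                    (3.0, "repressed", PulseProfile(0.125), 0.4),
                ])
            ]
            model = ImprintingModel(genes, ImprintingModelParams(D=0.3, dt=dt))
            return model.run_scenario("stress_decay").counts

        coarse, fine = run(0.05), run(0.005)
        assert np.max(np.abs(coarse / fine - 1)) < 0.005


def test_gene_param_validation():
    with pytest.raises(ValueError):
        GeneKineticParams("g", beta_basal=-1.0)
    with pytest.raises(ValueError):
        GeneKineticParams("g", beta_basal=1.0, stress_class="upregulated")
    with pytest.raises(ValueError):
        ImprintingModelParams(p_basal=1.2)
    with pytest.raises(ValueError):
        ImprintingModelParams(k_U=0.0)
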