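import numpy as np
import pytest
from scipy.linalg import expm

from neuropm.io import Connectome, RegionalSeries
from neuropm.mcm import (
    CognitiveModel,
    MCMParams,
    build_operator,
    effective_metrics,
    estimate_cognitive_weights,
    mcm_fit,
    mcm_simulate,
    to_alterations,
)
from neuropm.synthetic import generate_mcm_dataset

TRUE_LOCAL = np.array([[-0.5, 0.4], [0.1, -0.6]])


@pytest.fixture(scope="module")
def truth_params():
    return MCMParams(TRUE_LOCAL, spreading_weights=[0.3, 0.2],
                     network_fractions=[1.0, 1.0])


@pytest.fixture(scope="module")
def noiseless_cohort(mcm_connectome, truth_params):
    rng = np.random.default_rng(0)
    S0 = rng.normal(0, 1, size=16)
    times = np.linspace(0, 5, 6)
    cohort, truth = generate_mcm_dataset(truth_params, mcm_connectome, times,
                                         noise_sd=0.0, n_subjects=1, seed=0,
                                         S0=S0)
    return cohort[0], truth


class TestOperator:
    def test_zero_params_zero_operator(self, mcm_connectome):
        p = MCMParams(np.zeros((2, 2)), np.zeros(2), np.ones(2))
        op = build_operator(p, mcm_connectome)
        np.testing.assert_array_equal(op.A, 0.0)

    def test_single_factor_assembly(self, mcm_connectome):
        p = MCMParams(np.array([[-0.3]]), [1.0], [1.0])
        op = build_operator(p, mcm_connectome)
        expected = mcm_connectome.weights.copy()
        np.fill_diagonal(expected, 0.0)
        expected = expected - 0.3 * np.eye(8)
        np.testing.assert_allclose(op.A, expected)

    def test_cross_factor_block_placement(self, mcm_connectome):
        # effect of factor 0 on factor 1 sits in block row 1, block col 0
        p = MCMParams(np.array([[0.0, 0.7], [0.0, 0.0]]), np.zeros(2), np.ones(2))
        A = build_operator(p, mcm_connectome).A
        np.testing.assert_allclose(A[8:, :8], 0.7 * np.eye(8))
        assert np.all(A[:8, 8:] == 0)

    def test_region_permutation_conjugates_operator(self, mcm_connectome,
                                                    truth_params):
        perm = np.roll(np.arange(8), 3)
        P1 = np.eye(8)[perm]
        conn_p = Connectome(mcm_connectome.weights[np.ix_(perm, perm)])
        A = build_operator(truth_params, mcm_connectome).A
        Ap = build_operator(truth_params, conn_p).A
        P = np.kron(np.eye(2), P1)
        np.testing.assert_allclose(Ap, P @ A @ P.T, atol=1e-12)

    def test_connectome_size_mismatch_rejected(self, mcm_connectome):
        p = MCMParams(np.zeros((1, 1)), [0.0], [1.0])
        other = Connectome(np.zeros((5, 5)))
        with pytest.raises(ValueError, match="disagree"):
            build_operator(p, [mcm_connectome, other])

    def test_parameter_vector_round_trip(self, truth_params):
        vec = truth_params.to_vector()
        assert vec.size == 4 + 2 + 2
        back = MCMParams.from_vector(vec, 2)
        np.testing.assert_array_equal(back.local_interactions, TRUE_LOCAL)


class TestSimulate:
    def test_zero_operator_constant_state(self, mcm_connectome, rng):
        p = MCMParams(np.zeros((2, 2)), np.zeros(2), np.ones(2))
        op = build_operator(p, mcm_connectome)
        S0 = rng.normal(size=16)
        S, _ = mcm_simulate(op, S0, np.linspace(0, 3, 4))
        np.testing.assert_allclose(S, S0[:, None] * np.ones((1, 4)))

    def test_diagonal_operator_matches_exponential(self, mcm_connectome, rng):
        a = -0.7
        p = MCMParams(a * np.eye(2), np.zeros(2), np.ones(2))
        op = build_operator(p, mcm_connectome)
        S0 = rng.normal(size=16)
        times = np.linspace(0, 2, 5)
        S, _ = mcm_simulate(op, S0, times)
        for k, t in enumerate(times):
            np.testing.assert_allclose(S[:, k], np.exp(a * t) * S0, atol=1e-9)

    def test_zero_intensity_input_is_null(self, mcm_connectome, truth_params, rng):
        op = build_operator(truth_params, mcm_connectome)
        S0 = rng.normal(size=16)
        times = np.linspace(0, 4, 6)
        base, _ = mcm_simulate(op, S0, times)
        sched = [{"start": 1.0, "stop": 2.0, "intensity": 0.0, "regions": [0, 1]}]
        forced, _ = mcm_simulate(op, S0, times, input_schedule=sched,
                                 input_effects=np.ones(2))
        np.testing.assert_allclose(forced, base, atol=1e-12)

    def test_constant_input_matches_closed_form(self):
        # scalar dS/dt = u with A = 0: S(t) = u*t on the active window
        conn = Connectome(np.zeros((1, 1)))
        p = MCMParams(np.zeros((1, 1)), [0.0], [1.0], input_effects=[1.0])
        op = build_operator(p, conn)
        sched = [{"start": 0.0, "stop": 2.0, "intensity": 1.5, "regions": [0]}]
        S, _ = mcm_simulate(op, [0.0], np.array([0.0, 1.0, 2.0, 3.0]),
                            input_schedule=sched)
        np.testing.assert_allclose(S[0], [0.0, 1.5, 3.0, 3.0], atol=1e-10)

    def test_linearity_in_initial_state(self, mcm_connectome, truth_params, rng):
        op = build_operator(truth_params, mcm_connectome)
        S0 = rng.normal(size=16)
        times = np.linspace(0, 3, 4)
        S1, _ = mcm_simulate(op, S0, times)
        S3, _ = mcm_simulate(op, 3.0 * S0, times)
        np.testing.assert_allclose(S3, 3.0 * S1, atol=1e-10)

    def test_cognitive_trajectory(self, mcm_connectome, truth_params, rng):
        op = build_operator(truth_params, mcm_connectome)
        w = rng.normal(size=16)
        cog_model = CognitiveModel(weights=w, intercept=1.0)
        S, cog = mcm_simulate(op, rng.normal(size=16), np.linspace(0, 2, 3),
                              cognitive=cog_model)
        np.testing.assert_allclose(cog, S.T @ w + 1.0)


class TestCognitiveWeights:
    def test_exact_recovery_overdetermined(self, rng):
        X = rng.normal(size=(200, 10))
        w = rng.normal(size=10)
        model = estimate_cognitive_weights(X, X @ w + 2.0)
        np.testing.assert_allclose(model.weights, w, atol=1e-6)
        assert model.intercept == pytest.approx(2.0, abs=1e-6)

    def test_pure_noise_has_no_out_of_sample_skill(self, rng):
        X = rng.normal(size=(500, 20))
        y = rng.normal(size=500)
        model = estimate_cognitive_weights(X[:250], y[:250])
        pred = model.predict(X[250:])
        ss_res = np.sum((y[250:] - pred) ** 2)
        ss_tot = np.sum((y[250:] - y[250:].mean()) ** 2)
        assert abs(1 - ss_res / ss_tot) < 0.05

    def test_single_node_toy(self, rng):
        s = rng.normal(size=(50, 1))
        model = estimate_cognitive_weights(s, 2.0 * s[:, 0])
        assert model.weights[0] == pytest.approx(2.0, abs=1e-8)

    def test_underdetermined_uses_ridge(self, rng):
        X = rng.normal(size=(10, 40))
        w = np.zeros(40)
        w[:3] = [1.0, -2.0, 0.5]
        model = estimate_cognitive_weights(X, X @ w)
        assert np.isfinite(model.weights).all()

    def test_constant_score_warns(self, rng):
        with pytest.warns(UserWarning, match="constant"):
            model = estimate_cognitive_weights(rng.normal(size=(20, 3)),
                                               np.full(20, 7.0))
        np.testing.assert_array_equal(model.weights, 0.0)


class TestFit:
    def test_spline_recovers_interactions(self, mcm_connectome, noiseless_cohort):
        obs, _ = noiseless_cohort
        fit = mcm_fit(obs, mcm_connectome, method="spline",
                      reference=np.zeros((8, 2)))
        err = np.max(np.abs(fit.params.local_interactions - TRUE_LOCAL))
        assert err < 0.05 * np.max(np.abs(TRUE_LOCAL))
        assert fit.accuracy_first > 99.0

    def test_null_system_recovers_zeros(self, mcm_connectome):
        vals = np.ones((8, 2, 4)) * np.arange(1, 3)[None, :, None]
        obs = RegionalSeries(subject_id="s", modalities=["a", "b"],
                             times=np.linspace(0, 3, 4), values=vals)
        fit = mcm_fit(obs, mcm_connectome, method="spline", tikhonov=1e-6)
        assert np.max(np.abs(fit.params.local_interactions)) < 1e-3
        assert np.max(fit.params.spreading_weights) < 1e-3

    def test_methods_agree_on_noiseless_data(self, mcm_connectome,
                                             noiseless_cohort):
        obs, _ = noiseless_cohort
        ref = np.zeros((8, 2))
        f1 = mcm_fit(obs, mcm_connectome, method="spline", reference=ref)
        f2 = mcm_fit(obs, mcm_connectome, method="multistart", reference=ref,
                     n_starts=6, n_iterations=1, seed=0)
        rel = (np.max(np.abs(f1.params.local_interactions
                             - f2.params.local_interactions))
               / np.max(np.abs(f2.params.local_interactions)))
        assert rel < 0.10

    def test_recovery_degrades_with_noise(self, mcm_connectome, truth_params):
        rng = np.random.default_rng(5)
        S0 = rng.normal(0, 1, size=16)
        times = np.linspace(0, 5, 6)
        med_err = []
        for sd in (0.0, 0.01, 0.05):
            errs = []
            for seed in range(5):
                cohort, _ = generate_mcm_dataset(truth_params, mcm_connectome,
                                                 times, noise_sd=sd,
                                                 n_subjects=1, seed=seed, S0=S0)
                fit = mcm_fit(cohort[0], mcm_connectome, method="spline",
                              reference=np.zeros((8, 2)))
                errs.append(np.sqrt(np.mean(
                    (fit.params.local_interactions - TRUE_LOCAL) ** 2)))
            med_err.append(np.median(errs))
        assert med_err[0] <= med_err[1] <= med_err[2]

    def test_missing_modality_rejected(self, mcm_connectome):
        vals = np.ones((8, 2, 4))
        vals[0, 0, 1] = np.nan
        obs = RegionalSeries(subject_id="s", modalities=["a", "b"],
                             times=np.arange(4.0), values=vals)
        with pytest.raises(ValueError, match="missing"):
            mcm_fit(obs, mcm_connectome)

    def test_estimate_S0_backprojects(self, mcm_connectome, noiseless_cohort):
        obs, truth = noiseless_cohort
        fit = mcm_fit(obs, mcm_connectome, method="spline",
                      reference=np.zeros((8, 2)), estimate_S0=True,
                      perturbation_time=-1.0)
        A = fit.operator.A
        expected = expm(-A * 1.0) @ fit.S0
        np.testing.assert_allclose(fit.params.S0_perturbation, expected,
                                   atol=1e-8)


class TestAlterations:
    def test_first_evaluation_default_reference(self, rng):
        vals = rng.normal(size=(4, 2, 3))
        s = RegionalSeries(subject_id="x", modalities=["a", "b"],
                           times=np.arange(3.0), values=vals)
        alt = to_alterations(s)
        np.testing.assert_allclose(alt[:, :, 0], 0.0)
        np.testing.assert_allclose(alt[:, :, 2], vals[:, :, 2] - vals[:, :, 0])


class TestEffectiveMetrics:
    def test_single_factor_sole_term(self, mcm_connectome, rng):
        p = MCMParams(np.array([[-0.4]]), [0.0], [1.0])
        states = rng.normal(size=(8, 1, 3))
        m = effective_metrics(p, mcm_connectome, states)
        np.testing.assert_allclose(m["causality"], [[100.0]])
        assert m["spreading"][0] == 0.0

    def test_zero_cross_interactions_zero_offdiagonal(self, mcm_connectome, rng):
        p = MCMParams(np.diag([-0.5, -0.3]), [0.1, 0.1], [1.0, 1.0])
        m = effective_metrics(p, mcm_connectome, rng.normal(size=(8, 2, 3)))
        assert m["causality"][0, 1] == 0.0 and m["causality"][1, 0] == 0.0

    def test_hand_computed_ratio_table(self):
        conn = Connectome(np.ones((2, 2)))  # off-diagonal ones after zeroing
        p = MCMParams(np.array([[-1.0, 0.5], [0.25, -0.5]]), [2.0, 0.0],
                      [1.0, 1.0])
        states = np.ones((2, 2, 1))
        m = effective_metrics(p, conn, states)
        # target 0: |−1|*2 + |0.25|*2 + spreading 2*(1*1)*2 = 2 + 0.5 + 4
        np.testing.assert_allclose(m["causality"][:, 0],
                                   [100 * 2 / 6.5, 100 * 0.5 / 6.5])
        assert m["spreading"][0] == pytest.approx(100 * 4 / 6.5)
        # target 1: |0.5|*2 + |−0.5|*2, no spreading
        np.testing.assert_allclose(m["causality"][:, 1], [50.0, 50.0])

    def test_conservation_per_target(self, mcm_connectome, rng):
        p = MCMParams(rng.normal(0, 0.4, (3, 3)), rng.uniform(0, 0.5, 3),
                      rng.uniform(0, 1, 3))
        m = effective_metrics(p, mcm_connectome, rng.normal(size=(8, 3, 4)))
        total = m["causality"].sum(axis=0) + m["spreading"] + m["input"]
        np.testing.assert_allclose(total, 100.0, atol=1e-9)

    def test_all_zero_dynamics_warns(self, mcm_connectome):
        p = MCMParams(np.zeros((2, 2)), np.zeros(2), np.ones(2))
        with pytest.warns(UserWarning, match="zero"):
            m = effective_metrics(p, mcm_connectome, np.zeros((8, 2, 3)))
        np.testing.assert_array_equal(m["causality"], 0.0)
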