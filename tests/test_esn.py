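import numpy as np
import pytest

from bioesn import (
    BioESN,
    DegenerateInputError,
    ESNConfig,
    Readout,
    ValidationError,
    make_bio_no_rank,
    make_memory_capacity_data,
    score_memory_capacity,
)
from bioesn.esn import fit_readout, init_input_weights, predict, run_reservoir


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        {"spectral_radius": 0.0},
        {"input_scaling": 0.0},
        {"leakage": 0.0},
        {"leakage": 1.5},
        {"transient": -1},
        {"reservoir_activation": "sigmoid"},
        {"output_activation": "softmax"},
        {"leak_integration": "other"},
    ])
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            ESNConfig(**kwargs)

    def test_defaults_are_fixed_constellation(self):
        cfg = ESNConfig()
        assert (cfg.spectral_radius, cfg.input_scaling, cfg.leakage, cfg.bias) == (
            0.99, 1e-5, 1.0, 1.0,
        )


class TestInputWeights:
    def test_shape_bounds_determinism(self):
        w = init_input_weights(200, 1, seed=0)
        assert w.shape == (200, 1)
        assert np.all(np.abs(w) <= 1)
        np.testing.assert_array_equal(w, init_input_weights(200, 1, seed=0))


class TestDynamics:
    def test_zero_input_weights_and_bias_give_zero_states(self):
        cfg = ESNConfig(bias=0.0, seed=0)
        W = np.array([[0.0, 0.5], [0.5, 0.0]])
        x = np.random.default_rng(1).normal(size=(50, 1))
        traj = run_reservoir(x, W, np.zeros((2, 1)), cfg)
        assert np.all(traj.states == 0)

    def test_manual_recursion_oracle(self):
        """One-step-at-a-time NumPy recursion reproduces run_reservoir."""
        rng = np.random.default_rng(2)
        W = rng.normal(size=(4, 4)) * 0.3
        W_in = rng.normal(size=(4, 2))
        x = rng.normal(size=(20, 2))
        cfg = ESNConfig(input_scaling=0.5, leakage=0.7, bias=0.2, seed=0)
        traj = run_reservoir(x, W, W_in, cfg)
        r = np.zeros(4)
        for t in range(20):
            r_new = np.tanh(W_in @ (0.5 * x[t]) + W @ r + 0.2)
            r = 0.7 * r_new + 0.3 * r
            np.testing.assert_allclose(traj.states[t], r, atol=1e-14)

    def test_leak_forms_identical_at_alpha_one(self):
        rng = np.random.default_rng(3)
        W = rng.normal(size=(5, 5)) * 0.2
        W_in = rng.normal(size=(5, 1))
        x = rng.normal(size=(30, 1))
        a = run_reservoir(x, W, W_in, ESNConfig(leakage=1.0, leak_integration="standard"))
        b = run_reservoir(x, W, W_in, ESNConfig(leakage=1.0, leak_integration="as-printed"))
        np.testing.assert_array_equal(a.states, b.states)

    def test_leak_forms_differ_below_alpha_one(self):
        rng = np.random.default_rng(4)
        W = rng.normal(size=(5, 5)) * 0.2
        W_in = rng.normal(size=(5, 1))
        x = rng.normal(size=(30, 1))
        a = run_reservoir(x, W, W_in, ESNConfig(leakage=0.6, leak_integration="standard"))
        b = run_reservoir(x, W, W_in, ESNConfig(leakage=0.6, leak_integration="as-printed"))
        assert np.max(np.abs(a.states - b.states)) > 1e-6

    def test_tanh_states_bounded(self, modular_connectome):
        r = make_bio_no_rank(modular_connectome, seed=0)
        model = BioESN(r, 1, ESNConfig(seed=1))
        x = np.random.default_rng(2).uniform(-0.5, 0.5, size=(500, 1))
        states = model.run(x).states
        assert np.all(np.abs(states) <= 1.0)

    def test_echo_state_contraction(self):
        """Two different initial states converge under the same drive (rho<1)."""
        rng = np.random.default_rng(5)
        W = rng.normal(size=(30, 30))
        W = W * (0.9 / np.max(np.abs(np.linalg.eigvals(W))))
        W_in = init_input_weights(30, 1, seed=6)
        x = rng.uniform(-0.5, 0.5, size=(500, 1))
        cfg = ESNConfig(spectral_radius=0.9, bias=0.0, input_scaling=1.0)
        a = run_reservoir(x, W, W_in, cfg)
        b = run_reservoir(x, W, W_in, cfg, initial_state=rng.uniform(-1, 1, 30))
        assert np.linalg.norm(a.states[-1] - b.states[-1]) < 1e-6

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValidationError):
            run_reservoir(np.array([[np.nan]]), np.zeros((2, 2)),
                          np.ones((2, 1)), ESNConfig())

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            run_reservoir(np.ones((10, 2)), np.zeros((3, 3)),
                          np.ones((3, 1)), ESNConfig())


class TestReadout:
    def _instance(self, T=50, n_r=5, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(T, 1))
        states = rng.normal(size=(T, n_r))
        y = rng.normal(size=(T, 2))
        return x, states, y

    def test_matches_normal_equations_oracle(self):
        x, states, y = self._instance()
        cfg = ESNConfig(transient=0)
        readout = fit_readout(x, states, y, cfg)
        z = np.hstack([x, states])
        oracle = np.linalg.solve(z.T @ z, z.T @ y).T
        np.testing.assert_allclose(readout.W_out, oracle, atol=1e-8)

    def test_zero_residual_when_target_is_an_input_column(self):
        x, states, _ = self._instance()
        cfg = ESNConfig(transient=0)
        readout = fit_readout(x, states, x[:, [0]], cfg)
        y_hat = predict(x, states, readout)
        np.testing.assert_allclose(y_hat, x[:, [0]], atol=1e-10)

    def test_transient_rows_excluded(self):
        x, states, y = self._instance(T=60)
        # corrupt the first 10 target rows; with transient=10 the fit is unaffected
        y_bad = y.copy()
        y_bad[:10] = 1e6
        a = fit_readout(x, states, y, ESNConfig(transient=10))
        b = fit_readout(x, states, y_bad, ESNConfig(transient=10))
        np.testing.assert_array_equal(a.W_out, b.W_out)

    def test_nan_target_rows_dropped(self):
        x, states, y = self._instance(T=60)
        y_nan = y.copy()
        y_nan[:20] = np.nan
        readout = fit_readout(x, states, y_nan, ESNConfig(transient=0))
        oracle = fit_readout(x[20:], states[20:], y[20:], ESNConfig(transient=0))
        np.testing.assert_allclose(readout.W_out, oracle.W_out, atol=1e-12)

    def test_too_few_steps_rejected(self):
        x, states, y = self._instance(T=10)
        with pytest.raises(DegenerateInputError):
            fit_readout(x, states, y, ESNConfig(transient=10))

    def test_relu_predictions_nonnegative(self):
        x, states, _ = self._instance()
        readout = Readout(W_out=np.random.default_rng(1).normal(size=(1, 6)),
                          output_activation="relu")
        assert np.all(predict(x, states, readout) >= 0)

    def test_zero_readout_gives_zero_predictions(self):
        x, states, _ = self._instance()
        readout = Readout(W_out=np.zeros((1, 6)))
        assert np.all(predict(x, states, readout) == 0)


class TestDelayLineOracle:
    """A hand-built linear shift reservoir is a perfect delay line: state i
    holds x(t-i+1), so every lag tau <= N_r - 1 is reconstructed exactly."""

    def test_per_lag_scores_all_one(self):
        n = 12
        W = np.eye(n, k=-1)  # subdiagonal shift
        W_in = np.zeros((n, 1))
        W_in[0, 0] = 1.0
        cfg = ESNConfig(reservoir_activation="identity", bias=0.0,
                        input_scaling=1.0, transient=20)
        lags = tuple(range(1, n))  # 1..11
        ds = make_memory_capacity_data(400, lags, seed=0)
        train, test = ds.split(300)
        traj = run_reservoir(train.x, W, W_in, cfg)
        # closed-form unrolling: r_i(t) = x(t - i + 1)
        for i in range(n):
            np.testing.assert_allclose(
                traj.states[n:, i], train.x[n - i:train.x.shape[0] - i, 0], atol=1e-12
            )
        readout = fit_readout(train.x, traj.states, train.y, cfg)
        test_traj = run_reservoir(test.x, W, W_in, cfg)
        y_hat = predict(test.x, test_traj.states, readout)
        ev = score_memory_capacity(test.y, y_hat, lags, transient=cfg.transient)
        np.testing.assert_allclose(ev.per_output_scores, 1.0, atol=1e-9)
        assert ev.aggregate == pytest.approx(len(lags), abs=1e-8)


class TestModelAPI:
    def test_fit_predict_summary(self, modular_connectome):
        r = make_bio_no_rank(modular_connectome, seed=0)
        model = BioESN(r, 1, ESNConfig(seed=1, transient=50))
        ds = make_memory_capacity_data(900, range(1, 6), seed=2)
        train, test = ds.split(700)
        res = model.fit(train.x, train.y)
        assert res.fittedvalues.shape == (700, 5)
        y_hat = res.predict(test.x)
        assert y_hat.shape == (200, 5)
        text = res.summary()
        assert "bio_no_rank" in text and "0.99" in text

    def test_model_scales_reservoir_to_config_radius(self, modular_connectome):
        r = make_bio_no_rank(modular_connectome, seed=0)
        model = BioESN(r, 1, ESNConfig(seed=1))
        assert np.max(np.abs(np.linalg.eigvals(model.W))) == pytest.approx(0.99, rel=1e-8)

    def test_fit_is_deterministic(self, small_connectome):
        def one():
            r = make_bio_no_rank(small_connectome, seed=3)
            model = BioESN(r, 1, ESNConfig(seed=4, transient=20))
            ds = make_memory_capacity_data(400, range(1, 4), seed=5)
            train, _ = ds.split(300)
            return model.fit(train.x, train.y).readout.W_out

        np.testing.assert_array_equal(one(), one())

    def test_from_condition_dispatch(self, small_connectome):
        m = BioESN.from_condition(small_connectome, "bio-no-rank", seed=0,
                                  config=ESNConfig(seed=1))
        assert m.reservoir.condition == "bio_no_rank"
        with pytest.raises(ValidationError):
            BioESN.from_condition(small_connectome, "bio_ranked", seed=0)

    def test_explicit_input_weights_shape_checked(self, small_connectome):
        r = make_bio_no_rank(small_connectome, seed=0)
        with pytest.raises(ValidationError):
            BioESN(r, 1, ESNConfig(seed=1), input_weights=np.ones((3, 1)))
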