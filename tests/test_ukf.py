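import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sleepda as sd
from sleepda.ukf import (FilterState, ObservationSpec, UKFConfig, assimilate,
                         correct, predict, sigma_points)

from conftest import LinearMapModel, kalman_filter


class IdentityModel:
    def step_points(self, X, t, dt):
        return X


class TestSigmaPoints:
    def test_scalar_case(self):
        pts, w = sigma_points(np.array([0.0]), np.array([[4.0]]))
        assert sorted(pts.ravel()) == [-2.0, 2.0]
        assert np.allclose(w, 0.5)

    def test_weighted_mean_is_estimate(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((4, 4))
        P = A @ A.T + 0.1 * np.eye(4)
        x = rng.standard_normal(4)
        pts, w = sigma_points(x, P)
        assert np.allclose(pts @ w, x)

    def test_two_dim_identity(self):
        pts, w = sigma_points(np.zeros(2), np.eye(2))
        norms = np.linalg.norm(pts, axis=0)
        assert np.allclose(norms, np.sqrt(2))
        cov = (pts * w) @ pts.T
        assert np.allclose(cov, np.eye(2))

    @given(st.integers(1, 6), st.integers(0, 1000))
    @settings(max_examples=30, derandomize=True)
    def test_weighted_covariance_reconstructs_P(self, n, seed):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((n, n))
        P = A @ A.T + 1e-3 * np.eye(n)
        x = rng.standard_normal(n)
        pts, w = sigma_points(x, P)
        d = pts - x[:, None]
        assert np.allclose((d * w) @ d.T, P, atol=1e-8)

    def test_near_singular_repaired_by_jitter(self):
        P = np.diag([1.0, 0.0])  # semidefinite
        pts, _ = sigma_points(np.zeros(2), P)
        assert np.all(np.isfinite(pts))


class TestPredict:
    def test_static_model_no_inflation(self):
        fs = FilterState(np.array([1.0, -2.0]), np.diag([0.5, 0.2]))
        cfg = UKFConfig(model=IdentityModel(), dt=1.0, Q=np.zeros(2))
        pred, _ = predict(fs, cfg)
        assert np.allclose(pred.x_hat, fs.x_hat)
        assert np.allclose(pred.P, fs.P)

    def test_identity_model_grows_by_q(self):
        fs = FilterState(np.zeros(3), np.eye(3))
        cfg = UKFConfig(model=IdentityModel(), dt=1.0, Q=np.full(3, 0.1))
        pred, _ = predict(fs, cfg)
        assert np.allclose(pred.P, 1.1 * np.eye(3))

    def test_linear_model_matches_fpf_plus_q(self, linear_model):
        rng = np.random.default_rng(7)
        A = rng.standard_normal((3, 3))
        P = A @ A.T + 0.2 * np.eye(3)
        q = np.array([0.01, 0.02, 0.03])
        fs = FilterState(rng.standard_normal(3), P)
        cfg = UKFConfig(model=linear_model, dt=1.0, Q=q)
        pred, _ = predict(fs, cfg)
        Phi = linear_model.Phi
        assert np.allclose(pred.P, Phi @ P @ Phi.T + np.diag(q), atol=1e-8)
        assert np.allclose(pred.x_hat, Phi @ fs.x_hat, atol=1e-10)


class TestCorrect:
    def setup_method(self):
        self.fs = FilterState(np.zeros(2), np.eye(2))
        self.cfg = UKFConfig(model=IdentityModel(), dt=1.0, Q=np.zeros(2))
        self.obs = ObservationSpec(np.array([0]))

    def test_infinite_noise_keeps_prediction(self):
        pred, pts = predict(self.fs, self.cfg)
        out = correct(pred, pts, np.array([5.0]), self.obs, np.array([[1e12]]))
        assert np.allclose(out.x_hat, pred.x_hat, atol=1e-9)

    def test_zero_noise_pins_observed_component(self):
        pred, pts = predict(self.fs, self.cfg)
        out = correct(pred, pts, np.array([0.7]), self.obs, np.array([[1e-14]]))
        assert out.x_hat[0] == pytest.approx(0.7, abs=1e-6)

    def test_scalar_gain_half(self):
        # P_yy = 1, R = 1, direct observation -> K = 1/2
        pred, pts = predict(self.fs, self.cfg)
        out = correct(pred, pts, np.array([2.0]), self.obs, np.array([[1.0]]))
        assert out.x_hat[0] == pytest.approx(1.0)  # (0 + 2)/2

    def test_nonfinite_observation_rejected(self):
        pred, pts = predict(self.fs, self.cfg)
        with pytest.raises(ValueError):
            correct(pred, pts, np.array([np.nan]), self.obs, np.array([[1.0]]))


class TestAssimilate:
    def test_noise_free_self_consistency(self, db_model):
        """Truth from the filter model, exact initial state, Q=0: the
        reconstruction reproduces the truth."""
        p = db_model.params.copy()
        p.set("noise_rate", 0.0)
        m = sd.SleepModel(p)
        truth = m.simulate(600.0, 0.5)
        names = list(m.state_names)
        y = truth[["F_LC"]].to_numpy()[1:]
        spec = ObservationSpec(m.index_of("F_LC"), np.array([1e-6]))
        cfg = UKFConfig(model=m, dt=0.5, Q=np.zeros(12), R=np.array([1e-6]))
        xs, _, _ = assimilate(y, spec, cfg, m.default_state(),
                              1e-12 * np.eye(12))
        X = truth.iloc[1:, 1:].to_numpy()
        assert np.abs(xs - X).max() < 1e-4

    def test_linear_gaussian_matches_exact_kalman_filter(self, linear_model):
        rng = np.random.default_rng(0)
        Phi = linear_model.Phi
        H = np.array([[1.0, 0.0, 0.0]])
        Rv = 0.05
        x = np.array([1.0, -0.5, 0.2])
        ys = []
        for _ in range(1000):
            x = Phi @ x
            ys.append([x[0] + rng.normal(0, np.sqrt(Rv))])
        ys = np.array(ys)
        spec = ObservationSpec(np.array([0]), np.array([Rv]))
        cfg = UKFConfig(model=linear_model, dt=1.0, Q=np.zeros(3),
                        R=np.array([Rv]))
        xs, Ps, _ = assimilate(ys, spec, cfg, np.zeros(3), np.eye(3),
                               engine="python")
        kx, kP = kalman_filter(Phi, H, np.zeros((3, 3)), np.array([[Rv]]),
                               ys, np.zeros(3), np.eye(3))
        assert np.abs(xs - kx).max() < 1e-8
        assert np.abs(Ps - kP[:, range(3), range(3)]).max() < 1e-8

    def test_engines_agree_on_sleep_model(self, db_model, variances):
        truth = db_model.simulate(600.0, 0.5, seed=9)
        y, spec = sd.observe(truth, "F_LC", 0.04, seed=10, model=db_model)
        cfg = UKFConfig(model=db_model, dt=0.5,
                        Q=sd.default_q(db_model, variances),
                        R=spec.noise_variances)
        x0, P0 = db_model.default_state(), np.diag(variances)
        xs_nb, Ps_nb, _ = assimilate(y[1:], spec, cfg, x0, P0, engine="numba")
        xs_py, Ps_py, _ = assimilate(y[1:], spec, cfg, x0, P0, engine="python")
        assert np.allclose(xs_nb, xs_py, atol=1e-8)
        assert np.allclose(Ps_nb, Ps_py, atol=1e-8)

    def test_missing_observations_predict_only(self, linear_model):
        ys = np.full((5, 1), np.nan)
        spec = ObservationSpec(np.array([0]), np.array([0.1]))
        cfg = UKFConfig(model=linear_model, dt=1.0, Q=np.zeros(3),
                        R=np.array([0.1]))
        x0 = np.array([1.0, 0.0, 0.0])
        xs, _, _ = assimilate(ys, spec, cfg, x0, np.eye(3), engine="python")
        free = x0.copy()
        for k in range(5):
            free = linear_model.Phi @ free
            assert np.allclose(xs[k], free, atol=1e-12)

    def test_covariance_symmetric_psd_throughout(self, db_model, variances):
        truth = db_model.simulate(600.0, 0.5, seed=15)
        y, spec = sd.observe(truth, "F_LC", 0.04, seed=16, model=db_model)
        cfg = UKFConfig(model=db_model, dt=0.5,
                        Q=sd.default_q(db_model, variances),
                        R=spec.noise_variances)
        _, Ps, fs = assimilate(y[1:], spec, cfg, db_model.default_state(),
                               np.diag(variances))
        assert np.all(Ps > -1e-10)  # diagonals non-negative at every step
        assert np.allclose(fs.P, fs.P.T)
        assert np.linalg.eigvalsh(fs.P).min() > -1e-8

    def test_inflation_monotonicity_of_gain(self, db_model, variances):
        """Raising one Q entry does not decrease the corresponding
        Kalman-gain row norm at the next correction."""
        truth = db_model.simulate(300.0, 0.5, seed=20)
        y, spec = sd.observe(truth, "F_LC", 0.04, seed=21, model=db_model)
        x0, P0 = db_model.default_state(), np.diag(variances)
        i = list(db_model.state_names).index("F_VLPO")

        def gain_row_norm(qi):
            q = sd.default_q(db_model, variances)
            q[i] = qi
            cfg = UKFConfig(model=db_model, dt=0.5, Q=q, R=spec.noise_variances)
            # one step to apply Q, then measure the gain at the next correction
            fs = FilterState(x0, P0)
            t = 0.0
            for k in range(2):
                fs, pts = predict(fs, cfg, t)
                if k == 1:
                    n = x0.size
                    dX = pts - pts.mean(axis=1, keepdims=True)
                    dY = dX[spec.observed_indices]
                    Pyy = dY @ dY.T / (2 * n)
                    Pxy = dX @ dY.T / (2 * n)
                    K = Pxy @ np.linalg.inv(Pyy + np.diag(spec.noise_variances))
                    return np.linalg.norm(K[i])
                fs = correct(fs, pts, y[1 + k], spec,
                             np.diag(spec.noise_variances))
                t += 0.5

        norms = [gain_row_norm(q) for q in (1e-6, 1e-4, 1e-2)]
        assert norms[0] <= norms[1] <= norms[2]

    def test_q_validation(self, db_model):
        cfg = UKFConfig(model=db_model, dt=0.5, Q=-np.ones(12))
        with pytest.raises(ValueError):
            cfg.q_diag(12)


def test_default_q_scales_with_variances(db_model, variances):
    q = sd.default_q(db_model, variances, multiplier=1e-4)
    assert np.allclose(q, 1e-4 * variances)


def test_observe_noise_variance_fraction(db_model, short_truth):
    y, spec = sd.observe(short_truth, "F_LC", 0.04, seed=2, model=db_model)
    resid = y[:, 0] - short_truth["F_LC"].to_numpy()
    frac = resid.var() / short_truth["F_LC"].var()
    assert frac == pytest.approx(0.04, rel=0.15)
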