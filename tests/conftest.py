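import numpy as np
import pytest

import sleepda as sd


@pytest.fixture(scope="session")
def db_model():
    return sd.SleepModel(variant="db")


@pytest.fixture(scope="session")
def fbfd_model():
    return sd.SleepModel(variant="fbfd")


@pytest.fixture(scope="session")
def variances(db_model):
    """Typical per-variable variances from the reference simulation."""
    return sd.typical_variances(db_model)


@pytest.fixture(scope="session")
def short_truth(db_model):
    """A 30-minute noisy trajectory used by several unit tests."""
    return db_model.simulate(1800.0, 0.5, seed=101)


@pytest.fixture(scope="session")
def obsmap(db_model):
    """State-conditioned observation map from a 6 h model run."""
    return sd.build_observation_map(db_model, duration=6 * 3600.0, seed=11)


@pytest.fixture(scope="session")
def smooth_nrem_state(db_model):
    """A state inside a NREM bout of the deterministic system, away from
    the homeostatic switching threshold (the vector field is smooth in a
    neighbourhood of the trajectory that follows)."""
    p = db_model.params.copy()
    p.set("noise_rate", 0.0)
    m = sd.SleepModel(p)
    traj = m.simulate(3 * 3600.0, 0.5)
    sov = sd.score_sov(traj, p)
    flc = traj["F_LC"].to_numpy()
    for k in range(7200, len(sov) - 200):
        seg = slice(k, k + 120)
        if np.all(sov[seg] == 1) and flc[seg].max() < 2.5 and flc[seg].min() > 0.05:
            return traj.iloc[k, 1:].to_numpy()
    raise RuntimeError("no smooth NREM window found in reference run")


class LinearMapModel:
    """Discrete linear map exposing the filter-model protocol."""

    def __init__(self, Phi):
        self.Phi = np.asarray(Phi, dtype=float)

    def step_points(self, X, t, dt):
        return self.Phi @ X


@pytest.fixture(scope="session")
def linear_model():
    Phi = np.array([[0.95, 0.10, 0.00],
                    [-0.10, 0.90, 0.05],
                    [0.00, -0.05, 0.97]])
    return LinearMapModel(Phi)


def kalman_filter(Phi, H, Q, R, ys, x0, P0):
    """Closed-form Kalman filter oracle for x_{k+1} = Phi x_k, y = H x + v."""
    Phi, H = np.asarray(Phi, float), np.atleast_2d(np.asarray(H, float))
    x, P = np.asarray(x0, float).copy(), np.asarray(P0, float).copy()
    xs, Ps = [], []
    for y in np.atleast_2d(ys):
        x = Phi @ x
        P = Phi @ P @ Phi.T + Q
        S = H @ P @ H.T + R
        K = P @ H.T @ np.linalg.inv(S)
        x = x + K @ (np.atleast_1d(y) - H @ x)
        P = P - K @ S @ K.T
        xs.append(x.copy())
        Ps.append(P.copy())
    return np.array(xs), np.array(Ps)
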