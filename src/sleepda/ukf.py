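"""Unscented Kalman filter for state reconstruction from sparse observations.

The filter follows the symmetric 2n-sigma-point formulation: points are
placed at the estimate plus/minus the columns of a matrix square root of
``n*P`` and carry equal weights ``1/(2n)``, so their weighted mean and
covariance reproduce the estimate and its uncertainty exactly.  Each
prediction propagates the points one step through the deterministic filter
model; the forecast covariance is the sample covariance of the propagated
points plus a diagonal covariance-inflation matrix Q that accounts for
process noise and model inadequacy.  The correction weighs forecast against
measurement through the Kalman gain ``K = P_xy (P_yy + R)^-1``.

Two execution engines produce identical results: a generic pure-NumPy path
that accepts any model exposing ``step_points(X, t, dt)``, and a compiled
fast path for the sleep-wake models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .models import SleepModel

__all__ = [
    "FilterState", "ObservationSpec", "UKFConfig",
    "sigma_points", "predict", "correct", "assimilate",
    "default_q", "typical_variances", "observe",
    "FilterNumericalError",
]

_JITTERS = (0.0, 1e-12, 1e-10, 1e-8, 1e-6)


class FilterNumericalError(RuntimeError):
    """Covariance factorization or innovation solve failed beyond repair."""


@dataclass
class FilterState:
    """UKF mean estimate and covariance at one iteration."""

    x_hat: np.ndarray
    P: np.ndarray
    k: int = 0

    def __post_init__(self):
        self.x_hat = np.asarray(self.x_hat, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        n = self.x_hat.size
        if self.P.shape != (n, n):
            raise ValueError("P must be n-by-n")
        if not np.allclose(self.P, self.P.T, atol=1e-10):
            raise ValueError("P must be symmetric")


@dataclass
class ObservationSpec:
    """Which state components are measured and with what noise variance."""

    observed_indices: np.ndarray
    noise_variances: np.ndarray | None = None
    names: tuple = ()

    def __post_init__(self):
        self.observed_indices = np.asarray(self.observed_indices, dtype=np.int64)
        if len(np.unique(self.observed_indices)) != self.observed_indices.size:
            raise ValueError("observed indices must be unique")
        if self.noise_variances is not None:
            self.noise_variances = np.asarray(self.noise_variances, dtype=float)

    @classmethod
    def from_names(cls, model: SleepModel, names, noise_variances=None):
        names = [names] if isinstance(names, str) else list(names)
        return cls(model.index_of(names), noise_variances, tuple(names))

    @property
    def m(self) -> int:
        return self.observed_indices.size


@dataclass
class UKFConfig:
    """Filter configuration: model, step, inflation Q and noise R.

    ``Q`` is the diagonal of the covariance inflater (length n, all
    entries >= 0).  ``R`` may be a scalar, an m-vector (diagonal), an
    m-by-m matrix, or a T-by-m array of per-step diagonal entries for
    time-varying measurement uncertainty.
    """

    model: object
    dt: float = 0.5
    Q: np.ndarray = None
    R: np.ndarray = None

    def q_diag(self, n: int) -> np.ndarray:
        if self.Q is None:
            return np.zeros(n)
        q = np.asarray(self.Q, dtype=float).ravel()
        if q.size == 1:
            q = np.full(n, q[0])
        if q.size != n:
            raise ValueError(f"Q diagonal has size {q.size}, expected {n}")
        if np.any(q < 0):
            raise ValueError("Q diagonal entries must be >= 0")
        return q


def _matrix_sqrt_columns(P: np.ndarray) -> np.ndarray:
    """Lower-Cholesky factor of n*P with escalating diagonal jitter."""
    n = P.shape[0]
    A = n * P
    for jit in _JITTERS:
        try:
            return np.linalg.cholesky(A + jit * n * np.eye(n))
        except np.linalg.LinAlgError:
            continue
    raise FilterNumericalError("covariance square root failed after max jitter")


def sigma_points(x_hat: np.ndarray, P: np.ndarray):
    """Symmetric sigma points: x +/- columns of sqrt(n*P), weights 1/(2n).

    Returns ``(points, weights)`` with points of shape (n, 2n).  The weighted
    mean of the points is ``x_hat`` and their weighted covariance is ``P``.
    """
    x_hat = np.asarray(x_hat, dtype=float)
    P = np.asarray(P, dtype=float)
    n = x_hat.size
    L = _matrix_sqrt_columns(P)
    pts = np.empty((n, 2 * n))
    pts[:, :n] = x_hat[:, None] + L
    pts[:, n:] = x_hat[:, None] - L
    return pts, np.full(2 * n, 1.0 / (2 * n))


def predict(fs: FilterState, cfg: UKFConfig, t: float = 0.0):
    """Forecast step: propagate sigma points through the filter model.

    Returns the predicted :class:`FilterState` and the propagated points
    (needed by :func:`correct`).  Predicted covariance is the sample
    covariance of the propagated points plus diag(Q).
    """
    n = fs.x_hat.size
    pts, _ = sigma_points(fs.x_hat, fs.P)
    prop = cfg.model.step_points(pts, t, cfg.dt)
    xpred = prop.mean(axis=1)
    dX = prop - xpred[:, None]
    Pp = dX @ dX.T / (2 * n) + np.diag(cfg.q_diag(n))
    return FilterState(xpred, 0.5 * (Pp + Pp.T), fs.k + 1), prop


def correct(predicted: FilterState, prop_points: np.ndarray, y: np.ndarray,
            obs: ObservationSpec, R: np.ndarray) -> FilterState:
    """Measurement update with gain ``K = P_xy (P_yy + R)^-1``."""
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if not np.all(np.isfinite(y)):
        raise ValueError("observation contains non-finite values")
    n = predicted.x_hat.size
    m = obs.m
    R = np.asarray(R, dtype=float)
    if R.ndim == 0:
        R = np.eye(m) * R
    elif R.ndim == 1:
        R = np.diag(R)
    xpred = predicted.x_hat
    dX = prop_points - prop_points.mean(axis=1, keepdims=True)
    dY = dX[obs.observed_indices]
    Pyy = dY @ dY.T / (2 * n)
    Pxy = dX @ dY.T / (2 * n)
    S = Pyy + R
    try:
        K = np.linalg.solve(S.T, Pxy.T).T
    except np.linalg.LinAlgError as e:
        raise FilterNumericalError(f"singular innovation covariance: {e}") from e
    x = xpred + K @ (y - xpred[obs.observed_indices])
    P = predicted.P - K @ S @ K.T
    return FilterState(x, 0.5 * (P + P.T), predicted.k)


def _normalize_R(R, T: int, m: int) -> np.ndarray:
    """Normalize R input to a (T, m) array of per-step diagonals."""
    R = np.asarray(R, dtype=float)
    if R.ndim == 0:
        return np.full((T, m), float(R))
    if R.ndim == 1:
        if R.size != m:
            raise ValueError("R diagonal length must equal number of observations")
        return np.tile(R, (T, 1))
    if R.ndim == 2 and R.shape == (m, m):
        if not np.allclose(R, np.diag(np.diag(R))):
            raise ValueError("time-constant full R must be diagonal for this path")
        return np.tile(np.diag(R), (T, 1))
    if R.ndim == 2 and R.shape == (T, m):
        return R
    raise ValueError(f"cannot interpret R with shape {R.shape}")


def assimilate(observations: np.ndarray, obs: ObservationSpec, cfg: UKFConfig,
               x0: np.ndarray, P0: np.ndarray, t0: float = 0.0,
               engine: str = "auto"):
    """Run the full predict/correct recursion over an observation series.

    ``observations`` has shape (T, m); row k is the measurement at time
    ``t0 + (k+1)*dt``.  Rows with non-finite entries are treated as missing
    (predict-only).  Returns ``(xs, var, fs)``: reconstructed means (T, n),
    per-step covariance diagonals (T, n), and the final filter state.

    The filter model is deterministic: for the sleep models the thalamic
    impulse generator is excluded, delta decays freely and its uncertainty
    is supplied by Q.
    """
    y = np.atleast_2d(np.asarray(observations, dtype=float))
    if y.shape[1] != obs.m:
        raise ValueError("observation width does not match ObservationSpec")
    T = y.shape[0]
    x0 = np.asarray(x0, dtype=float)
    n = x0.size
    P0 = np.asarray(P0, dtype=float)
    qdiag = cfg.q_diag(n)
    Rd = _normalize_R(cfg.R if cfg.R is not None else obs.noise_variances, T, obs.m)

    use_numba = engine == "numba" or (engine == "auto" and isinstance(cfg.model, SleepModel))
    if use_numba:
        if not isinstance(cfg.model, SleepModel):
            raise ValueError("numba engine requires a SleepModel filter model")
        xs, Ps, Pfin, bad = _kernel._ukf_loop(
            np.ascontiguousarray(y), obs.observed_indices,
            np.ascontiguousarray(Rd), qdiag, x0,
            np.ascontiguousarray(P0), cfg.model._theta, cfg.dt,
            cfg.model._code, t0)
        if bad >= 0:
            raise FilterNumericalError(f"sigma-point factorization failed at step {bad}")
        return xs, Ps, FilterState(xs[-1], Pfin, T)

    fs = FilterState(x0, P0)
    xs = np.empty((T, n))
    Ps = np.empty((T, n))
    t = t0
    for k in range(T):
        fs, prop = predict(fs, cfg, t)
        if np.all(np.isfinite(y[k])):
            fs = correct(fs, prop, y[k], obs, np.diag(Rd[k]))
        xs[k] = fs.x_hat
        Ps[k] = np.diag(fs.P)
        t = t0 + (k + 1) * cfg.dt
    return xs, Ps, fs


def typical_variances(model: SleepModel, duration: float = 4 * 3600.0,
                      dt: float = 0.5, seed: int = 12345,
                      transient: float = 1800.0) -> np.ndarray:
    """Per-variable variances from a reference simulation (noise on), used
    to scale the default inflation Q and initial covariance."""
    traj = model.simulate(duration, dt, seed=seed)
    X = traj.iloc[int(transient / dt):, 1:].to_numpy()
    v = X.var(axis=0)
    return np.maximum(v, 1e-10)


def default_q(model: SleepModel, variances: np.ndarray | None = None,
              multiplier: float = 1e-4) -> np.ndarray:
    """Default inflation diagonal: ``multiplier`` times each variable's
    typical variance."""
    if variances is None:
        variances = typical_variances(model)
    return multiplier * np.asarray(variances, dtype=float)


def observe(traj, names, noise_frac: float = 0.04, seed: int | None = None,
            model: SleepModel | None = None):
    """Identical-twin observation operator.

    Selects the named columns of a truth trajectory and adds independent
    zero-mean Gaussian noise with variance ``noise_frac`` times each
    variable's variance over the series.  Returns ``(y, spec)`` where the
    ObservationSpec carries the per-channel noise variances used.
    """
    names = [names] if isinstance(names, str) else list(names)
    rng = np.random.default_rng(seed)
    cols = traj[names].to_numpy()
    var = cols.var(axis=0)
    noise_var = noise_frac * var
    y = cols + rng.standard_normal(cols.shape) * np.sqrt(noise_var)
    if model is None:
        model = SleepModel()
    spec = ObservationSpec.from_names(model, names, noise_var)
    return y, spec
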