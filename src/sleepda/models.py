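"""Simulators for the core (DB) and circadian (FBFD) sleep-wake network models.

The core model has 12 state variables: five population firing rates (LC, DR,
VLPO, R, WR), the five transmitter concentrations they release (NE, 5-HT,
GABA, and ACh separately from R and WR), the homeostatic sleep drive ``h``
and the leaky-integrated thalamic noise input ``delta``.  The circadian
variant appends the SCN firing rate and its GABAergic output.

Dynamics: each firing rate relaxes toward a sigmoidal function of its
weighted transmitter input sum (total ACh being the sum of the R and WR
contributions); each concentration relaxes toward a saturating function of
its source population's rate; ``h`` accumulates while the LC rate exceeds a
wake threshold and dissipates otherwise; ``delta`` integrates Poisson
impulses and decays.  Integration is classical 4th-order Runge-Kutta with
impulses applied between steps, so the deterministic part keeps full order.

The scored state of vigilance (Wake / NREM / REM) is derived from the
rank-ordered firing rates, REM-active activity taking precedence.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import _kernel
from .params import (DB_STATE_NAMES, FBFD_STATE_NAMES, CellGroupParams,
                     HomeostaticParams, ModelParams, SCNParams,
                     ThalamicNoiseParams, default_params)

__all__ = [
    "WAKE", "NREM", "REM", "SOV_LABELS",
    "IntegrationError", "SleepModel",
    "steady_state_firing", "steady_state_concentration",
    "homeostatic_derivative", "thalamic_noise_step", "circ_drive",
    "model_derivative", "simulate", "score_sov",
]

WAKE, NREM, REM = 0, 1, 2
SOV_LABELS = {WAKE: "Wake", NREM: "NREM", REM: "REM"}

#: default vigilance-scoring thresholds, as fractions of F_max
REM_THRESHOLD_FRAC = 0.3
WAKE_THRESHOLD_FRAC = 0.5


class IntegrationError(RuntimeError):
    """Raised when the integrator produces a non-finite state."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(f"non-finite state at integration step {step}")


def steady_state_firing(c_in: float, group: CellGroupParams, h: float = 0.0) -> float:
    """Steady-state firing rate for input concentration ``c_in``.

    ``F_inf(c) = (F_max/2) * (1 + tanh((c - beta)/alpha))``; for the VLPO the
    midpoint is ``beta - h_gain*h`` so the homeostatic drive lowers the
    firing threshold.
    """
    if group.alpha == 0:
        raise ValueError("alpha must be nonzero")
    beta = group.beta - group.h_gain * h
    return 0.5 * group.F_max * (1.0 + math.tanh((c_in - beta) / group.alpha))


def steady_state_concentration(F: float, group: CellGroupParams) -> float:
    """Steady-state released concentration, ``tanh(F / gamma)``.

    Monotone and saturating; zero at zero firing.
    """
    if F < 0:
        raise ValueError("firing rate must be >= 0")
    return math.tanh(F / group.gamma)


def homeostatic_derivative(h: float, F_wake: float, p: HomeostaticParams) -> float:
    """dh/dt: accumulate toward ``h_max`` while the wake-active rate exceeds
    ``theta``, dissipate toward 0 otherwise."""
    if F_wake > p.theta:
        return (p.h_max - h) / p.tau_acc
    return -h / p.tau_diss


def thalamic_noise_step(delta: float, dt: float, p: ThalamicNoiseParams,
                        rng: np.random.Generator) -> float:
    """Advance the thalamic noise concentration one step: exponential decay
    plus Poisson(rate*dt) impulses of ``impulse_amplitude`` each."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    out = delta * math.exp(-dt / p.tau_delta)
    k = rng.poisson(p.rate * dt)
    return out + p.impulse_amplitude * k


def circ_drive(t: float, p: SCNParams) -> float:
    """Circadian input to the SCN: a 24 h sinusoid peaking mid-light, with
    light onset at ``phase_shift`` (default 06:00)."""
    return p.circ_offset + p.circ_amplitude * math.sin(
        2.0 * math.pi * (t - p.phase_shift) / p.circ_period
    )


class SleepModel:
    """A sleep-wake network model: parameters plus a variant.

    ``variant`` is ``"db"`` (core, 12 variables) or ``"fbfd"`` (circadian,
    14 variables).  Instances are the filter model of the UKF as well as the
    synthetic-truth generator: :meth:`simulate` adds the Poisson thalamic
    impulses, while :meth:`step_points` (used by the filter) integrates the
    deterministic skeleton only, so ``delta`` decays freely inside the
    filter and its uncertainty is carried entirely by the inflation Q.
    """

    def __init__(self, params: ModelParams | None = None, variant: str = "db"):
        if variant not in ("db", "fbfd"):
            raise ValueError(f"unknown variant {variant!r}")
        self.params = params if params is not None else default_params()
        self.params.validate()
        self.variant = variant
        self._code = 0 if variant == "db" else 1
        self._theta = self.params.to_vector()

    # -- introspection ----------------------------------------------------

    @property
    def state_names(self) -> tuple:
        return DB_STATE_NAMES if self.variant == "db" else FBFD_STATE_NAMES

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def index_of(self, names) -> np.ndarray:
        """Indices of canonical variable names in the state vector."""
        if isinstance(names, str):
            names = [names]
        lookup = {nm: i for i, nm in enumerate(self.state_names)}
        try:
            return np.array([lookup[nm] for nm in names], dtype=np.int64)
        except KeyError as e:
            raise KeyError(f"unknown state variable {e.args[0]!r} "
                           f"for variant {self.variant}") from None

    def with_param(self, name: str, value: float) -> "SleepModel":
        """Copy of this model with one flat-named parameter replaced."""
        return SleepModel(self.params.replace(name, value), self.variant)

    # -- dynamics ---------------------------------------------------------

    def derivative(self, x: np.ndarray, t: float = 0.0) -> np.ndarray:
        """Deterministic time derivative of the state vector."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_states,):
            raise ValueError(
                f"state dimension {x.shape} does not match variant "
                f"{self.variant!r} (expected ({self.n_states},))")
        out = np.empty((self.n_states, 1))
        _kernel._rhs_mat(x.reshape(-1, 1), t, self._theta, self._code, out)
        return out[:, 0]

    def step_points(self, X: np.ndarray, t: float, dt: float) -> np.ndarray:
        """One deterministic RK4 step for a batch of states (columns)."""
        return _kernel._rk4_mat(np.ascontiguousarray(X, dtype=float),
                                t, dt, self._theta, self._code)

    def default_state(self) -> np.ndarray:
        """A generic waking initial condition with moderate sleep pressure."""
        x0 = np.zeros(self.n_states)
        x0[0] = 5.0    # F_LC
        x0[5] = 0.9    # C_N
        x0[10] = 0.6   # h
        return x0

    def simulate(self, duration: float, dt: float = 0.5,
                 x0: np.ndarray | None = None, seed: int | None = None,
                 t0: float = 0.0) -> pd.DataFrame:
        """Integrate for ``duration`` seconds and return a trajectory table.

        The returned DataFrame has a time column ``t`` followed by the
        canonical state columns, one row per step including the initial
        condition.  ``seed`` fixes the Poisson impulse stream; identical
        seed and configuration give bitwise-identical trajectories.
        """
        if dt <= 0:
            raise ValueError("dt must be > 0")
        if duration < dt:
            raise ValueError("duration must be >= dt")
        nsteps = int(round(duration / dt))
        if x0 is None:
            x0 = self.default_state()
        x0 = np.asarray(x0, dtype=float)
        if x0.shape != (self.n_states,):
            raise ValueError("x0 dimension does not match variant")
        rng = np.random.default_rng(seed)
        rate = self.params.noise.rate
        if rate > 0:
            impulses = rng.poisson(rate * dt, size=nsteps).astype(np.int64)
        else:
            impulses = np.zeros(nsteps, dtype=np.int64)
        X, bad = _kernel._simulate(x0, nsteps, dt, self._theta, self._code,
                                   impulses, t0)
        if bad >= 0:
            raise IntegrationError(bad)
        t = t0 + dt * np.arange(nsteps + 1)
        df = pd.DataFrame(X, columns=list(self.state_names))
        df.insert(0, "t", t)
        return df


def model_derivative(state: np.ndarray, t: float, params: ModelParams,
                     variant: str = "db") -> np.ndarray:
    """Functional wrapper around :meth:`SleepModel.derivative`."""
    return SleepModel(params, variant).derivative(state, t)


def simulate(duration: float, dt: float = 0.5, params: ModelParams | None = None,
             variant: str = "db", x0: np.ndarray | None = None,
             seed: int | None = None, t0: float = 0.0) -> pd.DataFrame:
    """Simulate a trajectory with the given parameters (see SleepModel)."""
    return SleepModel(params, variant).simulate(duration, dt, x0, seed, t0)


def score_sov(traj: pd.DataFrame, params: ModelParams | None = None,
              rem_frac: float = REM_THRESHOLD_FRAC,
              wake_frac: float = WAKE_THRESHOLD_FRAC) -> np.ndarray:
    """Score the state of vigilance from a trajectory.

    REM whenever the REM-active rate exceeds ``rem_frac * F_max_R``
    (REM-active activity dominates the definition); otherwise Wake when the
    LC rate exceeds ``wake_frac * F_max_LC``, else NREM.  Returns an integer
    array (0 = Wake, 1 = NREM, 2 = REM), one label per row.
    """
    params = params if params is not None else default_params()
    for col in ("F_LC", "F_VLPO", "F_R"):
        if col not in traj.columns:
            raise ValueError(f"trajectory lacks required column {col!r}")
    f_lc = traj["F_LC"].to_numpy()
    f_r = traj["F_R"].to_numpy()
    sov = np.full(len(traj), NREM, dtype=np.int64)
    sov[f_lc > wake_frac * params.groups["LC"].F_max] = WAKE
    sov[f_r > rem_frac * params.groups["R"].F_max] = REM
    return sov
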