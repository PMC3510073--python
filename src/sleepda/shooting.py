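"""Multiple-shooting parameter estimation on UKF reconstructions.

The estimator alternates between state reconstruction and parameter
updates: the UKF reconstructs the full state over a window using the
current parameter value; short model trajectories are then re-launched
("shot") from the reconstruction at regular intervals and integrated with
candidate parameter values; the candidate minimizing the weighted squared
divergence between shots and reconstruction — restricted to the measured
variables — becomes the next estimate, with the per-iteration move capped
to keep the alternation stable.  Windows are longer than a sleep-wake cycle
so the cost samples the whole state space, and overlap so slowly varying
parameters can be tracked through time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel
from .models import SleepModel
from .ukf import ObservationSpec, UKFConfig, _normalize_R, assimilate

__all__ = ["ShootingConfig", "ParamTrack", "shooting_cost",
           "estimate_parameter", "track_parameter"]


@dataclass
class ShootingConfig:
    """Window, segment and candidate-grid settings for multiple shooting.

    ``window_length`` (s) must exceed a typical sleep-wake cycle;
    ``overlap_fraction`` 0.8 gives an update period of one fifth of the
    window.  Shots are ``segment_length`` seconds long and re-anchored on
    the reconstruction every ``reinit_interval`` seconds (default: segment
    length, i.e. contiguous segments).  The candidate grid has
    ``n_candidates`` points spanning ``±grid_span_frac`` of the current
    estimate (at least ``±grid_span_floor`` in absolute terms, so estimates
    near zero keep a usable grid); the accepted move per iteration is capped
    at ``max_step_fraction`` of the current estimate or ``max_step_floor``,
    whichever is larger.
    """

    window_length: float = 1800.0
    overlap_fraction: float = 0.8
    segment_length: float = 120.0
    reinit_interval: float | None = None
    n_candidates: int = 11
    grid_span_frac: float = 0.3
    grid_span_floor: float = 0.05
    max_step_fraction: float = 0.1
    max_step_floor: float = 0.02
    refine_factor: float = 0.5
    min_span_frac: float = 0.02
    #: the estimate counts as stabilized when the relative dispersion
    #: (std/|mean|) of the last ``stable_windows`` estimates drops below
    #: ``convergence_tol``
    convergence_tol: float = 0.02
    stable_windows: int = 8
    #: hard bounds on the estimate; candidates outside are never proposed.
    #: Useful when the cost saturates (e.g. a drive strong enough to clamp
    #: the dynamics is indistinguishable from a stronger one).
    param_bounds: tuple = (-np.inf, np.inf)

    def __post_init__(self):
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.segment_length >= self.window_length:
            raise ValueError("segment_length must be shorter than the window")
        if self.reinit_interval is None:
            self.reinit_interval = self.segment_length

    @property
    def update_period(self) -> float:
        return self.window_length * (1.0 - self.overlap_fraction)


@dataclass
class ParamTrack:
    """Windowed parameter estimates: one row per (overlapping) window."""

    table: pd.DataFrame
    parameter: str
    converged: bool = False
    final_estimate: float = np.nan

    @property
    def estimates(self) -> np.ndarray:
        return self.table["estimate"].to_numpy()

    @property
    def t_center(self) -> np.ndarray:
        return self.table["t_center"].to_numpy()


def shooting_cost(model: SleepModel, param: str, p_test: float,
                  reconstruction: np.ndarray, obs: ObservationSpec,
                  cfg: ShootingConfig, dt: float = 0.5,
                  weights: np.ndarray | None = None) -> float:
    """Window-averaged squared divergence between shots and reconstruction.

    ``reconstruction`` is the (T, n) UKF output over one window.  The model
    with ``param = p_test`` is integrated deterministically from the
    reconstructed state at each segment anchor; the cost is the average over
    all shot samples of the squared, weight-scaled error on the *measured*
    variables only.  Weights default to the reciprocal standard deviation of
    each measured variable over the window's reconstruction.  A candidate
    whose integration fails is infeasible (infinite cost).
    """
    recon = np.asarray(reconstruction, dtype=float)
    T, n = recon.shape
    seg = int(round(cfg.segment_length / dt))
    step = int(round(cfg.reinit_interval / dt))
    if seg < 1 or step < 1:
        raise ValueError("segment and reinit interval must span >= 1 step")
    midx = obs.observed_indices
    if weights is None:
        stds = recon[:, midx].std(axis=0)
        if np.any(stds <= 0):
            raise ValueError("zero variance in a measured variable over the window")
        weights = 1.0 / stds
    try:
        m = model.with_param(param, p_test)
    except ValueError:
        return np.inf  # candidate violates a parameter invariant: infeasible
    zero_imp = np.zeros(seg, dtype=np.int64)
    sq = 0.0
    count = 0
    for start in range(0, T - 1, step):
        length = min(seg, T - 1 - start)
        X, bad = _kernel._simulate(np.ascontiguousarray(recon[start]), length,
                                   dt, m._theta, m._code, zero_imp[:length], 0.0)
        if bad >= 0:
            return np.inf
        shot = X[1:, midx]
        ref = recon[start + 1:start + 1 + length, midx]
        err = (shot - ref) * weights
        sq += float(np.sum(err * err))
        count += err.shape[0]
    if count == 0:
        raise ValueError("window too short for any shooting segment")
    return sq / count


def _candidate_grid(p: float, span: float, cfg: ShootingConfig) -> np.ndarray:
    half = max(abs(p) * span, cfg.grid_span_floor)
    lo, hi = cfg.param_bounds
    return np.clip(np.linspace(p - half, p + half, cfg.n_candidates), lo, hi)


def _run_windows(y, Rdiag, obs, model, param, p0, cfg, ukf_cfg, x0, P0,
                 t0, stop_when_stable):
    """Shared streaming loop: assimilate, shoot, update, slide the window."""
    dt = ukf_cfg.dt
    Tw = int(round(cfg.window_length / dt))
    Tu = max(int(round(cfg.update_period / dt)), 1)
    T = y.shape[0]
    if T < Tw:
        raise ValueError("observation series shorter than one window")
    p_cur = float(p0)
    span = cfg.grid_span_frac
    rows = []
    interior_streak = 0
    stable = False
    fs_x, fs_P = np.asarray(x0, float), np.asarray(P0, float)
    filt = model.with_param(param, p_cur)
    ucfg = UKFConfig(model=filt, dt=dt, Q=ukf_cfg.Q, R=None)
    buf = np.empty((0, x0.size))
    pos = 0
    t = t0
    while pos < T:
        take = Tw - buf.shape[0] if buf.shape[0] < Tw else Tu
        take = min(take, T - pos)
        chunk_R = Rdiag[pos:pos + take]
        ucfg.model = model.with_param(param, p_cur)
        ucfg.R = chunk_R
        xs, _, fs = assimilate(y[pos:pos + take], obs, ucfg, fs_x, fs_P, t0=t)
        fs_x, fs_P = fs.x_hat, fs.P
        t += take * dt
        pos += take
        buf = np.vstack([buf, xs])[-Tw:]
        if buf.shape[0] < Tw:
            continue
        grid = _candidate_grid(p_cur, span, cfg)
        costs = np.array([shooting_cost(model, param, p, buf, obs, cfg, dt)
                          for p in grid])
        if not np.any(np.isfinite(costs)):
            raise RuntimeError(
                f"all shooting candidates infeasible at t={t:.0f}s "
                f"(parameter {param}, estimate {p_cur:.4g})")
        best = int(np.nanargmin(costs))
        p_new = float(grid[best])
        cap = max(abs(p_cur) * cfg.max_step_fraction, cfg.max_step_floor)
        p_next = p_cur + np.clip(p_new - p_cur, -cap, cap)
        if 0 < best < grid.size - 1:
            interior_streak += 1
            if interior_streak >= 2 and span * cfg.refine_factor >= cfg.min_span_frac:
                span *= cfg.refine_factor
                interior_streak = 0
        else:
            interior_streak = 0
        rows.append(dict(t_center=t - (Tw * dt) / 2.0, estimate=p_next,
                         min_cost=float(np.nanmin(costs)), span=span))
        p_cur = p_next
        stable = False
        if len(rows) >= cfg.stable_windows:
            recent = np.array([r["estimate"] for r in rows[-cfg.stable_windows:]])
            disp = recent.std() / max(abs(recent.mean()), 1e-12)
            stable = disp < cfg.convergence_tol
        if stop_when_stable and stable:
            break
    table = pd.DataFrame(rows)
    if stable:
        # point estimate: mean over the stabilized plateau
        final = float(np.mean([r["estimate"] for r in rows[-cfg.stable_windows:]]))
    else:
        final = p_cur
    return ParamTrack(table, param, stable, final)


def estimate_parameter(observations: np.ndarray, obs: ObservationSpec,
                       model: SleepModel, param: str, initial_guess: float,
                       cfg: ShootingConfig | None = None,
                       ukf_cfg: UKFConfig | None = None,
                       x0: np.ndarray | None = None,
                       P0: np.ndarray | None = None,
                       R: np.ndarray | None = None,
                       t0: float = 0.0) -> ParamTrack:
    """Estimate a stationary parameter by iterated shooting over windows.

    Stops once the relative change of the estimate stays below the
    convergence tolerance for ``stable_windows`` consecutive windows, or the
    data are exhausted.  ``model`` carries every parameter except ``param``,
    which starts from ``initial_guess``.
    """
    cfg = cfg or ShootingConfig()
    ukf_cfg = ukf_cfg or UKFConfig(model=model)
    y = np.atleast_2d(np.asarray(observations, dtype=float))
    Rdiag = _normalize_R(R if R is not None else obs.noise_variances,
                         y.shape[0], obs.m)
    if x0 is None:
        x0 = model.default_state()
    if P0 is None:
        P0 = np.eye(model.n_states)
    return _run_windows(y, Rdiag, obs, model, param, initial_guess, cfg,
                        ukf_cfg, x0, P0, t0, stop_when_stable=True)


def track_parameter(observations: np.ndarray, obs: ObservationSpec,
                    model: SleepModel, param: str, initial_guess: float = 0.0,
                    cfg: ShootingConfig | None = None,
                    ukf_cfg: UKFConfig | None = None,
                    x0: np.ndarray | None = None,
                    P0: np.ndarray | None = None,
                    R: np.ndarray | None = None,
                    t0: float = 0.0) -> ParamTrack:
    """Track a slowly varying parameter in overlapping windows.

    One estimate per window, anchored at the window center; the estimate is
    inherently smoothed at the window timescale.  The update period must be
    shorter than the parameter's variation timescale.
    """
    cfg = cfg or ShootingConfig()
    ukf_cfg = ukf_cfg or UKFConfig(model=model)
    y = np.atleast_2d(np.asarray(observations, dtype=float))
    Rdiag = _normalize_R(R if R is not None else obs.noise_variances,
                         y.shape[0], obs.m)
    if x0 is None:
        x0 = model.default_state()
    if P0 is None:
        P0 = np.eye(model.n_states)
    return _run_windows(y, Rdiag, obs, model, param, initial_guess, cfg,
                        ukf_cfg, x0, P0, t0, stop_when_stable=False)
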