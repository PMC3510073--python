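"""Assimilating discretized sleep state (hypnograms) instead of raw variables.

A hypnogram — the Wake/NREM/REM label per time step — is not a model
variable, but it can still drive the filter.  The state-conditioned
distributions of the firing rates are sharply separated between vigilance
states, so each label is translated into a pseudo-observation: the
state-conditioned *median* of each mapped variable, with the
state-conditioned *standard deviation* as its (time-varying) measurement
uncertainty.  The UKF then treats these inferred observations like any
other measurement series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .models import NREM, REM, SOV_LABELS, WAKE, SleepModel, score_sov
from .shooting import ParamTrack, ShootingConfig, estimate_parameter
from .ukf import ObservationSpec, UKFConfig, assimilate

__all__ = ["Hypnogram", "StateConditionedObsMap", "build_observation_map",
           "infer_observations", "assimilate_hypnogram", "map_baseline",
           "estimate_parameter_from_hypnogram"]

_ALL_LABELS = (WAKE, NREM, REM)

#: relative variance floor applied to the state-conditioned uncertainties,
#: as a fraction of the squared variable range, to avoid singular corrections
#: when a conditional distribution is near-degenerate
VARIANCE_FLOOR_FRAC = 1e-6


@dataclass
class Hypnogram:
    """Uniformly sampled state-of-vigilance series (0=Wake, 1=NREM, 2=REM)."""

    t: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.t.shape != self.labels.shape or self.t.ndim != 1:
            raise ValueError("t and labels must be 1-d and of equal length")
        if self.t.size >= 2:
            steps = np.diff(self.t)
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise ValueError("hypnogram must be uniformly sampled")
        if not np.isin(self.labels, _ALL_LABELS).all():
            raise ValueError("labels must be from {0=Wake, 1=NREM, 2=REM}")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @classmethod
    def from_trajectory(cls, traj: pd.DataFrame, params=None) -> "Hypnogram":
        return cls(traj["t"].to_numpy(), score_sov(traj, params))

    def resample(self, dt: float) -> "Hypnogram":
        """Zero-order hold onto a finer uniform grid (e.g. the filter step)."""
        if dt > self.dt + 1e-12:
            raise ValueError("can only resample to an equal or finer step")
        t_new = np.arange(self.t[0], self.t[-1] + dt / 2, dt)
        idx = np.minimum(((t_new - self.t[0]) / self.dt).astype(np.int64),
                         self.labels.size - 1)
        return Hypnogram(t_new, self.labels[idx])


@dataclass
class StateConditionedObsMap:
    """Per-state median and spread of model variables.

    ``medians``/``stds`` are DataFrames indexed by the label names
    ("Wake", "NREM", "REM") with one column per variable.  ``mapped``
    lists the variables used as pseudo-observations (default: the three
    scored firing rates); the map may cover more variables, which is useful
    as a baseline reconstruction.
    """

    medians: pd.DataFrame
    stds: pd.DataFrame
    mapped: tuple = ("F_LC", "F_VLPO", "F_R")
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        want = [SOV_LABELS[s] for s in _ALL_LABELS]
        if list(self.medians.index) != want or list(self.stds.index) != want:
            raise ValueError("map must cover exactly the states Wake, NREM, REM")
        if (self.stds.to_numpy() <= 0).any():
            raise ValueError("state-conditioned stds must be > 0")
        for v in self.mapped:
            if v not in self.medians.columns:
                raise ValueError(f"mapped variable {v!r} missing from map")

    def to_yaml(self, path) -> None:
        doc = dict(medians=self.medians.to_dict(), stds=self.stds.to_dict(),
                   mapped=list(self.mapped), metadata=self.metadata)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StateConditionedObsMap":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        order = [SOV_LABELS[s] for s in _ALL_LABELS]
        med = pd.DataFrame(doc["medians"]).loc[order]
        std = pd.DataFrame(doc["stds"]).loc[order]
        m = cls(med, std, tuple(doc.get("mapped", ("F_LC", "F_VLPO", "F_R"))),
                doc.get("metadata", {}))
        m.validate()
        return m


def build_observation_map(model: SleepModel, duration: float = 12 * 3600.0,
                          dt: float = 0.5, seed: int = 0,
                          variables=None, transient: float = 3600.0,
                          mapped=("F_LC", "F_VLPO", "F_R")
                          ) -> StateConditionedObsMap:
    """Estimate state-conditioned medians and spreads from a model run.

    Simulates the filter model, scores the vigilance state, and computes the
    per-state median and standard deviation of each variable.  The standard
    deviations are floored at ``sqrt(VARIANCE_FLOOR_FRAC) * range`` so a
    nearly constant conditional distribution cannot produce a singular
    correction.  Raises if any vigilance state is absent from the run.
    """
    traj = model.simulate(duration, dt, seed=seed)
    skip = int(round(transient / dt))
    traj = traj.iloc[skip:]
    sov = score_sov(traj, model.params)
    if variables is None:
        variables = [c for c in traj.columns if c != "t"]
    med, std = {}, {}
    X = traj[variables]
    ranges = np.ptp(X.to_numpy(), axis=0)
    floor = np.sqrt(VARIANCE_FLOOR_FRAC) * np.maximum(ranges, 1e-6)
    for s in _ALL_LABELS:
        mask = sov == s
        if not mask.any():
            raise ValueError(
                f"vigilance state {SOV_LABELS[s]} absent from the simulation; "
                "increase the duration")
        med[SOV_LABELS[s]] = X[mask].median()
        std[SOV_LABELS[s]] = np.maximum(X[mask].std(ddof=0), floor)
    medians = pd.DataFrame(med).T
    stds = pd.DataFrame(std).T
    m = StateConditionedObsMap(
        medians, stds, tuple(mapped),
        metadata=dict(duration=duration, dt=dt, seed=seed,
                      transient=transient, source="single seeded run"))
    m.validate()
    return m


def infer_observations(hyp: Hypnogram, obsmap: StateConditionedObsMap):
    """Translate a hypnogram into pseudo-observations and uncertainties.

    Returns ``(y, R)``: at each step, ``y`` holds the state-conditioned
    medians of the mapped variables and ``R`` the corresponding variances
    (std squared) — so the measurement uncertainty changes exactly at the
    hypnogram's state transitions.
    """
    obsmap.validate()
    cols = list(obsmap.mapped)
    med = obsmap.medians[cols].to_numpy()
    var = obsmap.stds[cols].to_numpy() ** 2
    labels = hyp.labels
    return med[labels], var[labels]


def assimilate_hypnogram(hyp: Hypnogram, obsmap: StateConditionedObsMap,
                         model: SleepModel, Q: np.ndarray,
                         x0: np.ndarray | None = None,
                         P0: np.ndarray | None = None, dt: float = 0.5,
                         t0: float = 0.0):
    """Reconstruct the full model state from a hypnogram alone.

    Composition of :func:`infer_observations` with the UKF using the
    time-varying state-conditioned uncertainties.  The hypnogram must be on
    the filter grid (coarser hypnograms are step-held onto it); its first
    row is the initial time, so row k >= 1 is the observation at
    ``t0 + k*dt`` and the reconstruction aligns with rows 1 onward.
    """
    if abs(hyp.dt - dt) > 1e-9:
        hyp = hyp.resample(dt)
    y, R = infer_observations(hyp, obsmap)
    y, R = y[1:], R[1:]
    spec = ObservationSpec.from_names(model, list(obsmap.mapped))
    cfg = UKFConfig(model=model, dt=dt, Q=Q, R=R)
    if x0 is None:
        x0 = model.default_state()
    if P0 is None:
        P0 = np.eye(model.n_states)
    return assimilate(y, spec, cfg, x0, P0, t0=t0)


def map_baseline(hyp: Hypnogram, obsmap: StateConditionedObsMap, variables):
    """Reconstruction that simply holds each variable at its state-conditioned
    median — the reference the filter should beat for unobserved variables."""
    med = obsmap.medians[list(variables)].to_numpy()
    return med[hyp.labels]


def estimate_parameter_from_hypnogram(hyp: Hypnogram,
                                      obsmap: StateConditionedObsMap,
                                      model: SleepModel, param: str,
                                      initial_guess: float,
                                      cfg: ShootingConfig | None = None,
                                      Q: np.ndarray | None = None,
                                      dt: float = 0.5,
                                      x0: np.ndarray | None = None,
                                      P0: np.ndarray | None = None
                                      ) -> ParamTrack:
    """Multiple-shooting parameter estimation driven by a hypnogram.

    The pseudo-observations and their time-varying uncertainties replace
    direct measurements; the shooting cost is restricted to the mapped
    variables.  Because state-conditioned medians carry no within-state
    detail, the default shooting segments are longer (5 min) than for
    direct observations: the parameter is identified mostly through
    state-transition timing, which short shots rarely contain.
    """
    if cfg is None:
        cfg = ShootingConfig(segment_length=300.0)
    if abs(hyp.dt - dt) > 1e-9:
        hyp = hyp.resample(dt)
    y, R = infer_observations(hyp, obsmap)
    spec = ObservationSpec.from_names(model, list(obsmap.mapped))
    ukf_cfg = UKFConfig(model=model, dt=dt, Q=Q)
    return estimate_parameter(y[1:], spec, model, param, initial_guess,
                              cfg=cfg, ukf_cfg=ukf_cfg, x0=x0, P0=P0, R=R[1:])
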