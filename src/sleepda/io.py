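"""File formats, experiment configuration and fixture generation.

Trajectories and reconstructions travel as plain CSV with a header row of
canonical variable names and time in seconds; hypnograms as two-column CSV
``(t_seconds, sov)`` with 0=Wake, 1=NREM, 2=REM; parameter sets and
observation maps as YAML.  Values are written with 17 significant digits so
a write/read round trip is lossless.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .hypnogram import Hypnogram
from .models import SleepModel, score_sov
from .params import ModelParams, default_params
from .ukf import UKFConfig, default_q, observe, typical_variances, assimilate, ObservationSpec
from .observability import nmse

log = logging.getLogger("sleepda")

__all__ = ["write_trajectory", "read_trajectory", "write_hypnogram",
           "read_hypnogram", "ExperimentConfig", "run_experiment",
           "make_fixture"]

_FLOAT_FMT = "%.17g"


def write_trajectory(traj: pd.DataFrame, path) -> None:
    """Write a trajectory table to CSV at full double precision."""
    traj.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trajectory(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trajectory file not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    if "t" not in df.columns:
        raise ValueError(f"{path} is not a trajectory file (no 't' column)")
    return df


def write_hypnogram(hyp: Hypnogram, path) -> None:
    pd.DataFrame({"t_seconds": hyp.t, "sov": hyp.labels}).to_csv(
        path, index=False, float_format=_FLOAT_FMT)


def read_hypnogram(path) -> Hypnogram:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"hypnogram file not found: {path}")
    df = pd.read_csv(path)
    if not {"t_seconds", "sov"} <= set(df.columns):
        raise ValueError(f"{path} is not a hypnogram file")
    return Hypnogram(df["t_seconds"].to_numpy(), df["sov"].to_numpy())


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce an identical-twin experiment."""

    variant: str = "db"
    duration: float = 4 * 3600.0
    dt: float = 0.5
    seed: int = 0
    observe: tuple = ("F_LC",)
    noise_frac: float = 0.04
    q_multiplier: float = 1e-4
    transient: float = 3600.0
    params: dict = field(default_factory=dict)
    outdir: str = "experiment_out"

    def to_dict(self) -> dict:
        d = dict(variant=self.variant, duration=self.duration, dt=self.dt,
                 seed=self.seed, observe=list(self.observe),
                 noise_frac=self.noise_frac, q_multiplier=self.q_multiplier,
                 transient=self.transient, params=self.params,
                 outdir=self.outdir)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}; "
                             f"expected a subset of {sorted(known)}")
        d = dict(d)
        if "observe" in d:
            d["observe"] = tuple(d["observe"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Simulate -> observe -> assimilate -> score, writing an artifact bundle.

    Writes truth and reconstruction CSVs, a hypnogram, per-variable NMSE,
    and a manifest recording the config hash, seed and completed stages.
    Returns the manifest dict.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = dict(config=cfg.to_dict(), config_hash=cfg.config_hash(),
                    stages={})
    manifest_path = outdir / "manifest.json"

    def checkpoint(stage, ok=True):
        manifest["stages"][stage] = "ok" if ok else "failed"
        manifest_path.write_text(json.dumps(manifest, indent=2))

    try:
        params = (ModelParams.from_dict(cfg.params) if cfg.params
                  else default_params())
        model = SleepModel(params, cfg.variant)
        log.info("simulating %s truth for %.0f s", cfg.variant, cfg.duration)
        truth = model.simulate(cfg.duration, cfg.dt, seed=cfg.seed)
        write_trajectory(truth, outdir / "truth.csv")
        hyp = Hypnogram.from_trajectory(truth, model.params)
        write_hypnogram(hyp, outdir / "hypnogram.csv")
        checkpoint("simulate")

        y, spec = observe(truth, list(cfg.observe), cfg.noise_frac,
                          seed=cfg.seed + 1, model=model)
        checkpoint("observe")

        var = typical_variances(model)
        ucfg = UKFConfig(model=model, dt=cfg.dt,
                         Q=default_q(model, var, cfg.q_multiplier),
                         R=spec.noise_variances)
        log.info("assimilating %d observations of %s", y.shape[0] - 1,
                 ",".join(cfg.observe))
        xs, Ps, _ = assimilate(y[1:], spec, ucfg, model.default_state(),
                               np.diag(var))
        recon = pd.DataFrame(xs, columns=list(model.state_names))
        recon.insert(0, "t", truth["t"].to_numpy()[1:])
        for i, nm in enumerate(model.state_names):
            recon[f"var_{nm}"] = Ps[:, i]
        write_trajectory(recon, outdir / "reconstruction.csv")
        checkpoint("assimilate")

        skip = int(round(cfg.transient / cfg.dt))
        truth_arr = truth.iloc[1:, 1:len(model.state_names) + 1].to_numpy()
        metrics = {}
        for i, nm in enumerate(model.state_names):
            tv = truth_arr[skip:, i]
            if tv.var() > 0:
                metrics[nm] = nmse(xs[skip:, i], tv)
        manifest["nmse"] = metrics
        (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2))
        checkpoint("metrics")
    except Exception:
        checkpoint("error", ok=False)
        raise
    return manifest


def make_fixture(kind: str = "small", seed: int = 0, outdir=None,
                 variant: str = "db"):
    """Generate seeded test fixtures.

    ``small``: a 10-minute trajectory plus hypnogram for unit tests;
    ``standard``: a 12-hour set for observability runs.  Regeneration under
    the same seed is idempotent.  Returns (trajectory, hypnogram); when
    ``outdir`` is given the pair is also written as CSV.
    """
    if kind == "small":
        duration = 600.0
    elif kind == "standard":
        duration = 12 * 3600.0
    else:
        raise ValueError("kind must be 'small' or 'standard'")
    model = SleepModel(variant=variant)
    traj = model.simulate(duration, 0.5, seed=seed)
    hyp = Hypnogram.from_trajectory(traj, model.params)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_trajectory(traj, outdir / f"trajectory_{kind}.csv")
        write_hypnogram(hyp, outdir / f"hypnogram_{kind}.csv")
    return traj, hyp
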