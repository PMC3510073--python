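"""Model parameters for the sleep-wake regulatory network models.

The network couples five neuronal populations — the wake-active locus
coeruleus (LC, releasing norepinephrine) and dorsal raphe (DR, serotonin),
the NREM-active ventrolateral preoptic nucleus (VLPO, GABA), and two
cholinergic LDT/PPT populations, one REM-active (R) and one active in both
wake and REM (WR) — with a homeostatic sleep drive ``h`` and a stochastic
thalamic input ``delta``.  The circadian variant adds a suprachiasmatic
nucleus (SCN) population with its GABAergic output.

Every parameter lives in a small dataclass mirroring a biological concept
(cell group, coupling weights, homeostatic drive, thalamic noise, SCN) and
can be addressed by a flat canonical name (e.g. ``g_ACh_LC``) for parameter
estimation, or round-tripped through YAML for provenance.

The default values shipped here are a tuned set that reproduces the
qualitative behaviour of the published rat sleep-wake models: ultradian
Wake/NREM/REM cycling on a 5-10 minute timescale, homeostatic wake pressure,
REM episodes emerging late in sleep bouts and terminating in brief
cholinergic arousals, and — in the circadian variant — sleep-dominated light
phases and wake-dominated dark phases.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "CellGroupParams",
    "CouplingWeights",
    "HomeostaticParams",
    "ThalamicNoiseParams",
    "SCNParams",
    "ModelParams",
    "default_params",
    "THETA_NAMES",
    "DB_STATE_NAMES",
    "FBFD_STATE_NAMES",
]

#: canonical state-variable ordering for the core (DB) model
DB_STATE_NAMES = (
    "F_LC", "F_DR", "F_VLPO", "F_R", "F_WR",
    "C_N", "C_S", "C_G", "C_AR", "C_AWR",
    "h", "delta",
)

#: the circadian (FBFD) model appends the SCN firing rate and its GABA output
FBFD_STATE_NAMES = DB_STATE_NAMES + ("F_SCN", "C_SCN")

GROUP_NAMES = ("LC", "DR", "VLPO", "R", "WR", "SCN")

#: transmitter released by each group (ACh is released by both R and WR)
TRANSMITTER_OF = {
    "LC": "NE", "DR": "5HT", "VLPO": "GABA",
    "R": "ACh_R", "WR": "ACh_WR", "SCN": "GABA_SCN",
}


@dataclass
class CellGroupParams:
    """Sigmoid and relaxation constants for one neuronal population.

    ``F_max`` is the maximum firing rate (Hz); ``alpha`` and ``beta`` are the
    slope and midpoint of the steady-state firing sigmoid (input-concentration
    units); ``tau_F`` and ``tau_C`` (s) are the firing-rate and transmitter
    relaxation times; ``gamma`` scales the saturating release curve.  For the
    VLPO the midpoint is not a constant: it is ``-h_gain * h``, so a rising
    homeostatic drive lowers the VLPO firing threshold and promotes sleep.
    ``h_gain`` is zero for every other group.
    """

    name: str
    F_max: float
    alpha: float
    beta: float
    tau_F: float
    tau_C: float
    gamma: float
    h_gain: float = 0.0

    def validate(self) -> None:
        if self.name not in GROUP_NAMES:
            raise ValueError(f"unknown cell group {self.name!r}")
        for attr in ("F_max", "tau_F", "tau_C", "gamma"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{self.name}.{attr} must be > 0")
        if self.alpha == 0:
            raise ValueError(f"{self.name}.alpha must be nonzero")
        if self.name == "VLPO" and self.h_gain <= 0:
            raise ValueError("VLPO.h_gain must be > 0 (h lowers the threshold)")
        if self.name != "VLPO" and self.h_gain != 0:
            raise ValueError(f"{self.name}.h_gain must be 0 (only VLPO is h-dependent)")


@dataclass
class CouplingWeights:
    """Signed synaptic weights of each transmitter onto each target group.

    Stored as magnitudes; the sign convention (GABA, NE and 5-HT inhibitory,
    ACh excitatory) is fixed by the circuit and applied inside the derivative,
    so all entries here are non-negative.  ACh acts through the *summed*
    concentration released by the R and WR groups.
    """

    g_ACh_LC: float
    g_GABA_LC: float
    g_ACh_DR: float
    g_GABA_DR: float
    g_NE_VLPO: float
    g_5HT_VLPO: float
    g_ACh_R: float
    g_NE_R: float
    g_5HT_R: float
    g_GABA_R: float
    g_ACh_WR: float
    g_GABA_WR: float

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"coupling {f.name} must be >= 0 (sign fixed by circuit)")


@dataclass
class HomeostaticParams:
    """Homeostatic sleep drive: accumulates during wake, dissipates in sleep.

    ``theta`` (Hz) is the wake-activity threshold on the LC firing rate that
    switches accumulation (toward ``h_max`` with time constant ``tau_acc``)
    to dissipation (toward 0 with ``tau_diss``).
    """

    h_max: float = 1.0
    theta: float = 3.0
    tau_acc: float = 400.0
    tau_diss: float = 300.0

    def validate(self) -> None:
        if self.h_max <= 0 or self.tau_acc <= 0 or self.tau_diss <= 0:
            raise ValueError("h_max, tau_acc, tau_diss must be > 0")


@dataclass
class ThalamicNoiseParams:
    """Poisson impulse input from thalamocortical circuits onto LC and DR.

    Impulses arrive at ``rate`` Hz, each adding ``impulse_amplitude`` to the
    leaky-integrated concentration ``delta`` which decays with ``tau_delta``.
    """

    rate: float = 0.003
    tau_delta: float = 10.0
    impulse_amplitude: float = 1.0

    def validate(self) -> None:
        if self.rate < 0:
            raise ValueError("noise rate must be >= 0")
        if self.tau_delta <= 0:
            raise ValueError("tau_delta must be > 0")


@dataclass
class SCNParams:
    """Circadian drive and SCN coupling for the extended (FBFD) model.

    ``CIRC(t) = circ_offset + circ_amplitude * sin(2*pi*(t - phase_shift)/circ_period)``
    peaks mid-light; ``phase_shift`` places light onset at 06:00 for the
    default 24 h period.  The SCN receives 5-HT and total-ACh feedback from
    the sleep-wake network (``feedback_weights``) and projects GABAergic
    inhibition forward onto LC, DR, VLPO and R (``g_scn``).
    """

    circ_period: float = 86400.0
    circ_amplitude: float = 0.8
    circ_offset: float = 0.5
    phase_shift: float = 21600.0
    light_fraction: float = 0.5
    feedback_weights: dict = field(default_factory=lambda: {"5HT": 0.2, "ACh": 0.2})
    g_scn: dict = field(
        default_factory=lambda: {"LC": 1.2, "DR": 1.0, "VLPO": 0.02, "R": 1.0}
    )

    def validate(self) -> None:
        if self.circ_period <= 0:
            raise ValueError("circ_period must be > 0")
        if set(self.g_scn) != {"LC", "DR", "VLPO", "R"}:
            raise ValueError("SCN feed-forward targets must be exactly {LC, DR, VLPO, R}")
        if set(self.feedback_weights) != {"5HT", "ACh"}:
            raise ValueError("SCN feedback inputs must be exactly {5HT, ACh}")


# flat parameter vector layout used by the compiled kernels; order matters
_GROUP_FIELDS = ("F_max", "alpha", "beta", "tau_F", "tau_C", "gamma", "h_gain")

THETA_NAMES: tuple[str, ...] = tuple(
    [f"{fld}_{g}" for g in GROUP_NAMES for fld in _GROUP_FIELDS]
    + [f.name for f in dataclasses.fields(CouplingWeights)]
    + ["h_max", "theta_W", "tau_acc", "tau_diss"]
    + ["noise_rate", "tau_delta", "impulse_amplitude"]
    + ["circ_period", "circ_amplitude", "circ_offset", "circ_phase"]
    + ["g_5HT_SCN", "g_ACh_SCN"]
    + ["g_SCN_LC", "g_SCN_DR", "g_SCN_VLPO", "g_SCN_R"]
    + ["scn_drive"]
)

_THETA_INDEX = {name: i for i, name in enumerate(THETA_NAMES)}


@dataclass
class ModelParams:
    """Complete parameter set for the core and circadian sleep-wake models."""

    groups: dict = field(default_factory=dict)
    coupling: CouplingWeights = None
    homeostatic: HomeostaticParams = field(default_factory=HomeostaticParams)
    noise: ThalamicNoiseParams = field(default_factory=ThalamicNoiseParams)
    scn: SCNParams = field(default_factory=SCNParams)
    #: quasi-static stand-in for the SCN feed-forward drive, added to the
    #: transmitter input sums of LC, DR, VLPO and R in the core model; used
    #: as the tracked parameter when a circadian-free filter assimilates
    #: circadian data.  Default 0 (no drive).
    scn_drive: float = 0.0

    def validate(self) -> None:
        if set(self.groups) != set(GROUP_NAMES):
            raise ValueError(f"groups must be exactly {set(GROUP_NAMES)}")
        for g in self.groups.values():
            g.validate()
        n_hdep = sum(1 for g in self.groups.values() if g.h_gain != 0)
        if n_hdep != 1:
            raise ValueError("exactly one group (VLPO) must have an h-dependent midpoint")
        self.coupling.validate()
        self.homeostatic.validate()
        self.noise.validate()
        self.scn.validate()

    # -- flat-name access (used by parameter estimation and config overrides) --

    def get(self, name: str) -> float:
        return float(self.to_vector()[_THETA_INDEX[name]])

    def set(self, name: str, value: float) -> None:
        v = self.to_vector()
        v[_THETA_INDEX[name]] = value
        new = ModelParams.from_vector(v)
        self.groups = new.groups
        self.coupling = new.coupling
        self.homeostatic = new.homeostatic
        self.noise = new.noise
        self.scn = new.scn
        self.scn_drive = new.scn_drive

    def replace(self, name: str, value: float) -> "ModelParams":
        """Return a copy with one flat-named parameter replaced."""
        v = self.to_vector()
        v[_THETA_INDEX[name]] = value
        return ModelParams.from_vector(v)

    def copy(self) -> "ModelParams":
        return ModelParams.from_vector(self.to_vector())

    # -- packed vector used by the numba kernels --

    def to_vector(self) -> np.ndarray:
        v = np.empty(len(THETA_NAMES))
        i = 0
        for gname in GROUP_NAMES:
            g = self.groups[gname]
            for fld in _GROUP_FIELDS:
                v[i] = getattr(g, fld)
                i += 1
        for f in dataclasses.fields(CouplingWeights):
            v[i] = getattr(self.coupling, f.name)
            i += 1
        h = self.homeostatic
        v[i:i + 4] = (h.h_max, h.theta, h.tau_acc, h.tau_diss)
        i += 4
        nz = self.noise
        v[i:i + 3] = (nz.rate, nz.tau_delta, nz.impulse_amplitude)
        i += 3
        s = self.scn
        v[i:i + 4] = (s.circ_period, s.circ_amplitude, s.circ_offset, s.phase_shift)
        i += 4
        v[i:i + 2] = (s.feedback_weights["5HT"], s.feedback_weights["ACh"])
        i += 2
        v[i:i + 4] = (s.g_scn["LC"], s.g_scn["DR"], s.g_scn["VLPO"], s.g_scn["R"])
        i += 4
        v[i] = self.scn_drive
        return v

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "ModelParams":
        v = np.asarray(v, dtype=float)
        groups = {}
        i = 0
        for gname in GROUP_NAMES:
            kw = {fld: float(v[i + j]) for j, fld in enumerate(_GROUP_FIELDS)}
            groups[gname] = CellGroupParams(name=gname, **kw)
            i += len(_GROUP_FIELDS)
        cfields = [f.name for f in dataclasses.fields(CouplingWeights)]
        coupling = CouplingWeights(**{n: float(v[i + j]) for j, n in enumerate(cfields)})
        i += len(cfields)
        homeo = HomeostaticParams(h_max=float(v[i]), theta=float(v[i + 1]),
                                  tau_acc=float(v[i + 2]), tau_diss=float(v[i + 3]))
        i += 4
        noise = ThalamicNoiseParams(rate=float(v[i]), tau_delta=float(v[i + 1]),
                                    impulse_amplitude=float(v[i + 2]))
        i += 3
        scn = SCNParams(
            circ_period=float(v[i]), circ_amplitude=float(v[i + 1]),
            circ_offset=float(v[i + 2]), phase_shift=float(v[i + 3]),
            feedback_weights={"5HT": float(v[i + 4]), "ACh": float(v[i + 5])},
            g_scn={"LC": float(v[i + 6]), "DR": float(v[i + 7]),
                   "VLPO": float(v[i + 8]), "R": float(v[i + 9])},
        )
        i += 10
        return cls(groups=groups, coupling=coupling, homeostatic=homeo,
                   noise=noise, scn=scn, scn_drive=float(v[i]))

    # -- YAML round trip --

    def to_dict(self) -> dict:
        d = {
            "groups": {g.name: {fld: getattr(g, fld) for fld in _GROUP_FIELDS}
                       for g in self.groups.values()},
            "coupling": dataclasses.asdict(self.coupling),
            "homeostatic": dataclasses.asdict(self.homeostatic),
            "noise": dataclasses.asdict(self.noise),
            "scn": dataclasses.asdict(self.scn),
            "scn_drive": self.scn_drive,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {"groups", "coupling", "homeostatic", "noise", "scn", "scn_drive"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(
                f"unknown parameter sections {sorted(unknown)}; expected {sorted(known)}"
            )
        p = default_params()
        for gname, gd in d.get("groups", {}).items():
            if gname not in p.groups:
                raise ValueError(f"unknown cell group {gname!r}")
            for k, val in gd.items():
                if k not in _GROUP_FIELDS:
                    raise ValueError(f"unknown field {k!r} for group {gname}")
                setattr(p.groups[gname], k, float(val))
        for k, val in d.get("coupling", {}).items():
            if not hasattr(p.coupling, k):
                raise ValueError(f"unknown coupling {k!r}")
            setattr(p.coupling, k, float(val))
        for section, obj in (("homeostatic", p.homeostatic), ("noise", p.noise)):
            for k, val in d.get(section, {}).items():
                if not hasattr(obj, k):
                    raise ValueError(f"unknown field {k!r} in {section}")
                setattr(obj, k, float(val))
        for k, val in d.get("scn", {}).items():
            if not hasattr(p.scn, k):
                raise ValueError(f"unknown field {k!r} in scn")
            setattr(p.scn, k, val if isinstance(val, dict) else float(val))
        if "scn_drive" in d:
            p.scn_drive = float(d["scn_drive"])
        p.validate()
        return p

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_params() -> ModelParams:
    """The package's versioned default parameter set (see module docstring)."""
    groups = {
        "LC": CellGroupParams("LC", F_max=6.5, alpha=0.25, beta=-0.1,
                              tau_F=20.0, tau_C=60.0, gamma=4.0),
        "DR": CellGroupParams("DR", F_max=5.0, alpha=0.25, beta=-0.1,
                              tau_F=20.0, tau_C=60.0, gamma=3.5),
        "VLPO": CellGroupParams("VLPO", F_max=5.0, alpha=0.30, beta=0.0,
                                tau_F=15.0, tau_C=10.0, gamma=3.0, h_gain=2.0),
        "R": CellGroupParams("R", F_max=5.0, alpha=0.8, beta=-1.1,
                             tau_F=10.0, tau_C=10.0, gamma=2.0),
        "WR": CellGroupParams("WR", F_max=5.0, alpha=0.5, beta=-0.3,
                              tau_F=10.0, tau_C=10.0, gamma=5.0),
        "SCN": CellGroupParams("SCN", F_max=8.0, alpha=0.5, beta=1.0,
                               tau_F=30.0, tau_C=60.0, gamma=4.0),
    }
    coupling = CouplingWeights(
        g_ACh_LC=1.25, g_GABA_LC=2.5,
        g_ACh_DR=1.0, g_GABA_DR=2.5,
        g_NE_VLPO=1.0, g_5HT_VLPO=1.0,
        g_ACh_R=0.2, g_NE_R=3.0, g_5HT_R=3.0, g_GABA_R=0.3,
        g_ACh_WR=1.5, g_GABA_WR=2.0,
    )
    p = ModelParams(groups=groups, coupling=coupling)
    p.validate()
    return p
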