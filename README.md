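# sleepda — data assimilation for sleep-wake network models

`sleepda` reconstructs the hidden state of mammalian sleep-wake regulatory
network models from sparse, noisy observations, ranks which variables are
worth measuring, and estimates unknown or slowly drifting parameters.  It is
aimed at computational sleep researchers running identical-twin experiments:
the same model generates a synthetic "truth", a noisy subset of its
variables (or only the scored Wake/NREM/REM hypnogram) is observed, and the
filter's reconstruction is validated against the known truth.

## The models and the method

Two firing-rate network models are built in:

* **Core (DB) model** — 12 state variables: firing rates of the wake-active
  LC and DR, the NREM-active VLPO, and the REM-active (R) and wake/REM-active
  (WR) LDT/PPT populations; the five transmitter concentrations they release
  (NE, 5-HT, GABA, and ACh separately from R and WR, with targets seeing the
  *summed* ACh); a homeostatic sleep drive `h`; and a Poisson-driven
  thalamic input `delta`.  Each rate relaxes toward
  `F_inf(c) = (F_max/2)(1 + tanh((c - beta)/alpha))` of its weighted
  transmitter input sum `c`; each concentration toward `tanh(F/gamma)`.
  The VLPO midpoint is `-k h`, so accumulated sleep pressure lowers the
  sleep-onset threshold.
* **Circadian (FBFD) model** — adds an SCN population driven by a 24-h
  `CIRC(t)` input (light phase 06:00–18:00) with 5-HT/ACh feedback, whose
  GABAergic output feeds forward onto LC, DR, VLPO and R, producing
  sleep-dominated light phases and wake-dominated dark phases.

Integration is classical RK4 at 0.5 s with impulses applied between steps.

State estimation uses an **unscented Kalman filter** with the symmetric
2n-point sigma set (spread `sqrt(n P)`, equal weights) and a diagonal
covariance-inflation matrix `Q`.  Reconstruction fidelity is scored by the
normalized mean square error `NMSE_i = <(x̂_i - x_i)^2> / var(x_i)` and the
**Empirical Observability Coefficient** `EOC = 1/(1 + NMSE) ∈ (0, 1]`,
assembled into a matrix (rows = reconstructed, columns = measured variable)
that ranks observables and guides tuning of `Q`.  Parameters are estimated
by **multiple shooting**: short model trajectories re-anchored on the UKF
reconstruction are compared to it over windows longer than a sleep-wake
cycle, and the candidate value minimizing the weighted divergence on the
measured variables is accepted with a capped step; overlapping windows turn
the same machinery into a tracker for slowly varying parameters.  A
discretized hypnogram can stand in for raw measurements via state-
conditioned medians and standard deviations used as pseudo-observations
with time-varying uncertainty.

## Worked example

Reconstruct the full 12-variable state from a noisy measurement of the
LC firing rate alone:

```python
import numpy as np
import sleepda as sd

model = sd.SleepModel(variant="db")
truth = model.simulate(4 * 3600, dt=0.5, seed=42)          # identical twin
y, spec = sd.observe(truth, "F_LC", noise_frac=0.04, seed=43, model=model)

var = sd.typical_variances(model)
cfg = sd.UKFConfig(model=model, dt=0.5, Q=sd.default_q(model, var),
                   R=spec.noise_variances)
xs, Ps, _ = sd.assimilate(y[1:], spec, cfg, model.default_state(), np.diag(var))

X = truth.iloc[1:, 1:].to_numpy()
skip = 7200                                                 # 1 h transient
for name in ("F_LC", "F_VLPO", "F_R", "h"):
    i = list(model.state_names).index(name)
    print(f"NMSE {name:7s} {sd.nmse(xs[skip:, i], X[skip:, i]):.4f}")
```

prints

```
NMSE F_LC    0.0032
NMSE F_VLPO  0.0129
NMSE F_R     0.0303
NMSE h       0.0098
```

The observed variable is reconstructed an order of magnitude below the 4%
measurement-noise floor, and the *unmeasured* NREM-active rate, REM-active
rate and homeostatic drive are all recovered with errors of 1–3% of their
natural variance.

The same workflows are available from the shell:

```bash
sleepda simulate --variant fbfd --duration 172800 --seed 1 --out truth.csv
sleepda assimilate --traj truth.csv --observe F_LC,F_R --out recon.csv
sleepda eoc --variant db --no-delta --duration-h 12 --out eoc.csv
sleepda fit-param --param g_ACh_LC --init 0.9 --traj truth.csv --out track.csv
```

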