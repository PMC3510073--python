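# Methods

This note records the models, numerical choices and design decisions behind
`sleepda`, and what the identical-twin experiments in the test suite do and
do not demonstrate.

## Sleep-wake network models

The core model couples five neuronal populations through released
neurotransmitter concentrations.  Each firing rate obeys
`dF/dt = (F_inf(c) - F)/tau_F` with
`F_inf(c) = (F_max/2)(1 + tanh((c - beta)/alpha))`, and each concentration
`dC/dt = (tanh(F/gamma) - C)/tau_C` (normalized so saturation is 1).  The
input sums are

```
c_LC   =  g_ACh_LC * C_A  - g_GABA_LC * C_G  + delta
c_DR   =  g_ACh_DR * C_A  - g_GABA_DR * C_G  + delta
c_VLPO = -g_NE_VLPO * C_N - g_5HT_VLPO * C_S
c_R    =  g_ACh_R * C_A   - g_NE_R * C_N - g_5HT_R * C_S - g_GABA_R * C_G
c_WR   =  g_ACh_WR * C_A  - g_GABA_WR * C_G
```

with `C_A = C_AR + C_AWR` the summed cholinergic output of the R and WR
populations.  GABA and the monoamines are inhibitory, ACh excitatory; the
couplings are stored as magnitudes and the signs fixed by the circuit.  The
VLPO midpoint is `beta_VLPO = -h_gain * h`: the homeostatic drive `h`
accumulates toward `h_max` with time constant `tau_acc` while `F_LC`
exceeds `theta` and dissipates with `tau_diss` otherwise.  Thalamic input
`delta` integrates Poisson impulses (rate 0.003 Hz, unit amplitude — only
the products of coupling and amplitude matter downstream) with a 10 s leak.

The circadian variant adds an SCN population driven by
`CIRC(t) = offset + amplitude * sin(2*pi*(t - 6 h)/24 h)` (light phase
06:00–18:00; the mean over a period equals the offset) plus 5-HT and
total-ACh feedback, and its GABAergic output is subtracted, with per-target
weights, from the LC, DR, VLPO and R input sums.  `t = 0` is midnight;
wall-clock phase is derived, never stored.

### Default parameter set

No single published table covers every constant of this model family in the
form used here, so the package ships its own versioned default set
(`params.default_params`, exportable to YAML).  The defaults were chosen —
once, before the acceptance suite was frozen — to reproduce the documented
phenomenology of the rat models this architecture comes from:

* ultradian Wake/NREM/REM cycling with a 10–15 min cycle: consolidated wake
  bouts of a few minutes, NREM bouts of 1–2 min, and a single REM bout late
  in each sleep episode terminated by a cholinergic arousal that ignites the
  wake-active populations;
* state fractions near W 45% / N 28% / R 27% for the core model;
* dark-phase wake fraction well above the light-phase fraction in the
  circadian variant (W 49% dark vs 14% light at the defaults);
* the observability structure reported for these models: the REM-active
  rate and its ACh output are among the best observables, the stochastic
  `delta` is the worst, and the observability matrix's diagonal entries are
  the maxima of their rows.

Two default choices deserve comment.  The REM-active sigmoid is deliberately
shallow (`alpha_R = 0.8`, midpoint −1.1): with a steep sigmoid the REM-active
rate is pinned at zero outside REM and carries no phase information, which
destroys exactly the observability structure listed above.  Graded
subthreshold firing is also the physiologically sensible choice.  Similarly
the monoamine release curves (`gamma` 4.0 / 3.5) and the WR release curve
(`gamma = 5`) operate off saturation so concentrations track rates.

## Unscented Kalman filter

Sigma points are the symmetric 2n-point set `x ± columns of chol(n P)` with
equal weights `1/(2n)`; their weighted mean and covariance reproduce the
estimate exactly, and no central point or extra scaling parameters are used.
Each point is propagated one filter step (RK4, 0.5 s by default — filter
step equals the data step) through the *deterministic* model: the impulse
generator is excluded, `delta` decays freely inside the filter and its
uncertainty is carried entirely by its inflation entry.  The forecast
covariance is the propagated-point covariance plus the diagonal inflation
`Q`; the gain is `K = P_xy (P_yy + R)^-1` with the cross- and
observed-space covariances formed from the same propagated points, and the
covariance update is `P - K (P_yy + R) K^T`, symmetrized every iteration.
Cholesky failures are repaired with escalating diagonal jitter
(1e-12 → 1e-6); observations containing non-finite values trigger a
predict-only step.

Because `Q` inflates only the forecast covariance (the gain uses the
propagated points), the filter coincides with the exact Kalman filter on
linear-Gaussian systems when `Q = 0`; with `Q ≠ 0` the forecast covariance
matches `F P F' + Q` exactly while the gain sees the inflation one step
later, through the widened sigma spread.  Both facts are tested.

Defaults: `Q_ii = 1e-4 ×` the typical variance of variable *i* (from a
seeded reference simulation), `P_0 = diag(typical variances)`, observation
noise 4% of each observed variable's variance.

Two engines produce identical output (tested to 1e-8): a generic pure-NumPy
recursion accepting any model with a `step_points(X, t, dt)` method, and a
numba-compiled loop for the sleep models that makes 12-hour assimilations a
few-second operation.

## Observability and inflation tuning

`NMSE_i = mean((x̂_i - x_i)^2)/var(x_i)`; `EOC = 1/(1 + NMSE)`.  The
regularized form is chosen for its bounds ((0, 1], 1 iff perfect) and
monotonicity; it is recorded in the matrix metadata.  The EOC matrix is
computed from data generated by the filter model itself (observability is a
model property), 12 h per column with the first hour discarded, 4% noise;
the no-noise variant (`include_delta=False`) switches the impulse process
off and drops `delta` from rows and columns.  Column failures are flagged
in metadata, never silently dropped.

Inflation tuning iterates: compute the matrix; find the variable with the
lowest *off-diagonal* mean row or column (the diagonal would mask poor
columns); a poor column means measuring that variable teaches the filter
little, so its `Q` entry is swept *upward* (log grid, 7 points per decade,
capped at the squared range of the variable); a poor row means the variable
is poorly reconstructed from anything, so its entry is swept *downward*
(including exactly 0).  The swept value maximizing the mean EOC of the
target observation column is accepted if that mean does not decrease.  At
the defaults the first selection is `delta` / increase, and raising
`Q_delta,delta` from 1.6e-6 to ~1e-3 roughly halves the REM-active rate's
reconstruction error from an LC-only measurement.

## Multiple-shooting parameter estimation

Within each window (default 1800 s, 80% overlap ⇒ 360 s updates) the model
with a candidate parameter value is re-launched from the reconstruction
every 120 s and integrated for 120 s; the cost is the average squared
divergence from the reconstruction over all shot samples, restricted to the
measured variables and weighted by the reciprocal of each measured
variable's standard deviation over the window's reconstruction.  Candidates
come from an 11-point grid spanning ±30% of the current estimate (with an
absolute floor of ±0.05 so near-zero estimates keep a usable grid, and
optional hard bounds); the accepted move is capped at 10% of the estimate
(absolute floor 0.02); the grid is refined ×0.5 when the minimizer is
interior on consecutive windows.  Infeasible candidates (integration
failure or a parameter-invariant violation) receive infinite cost.

**Stabilization.**  The estimate counts as stabilized when the relative
dispersion (std/|mean|) of the last 8 window estimates falls below 2%; the
reported point estimate is the mean over that plateau.  A per-step change
criterion cannot work here: each window moves the estimate by at least one
grid step, which typically exceeds any sensible tolerance.

**Resolution and identifiability.**  The window-to-window scatter of the
cost minimizer (~2–3% for the ACh→LC coupling at the defaults) — not the
refined grid — limits the final accuracy; recovery to within the coarse
grid's 6% resolution is what the tests assert.  The identifiability basin
of that coupling is narrower than ±50% and asymmetric: some noise
realizations started 30–50% away slide into a spurious low- or
high-coupling regime, because the reconstruction built with a wrong
parameter partially confirms it.  Windows spanning several sleep-wake
cycles (≥1 h for this model) widen the basin noticeably.  The estimator
never hides this: runs that do not stabilize return `converged=False`
rather than a guessed value.

**Tracking.**  For slowly varying parameters the same loop runs over all
windows without a stopping rule, one estimate per window center, inherently
smoothed at the window scale.  For the circadian-drive experiment — the
additive stand-in `scn_drive` injected into the LC/DR/VLPO/R input sums of
the circadian-free core model — the grid uses an absolute half-width of 0.3
and a step cap of 0.15 with bounds [−2, 1]: the drive crosses zero (relative
spans degenerate) and beyond −2 it saturates the dynamics, making stronger
values unidentifiable (the cost flattens).  Tracking 48 h of circadian
truth through F_LC/F_R observations recovers a drive oscillating between
≈0 (dark) and ≈−1.2 (light) with a dominant periodogram period of 23–25 h
across seeds (rectangular window, linear detrend, 16× zero padding — the
estimator was validated on synthetic partial-cycle records first, where a
Hann window biases the period high on 1.5-cycle records).

## Hypnogram assimilation

State-conditioned medians and standard deviations of the mapped variables
(default `F_LC`, `F_VLPO`, `F_R`; the map can cover all variables, which
provides the baseline below) are estimated from a seeded 12-h model run
with a 1-h transient discarded, with variances floored at
`1e-6 × range²` against degenerate conditional distributions.  Scoring uses
REM precedence (REM if `F_R > 0.3 F_max_R`, else Wake if
`F_LC > 0.5 F_max_LC`, else NREM); truth and reconstruction are always
scored with the same rule.  A hypnogram then maps to pseudo-observations
(the per-state medians) with time-varying `R` (the per-state variances),
and the standard filter runs.  Reconstruction of the *unobserved*
homeostatic drive and GABA concentration beats the median-map baseline
(holding every variable at its state-conditioned median) across seeds;
brief awakenings and fast transition details are not recovered — the
hypnogram simply does not contain them.

Hypnogram-driven parameter estimation uses 5-min shooting segments instead
of 2 min: with median-valued pseudo-observations the short-shot cost is
dominated by a preference for maximally rigid dynamics (the medians carry
no within-state detail) and the estimate can run away; longer shots restore
identifiability through state-transition timing, after which a coupling
started 30% off is recovered to within a few percent.

## What the identical-twin experiments do not show

All tests run the generating model as the filter model (exact structure,
and — except where a parameter is being estimated — exact parameters).
They validate the assimilation machinery, not the biological fidelity of
the models: real recordings bring structural model error, non-Gaussian and
correlated measurement noise, and observation functions far from a clean
variable subset.  The hypnogram experiments take one step in that
direction, and the circadian-drive tracking shows the filter absorbing a
*known* form of structural error (a missing oscillator) into a quasi-static
parameter; neither substitutes for validation against animal data.

## Problem sizes

Default experiment sizes were picked so each question is answered at the
smallest informative scale: 4 h of truth for reconstruction experiments
(≈20 sleep-wake cycles; 1 h transient discarded), 12 h per EOC column,
6 h for inflation tuning and parameter recovery, 48 h for circadian
tracking (12 h transient discarded, leaving 1.5 circadian cycles), and
1e6 s for impulse-rate statistics (~3000 expected impulses).
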