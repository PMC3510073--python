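"""Reconstruction fidelity, empirical observability, and Q optimization.

Reconstruction quality is scored by the normalized mean square error
(NMSE): the mean squared difference between reconstruction and truth,
divided by the variance of the truth series.  The Empirical Observability
Coefficient ``EOC = 1/(1 + NMSE)`` maps this onto (0, 1], with 1 for
perfect reconstruction, and is assembled into a matrix whose entry (i, j)
says how well variable i is reconstructed when variable j is measured in
an identical-twin experiment run on the filter model itself.

The EOC matrix doubles as a guide for tuning the covariance-inflation
diagonal Q: a variable whose *column* is poor (measuring it reconstructs
little) should trust measurements more — increase its Q entry; a variable
whose *row* is poor (it is poorly reconstructed from anything) should trust
the model more — decrease its Q entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import SleepModel
from .ukf import (FilterNumericalError, ObservationSpec, UKFConfig,
                  assimilate, default_q)

__all__ = ["nmse", "eoc", "EOCMatrix", "eoc_matrix", "eoc_multi",
           "optimize_q", "QOptimizationResult"]


def nmse(reconstructed: np.ndarray, truth: np.ndarray) -> float:
    """Normalized mean square error; 0 iff the series are identical."""
    r = np.asarray(reconstructed, dtype=float)
    t = np.asarray(truth, dtype=float)
    if r.shape != t.shape or r.ndim != 1:
        raise ValueError("series must be 1-d and of equal length")
    if r.size < 2:
        raise ValueError("series must have length >= 2")
    v = t.var()
    if v <= 0:
        raise ValueError("truth series has zero variance; NMSE undefined")
    return float(np.mean((r - t) ** 2) / v)


def eoc(nmse_value: float) -> float:
    """Empirical Observability Coefficient, ``1/(1 + NMSE)`` in (0, 1]."""
    if nmse_value < 0:
        raise ValueError("NMSE must be >= 0")
    return 1.0 / (1.0 + nmse_value)


@dataclass
class EOCMatrix:
    """EOC table: rows = reconstructed variable, columns = measured variable.

    ``values.loc[i, j]`` is EOC of i given measurement of j.  Columns whose
    assimilation failed numerically are NaN and listed in
    ``metadata['failed_columns']``.
    """

    values: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def variables(self):
        return list(self.values.index)

    def off_diagonal_row_means(self) -> pd.Series:
        v = self.values.to_numpy(copy=True)
        np.fill_diagonal(v, np.nan)
        return pd.Series(np.nanmean(v, axis=1), index=self.values.index)

    def off_diagonal_col_means(self) -> pd.Series:
        v = self.values.to_numpy(copy=True)
        np.fill_diagonal(v, np.nan)
        return pd.Series(np.nanmean(v, axis=0), index=self.values.columns)


def _twin_setup(model: SleepModel, duration, dt, seed, include_delta, transient):
    """Simulate identical-twin truth and derive scoring scaffolding."""
    sim_model = model if include_delta else model.with_param("noise_rate", 0.0)
    truth = sim_model.simulate(duration, dt, seed=seed)
    skip = int(round(transient / dt))
    X = truth.iloc[1:, 1:].to_numpy()      # rows align with observations
    variances = np.maximum(truth.iloc[skip:, 1:].to_numpy().var(axis=0), 1e-12)
    names = list(model.state_names)
    variables = [nm for nm in names
                 if include_delta or nm != "delta"]
    return sim_model, truth, X, variances, names, variables, skip


def _column_eoc(model, X, variances, names, variables, skip, measured,
                noise_frac, Q, dt, seed, col_seed):
    """Assimilate one measured set and return the EOC of every variable."""
    midx = [names.index(nm) for nm in measured]
    rng = np.random.default_rng([seed, col_seed])
    truth_cols = X[:, midx]
    noise_var = noise_frac * truth_cols.var(axis=0)
    y = truth_cols + rng.standard_normal(truth_cols.shape) * np.sqrt(noise_var)
    spec = ObservationSpec(np.array(midx), noise_var, tuple(measured))
    cfg = UKFConfig(model=model, dt=dt, Q=Q, R=noise_var)
    x0 = model.default_state()
    P0 = np.diag(variances)
    xs, _, _ = assimilate(y, spec, cfg, x0, P0)
    out = {}
    for nm in variables:
        i = names.index(nm)
        out[nm] = eoc(nmse(xs[skip:, i], X[skip:, i]))
    return out


def eoc_matrix(model: SleepModel, duration: float = 12 * 3600.0,
               dt: float = 0.5, noise_frac: float = 0.04,
               Q: np.ndarray | None = None, seed: int = 0,
               include_delta: bool = True,
               transient: float = 3600.0) -> EOCMatrix:
    """Identical-twin EOC matrix over all candidate measured variables.

    Truth is generated from the filter model itself (observability is a
    property of the model, so the data must come from the model).  With
    ``include_delta=False`` the thalamic noise process is switched off and
    delta is dropped from both rows and columns.  The first ``transient``
    seconds are excluded from scoring.
    """
    (sim_model, truth, X, variances, names, variables, skip) = _twin_setup(
        model, duration, dt, seed, include_delta, transient)
    filt = sim_model  # identical twin: filter model == generating model
    qdiag = default_q(filt, variances) if Q is None else np.asarray(Q, float)
    cols = {}
    failed = []
    for j, measured in enumerate(variables):
        try:
            cols[measured] = _column_eoc(
                filt, X, variances, names, variables, skip, [measured],
                noise_frac, qdiag, dt, seed, col_seed=j)
        except FilterNumericalError:
            cols[measured] = {nm: np.nan for nm in variables}
            failed.append(measured)
    values = pd.DataFrame(cols).loc[variables, variables]
    meta = dict(duration=duration, dt=dt, noise_frac=noise_frac, seed=seed,
                include_delta=include_delta, transient=transient,
                Q=np.asarray(qdiag).tolist(), failed_columns=failed,
                eoc_form="1/(1+NMSE)")
    return EOCMatrix(values, meta)


def eoc_multi(model: SleepModel, measured_set, duration: float = 12 * 3600.0,
              dt: float = 0.5, noise_frac: float = 0.04,
              Q: np.ndarray | None = None, seed: int = 0,
              include_delta: bool = True,
              transient: float = 3600.0) -> pd.Series:
    """EOC of every variable given joint measurement of ``measured_set``."""
    measured_set = list(measured_set)
    if len(measured_set) < 1:
        raise ValueError("measured_set must contain at least one variable")
    (sim_model, truth, X, variances, names, variables, skip) = _twin_setup(
        model, duration, dt, seed, include_delta, transient)
    qdiag = default_q(sim_model, variances) if Q is None else np.asarray(Q, float)
    # duplicate measurements carry no extra information; collapse them
    seen = []
    for nm in measured_set:
        if nm not in seen:
            seen.append(nm)
    col = _column_eoc(sim_model, X, variances, names, variables, skip, seen,
                      noise_frac, qdiag, dt, seed,
                      col_seed=1000 + len(seen))
    return pd.Series(col, name="|".join(seen))


@dataclass
class QOptimizationResult:
    Q: np.ndarray
    history: pd.DataFrame
    matrices: list


def optimize_q(model: SleepModel, observe="F_LC", Q0: np.ndarray | None = None,
               duration: float = 12 * 3600.0, dt: float = 0.5,
               noise_frac: float = 0.04, seed: int = 0,
               max_iterations: int = 3, tol: float = 1e-3,
               points_per_decade: int = 7, include_delta: bool = True,
               transient: float = 3600.0) -> QOptimizationResult:
    """EOC-guided iterative tuning of the covariance-inflation diagonal.

    Each iteration computes the full EOC matrix, selects the variable with
    the lowest off-diagonal mean row or column, and sweeps its Q entry —
    upward over a log grid to the squared full range of the variable when a
    *column* is worst (trust measurements more), downward toward zero when a
    *row* is worst (trust the model more).  The swept value maximizing the
    mean EOC of the target observation column is accepted if it improves
    that mean; optimization stops on an accepted improvement below ``tol``,
    a rejected sweep, or the iteration cap.
    """
    observe = [observe] if isinstance(observe, str) else list(observe)
    (sim_model, truth, X, variances, names, variables, skip) = _twin_setup(
        model, duration, dt, seed, include_delta, transient)
    ranges = np.ptp(truth.iloc[skip:, 1:].to_numpy(), axis=0)
    qdiag = (default_q(sim_model, variances) if Q0 is None
             else np.asarray(Q0, float).copy())

    def target_mean(qd, col_seed):
        col = _column_eoc(sim_model, X, variances, names, variables, skip,
                          observe, noise_frac, qd, dt, seed, col_seed)
        return np.mean(list(col.values()))

    history = []
    matrices = []
    current_mean = target_mean(qdiag, col_seed=9999)
    for it in range(max_iterations):
        M = eoc_matrix(model, duration, dt, noise_frac, qdiag, seed,
                       include_delta, transient)
        matrices.append(M)
        rm = M.off_diagonal_row_means()
        cm = M.off_diagonal_col_means()
        if np.isclose(M.values.to_numpy().std(), 0.0):
            break  # nothing to rank
        if cm.min() <= rm.min():
            var_sel, direction = cm.idxmin(), "increase"
        else:
            var_sel, direction = rm.idxmin(), "decrease"
        vi = names.index(var_sel)
        q_cur = qdiag[vi]
        q_max = max(ranges[vi] ** 2, q_cur * 10)
        q_lo = max(q_cur * 1e-2, 1e-12)
        if direction == "increase":
            lo, hi = max(q_cur, 1e-12), q_max
        else:
            lo, hi = q_lo * 1e-2, max(q_cur, 1e-12)
        decades = max(np.log10(hi / lo), 0.5)
        npts = int(np.ceil(decades * points_per_decade)) + 1
        grid = np.geomspace(lo, hi, npts)
        if direction == "decrease":
            grid = np.concatenate([[0.0], grid])
        scores = np.empty(grid.size)
        for gi, qv in enumerate(grid):
            qd = qdiag.copy()
            qd[vi] = qv
            scores[gi] = target_mean(qd, col_seed=9999)
        best = int(np.argmax(scores))
        accepted = scores[best] >= current_mean
        history.append(dict(iteration=it, variable=var_sel, direction=direction,
                            q_old=q_cur, q_new=float(grid[best]),
                            mean_eoc_before=current_mean,
                            mean_eoc_after=float(scores[best]),
                            accepted=bool(accepted)))
        if not accepted:
            break
        improvement = scores[best] - current_mean
        qdiag[vi] = grid[best]
        current_mean = float(scores[best])
        if improvement < tol:
            break
    return QOptimizationResult(qdiag, pd.DataFrame(history), matrices)
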