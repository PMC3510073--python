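"""Numba-compiled numerical kernels.

Everything here operates on the packed parameter vector (``params.THETA_NAMES``
order) and raw state arrays so that the hot loops — trajectory integration and
the sigma-point filter recursion — compile to machine code.  The public
modules wrap these kernels with validated, named interfaces.

State layout (columns): F_LC, F_DR, F_VLPO, F_R, F_WR, C_N, C_S, C_G, C_AR,
C_AWR, h, delta [, F_SCN, C_SCN].  Variant codes: 0 = core 12-variable model,
1 = circadian 14-variable model.
"""

import numpy as np
from numba import njit

from .params import THETA_NAMES

_IX = {name: i for i, name in enumerate(THETA_NAMES)}


def _g(name):
    return _IX[name]


# group parameter blocks: 7 fields per group in GROUP_NAMES order
_GF = 7
_LC, _DR, _VLPO, _R, _WR, _SCN = (i * _GF for i in range(6))
_F_MAX, _ALPHA, _BETA, _TAU_F, _TAU_C, _GAMMA, _H_GAIN = range(_GF)

_G_ACH_LC = _g("g_ACh_LC")
_G_GABA_LC = _g("g_GABA_LC")
_G_ACH_DR = _g("g_ACh_DR")
_G_GABA_DR = _g("g_GABA_DR")
_G_NE_V = _g("g_NE_VLPO")
_G_5HT_V = _g("g_5HT_VLPO")
_G_ACH_R = _g("g_ACh_R")
_G_NE_R = _g("g_NE_R")
_G_5HT_R = _g("g_5HT_R")
_G_GABA_R = _g("g_GABA_R")
_G_ACH_WR = _g("g_ACh_WR")
_G_GABA_WR = _g("g_GABA_WR")

_H_MAX = _g("h_max")
_THETA_W = _g("theta_W")
_TAU_ACC = _g("tau_acc")
_TAU_DISS = _g("tau_diss")

_RATE = _g("noise_rate")
_TAU_DELTA = _g("tau_delta")
_AMP = _g("impulse_amplitude")

_CIRC_PERIOD = _g("circ_period")
_CIRC_AMPL = _g("circ_amplitude")
_CIRC_OFFSET = _g("circ_offset")
_CIRC_PHASE = _g("circ_phase")
_G_5HT_SCN = _g("g_5HT_SCN")
_G_ACH_SCN = _g("g_ACh_SCN")
_G_SCN_LC = _g("g_SCN_LC")
_G_SCN_DR = _g("g_SCN_DR")
_G_SCN_V = _g("g_SCN_VLPO")
_G_SCN_R = _g("g_SCN_R")
_SCN_DRIVE = _g("scn_drive")


@njit(cache=True)
def _finf(c, fmax, alpha, beta):
    return 0.5 * fmax * (1.0 + np.tanh((c - beta) / alpha))


@njit(cache=True)
def _circ(t, th):
    return th[_CIRC_OFFSET] + th[_CIRC_AMPL] * np.sin(
        2.0 * np.pi * (t - th[_CIRC_PHASE]) / th[_CIRC_PERIOD]
    )


@njit(cache=True)
def _rhs_mat(X, t, th, variant, out):
    """Deterministic derivative for a batch of states (columns of X)."""
    m = X.shape[1]
    for j in range(m):
        F_LC = X[0, j]
        F_DR = X[1, j]
        F_V = X[2, j]
        F_R = X[3, j]
        F_WR = X[4, j]
        C_N = X[5, j]
        C_S = X[6, j]
        C_G = X[7, j]
        C_AR = X[8, j]
        C_AWR = X[9, j]
        h = X[10, j]
        delta = X[11, j]
        C_A = C_AR + C_AWR

        if variant == 1:
            C_GSCN = X[13, j]
        else:
            C_GSCN = 0.0
        drive = th[_SCN_DRIVE]

        c_LC = th[_G_ACH_LC] * C_A - th[_G_GABA_LC] * C_G + delta \
            - th[_G_SCN_LC] * C_GSCN + drive
        c_DR = th[_G_ACH_DR] * C_A - th[_G_GABA_DR] * C_G + delta \
            - th[_G_SCN_DR] * C_GSCN + drive
        c_V = -th[_G_NE_V] * C_N - th[_G_5HT_V] * C_S \
            - th[_G_SCN_V] * C_GSCN + drive
        c_R = th[_G_ACH_R] * C_A - th[_G_NE_R] * C_N - th[_G_5HT_R] * C_S \
            - th[_G_GABA_R] * C_G - th[_G_SCN_R] * C_GSCN + drive
        c_WR = th[_G_ACH_WR] * C_A - th[_G_GABA_WR] * C_G

        beta_V = th[_VLPO + _BETA] - th[_VLPO + _H_GAIN] * h

        out[0, j] = (_finf(c_LC, th[_LC + _F_MAX], th[_LC + _ALPHA], th[_LC + _BETA]) - F_LC) / th[_LC + _TAU_F]
        out[1, j] = (_finf(c_DR, th[_DR + _F_MAX], th[_DR + _ALPHA], th[_DR + _BETA]) - F_DR) / th[_DR + _TAU_F]
        out[2, j] = (_finf(c_V, th[_VLPO + _F_MAX], th[_VLPO + _ALPHA], beta_V) - F_V) / th[_VLPO + _TAU_F]
        out[3, j] = (_finf(c_R, th[_R + _F_MAX], th[_R + _ALPHA], th[_R + _BETA]) - F_R) / th[_R + _TAU_F]
        out[4, j] = (_finf(c_WR, th[_WR + _F_MAX], th[_WR + _ALPHA], th[_WR + _BETA]) - F_WR) / th[_WR + _TAU_F]

        out[5, j] = (np.tanh(F_LC / th[_LC + _GAMMA]) - C_N) / th[_LC + _TAU_C]
        out[6, j] = (np.tanh(F_DR / th[_DR + _GAMMA]) - C_S) / th[_DR + _TAU_C]
        out[7, j] = (np.tanh(F_V / th[_VLPO + _GAMMA]) - C_G) / th[_VLPO + _TAU_C]
        out[8, j] = (np.tanh(F_R / th[_R + _GAMMA]) - C_AR) / th[_R + _TAU_C]
        out[9, j] = (np.tanh(F_WR / th[_WR + _GAMMA]) - C_AWR) / th[_WR + _TAU_C]

        if F_LC > th[_THETA_W]:
            out[10, j] = (th[_H_MAX] - h) / th[_TAU_ACC]
        else:
            out[10, j] = -h / th[_TAU_DISS]

        out[11, j] = -delta / th[_TAU_DELTA]

        if variant == 1:
            F_SCN = X[12, j]
            c_SCN = _circ(t, th) + th[_G_5HT_SCN] * C_S + th[_G_ACH_SCN] * C_A
            out[12, j] = (_finf(c_SCN, th[_SCN + _F_MAX], th[_SCN + _ALPHA], th[_SCN + _BETA]) - F_SCN) / th[_SCN + _TAU_F]
            out[13, j] = (np.tanh(F_SCN / th[_SCN + _GAMMA]) - X[13, j]) / th[_SCN + _TAU_C]


@njit(cache=True)
def _rk4_mat(X, t, dt, th, variant):
    """One classical 4th-order Runge-Kutta step for a batch of states."""
    n, m = X.shape
    k1 = np.empty((n, m))
    k2 = np.empty((n, m))
    k3 = np.empty((n, m))
    k4 = np.empty((n, m))
    _rhs_mat(X, t, th, variant, k1)
    _rhs_mat(X + 0.5 * dt * k1, t + 0.5 * dt, th, variant, k2)
    _rhs_mat(X + 0.5 * dt * k2, t + 0.5 * dt, th, variant, k3)
    _rhs_mat(X + dt * k3, t + dt, th, variant, k4)
    return X + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


@njit(cache=True)
def _simulate(x0, nsteps, dt, th, variant, impulses, t0):
    """Integrate the model; Poisson impulse counts are applied to delta
    between RK4 steps so the deterministic integrator keeps its order."""
    n = x0.size
    X = np.empty((nsteps + 1, n))
    X[0] = x0
    x = x0.copy().reshape(n, 1)
    t = t0
    amp = th[_AMP]
    for k in range(nsteps):
        x = _rk4_mat(x, t, dt, th, variant)
        if impulses[k] > 0:
            x[11, 0] += amp * impulses[k]
        t = t0 + (k + 1) * dt
        for i in range(n):
            if not np.isfinite(x[i, 0]):
                return X, k
        X[k + 1] = x[:, 0]
    return X, -1


@njit(cache=True)
def _chol_lower(A, L):
    """Lower Cholesky factor; returns False instead of raising on failure."""
    n = A.shape[0]
    for i in range(n):
        for j in range(n):
            L[i, j] = 0.0
    for i in range(n):
        for j in range(i + 1):
            s = A[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 0.0:
                    return False
                L[i, j] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    return True


@njit(cache=True)
def _sigma_points(x, P, L, pts):
    """2n symmetric sigma points with spread sqrt(n*P); False on failure."""
    n = x.size
    A = n * P
    ok = _chol_lower(A, L)
    if not ok:
        jitter = 1e-12
        while jitter <= 1e-6:
            Aj = A.copy()
            for i in range(n):
                Aj[i, i] += n * jitter
            ok = _chol_lower(Aj, L)
            if ok:
                break
            jitter *= 100.0
        if not ok:
            return False
    for i in range(n):
        for j in range(n):
            pts[i, j] = x[i] + L[i, j]
            pts[i, n + j] = x[i] - L[i, j]
    return True


@njit(cache=True)
def _ukf_loop(y, obs_idx, Rdiag, Qdiag, x0, P0, th, dt, variant, t0):
    """Full predict/correct recursion over an observation series.

    y[k] is the measurement at time t0 + (k+1)*dt; a row containing any
    non-finite value is treated as missing (predict-only step).  Returns the
    reconstructed means, the covariance diagonals, the final covariance and
    a status step index (-1 on success, >= 0: sigma-point failure at step).
    """
    T, m = y.shape
    n = x0.size
    xs = np.empty((T, n))
    Ps = np.empty((T, n))
    x = x0.copy()
    P = P0.copy()
    L = np.empty((n, n))
    pts = np.empty((n, 2 * n))
    two_n = 2.0 * n
    t = t0
    for k in range(T):
        ok = _sigma_points(x, P, L, pts)
        if not ok:
            return xs, Ps, P, k
        prop = _rk4_mat(pts, t, dt, th, variant)
        # forecast mean and covariance (+ diagonal inflation Q)
        xpred = np.empty(n)
        for i in range(n):
            s = 0.0
            for j in range(2 * n):
                s += prop[i, j]
            xpred[i] = s / two_n
        dX = np.empty((n, 2 * n))
        for i in range(n):
            for j in range(2 * n):
                dX[i, j] = prop[i, j] - xpred[i]
        Pp = np.dot(dX, dX.T) / two_n
        for i in range(n):
            Pp[i, i] += Qdiag[i]

        have_obs = True
        for q in range(m):
            if not np.isfinite(y[k, q]):
                have_obs = False
        if have_obs:
            dY = np.empty((m, 2 * n))
            for q in range(m):
                for j in range(2 * n):
                    dY[q, j] = dX[obs_idx[q], j]
            Pyy = np.dot(dY, dY.T) / two_n
            Pxy = np.dot(dX, dY.T) / two_n
            S = Pyy.copy()
            for q in range(m):
                S[q, q] += Rdiag[k, q]
            K = np.linalg.solve(S.T.copy(), Pxy.T.copy()).T
            innov = np.empty(m)
            for q in range(m):
                innov[q] = y[k, q] - xpred[obs_idx[q]]
            x = xpred + np.dot(K, innov)
            Pp = Pp - np.dot(K, np.dot(S, K.T))
        else:
            x = xpred
        # enforce symmetry each iteration
        P = 0.5 * (Pp + Pp.T)
        for i in range(n):
            xs[k, i] = x[i]
            Ps[k, i] = P[i, i]
        t = t0 + (k + 1) * dt
    return xs, Ps, P, -1
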