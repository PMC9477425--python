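"""JIT-compiled inner loops (Euler integration, subset-entropy enumeration).

These kernels are numerical plumbing only; all science-facing defaults live in
the public modules. Noise inside the DMF kernel uses numba's Mersenne-Twister
(``np.random.seed`` in nopython mode), which is deterministic for a given seed
on every platform.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LOG_2PIE = float(np.log(2.0 * np.pi * np.e))


@njit(cache=True)
def transfer_rate_scalar(I: float, g: float, I_thr: float, d: float) -> float:
    """Sigmoidal current-to-rate transfer g(I-I_thr)/(1-exp(-d g (I-I_thr)))."""
    x = g * (I - I_thr)
    dx = d * x
    if abs(dx) < 1e-9:
        # analytic limit 1/d with first-order correction x/2
        return 1.0 / d + 0.5 * x
    return x / (1.0 - np.exp(-dx))


@njit(cache=True)
def dmf_euler(
    C,
    J,
    G,
    n_steps,
    dt,
    sigma,
    seed,
    I0,
    W_E,
    W_I,
    w_plus,
    J_NMDA,
    I_thr_E,
    I_thr_I,
    g_E,
    g_I,
    d_E,
    d_I,
    gamma_kin,
    tau_E,
    tau_I,
    S_E0,
    S_I0,
    record_gating,
):
    """Euler-Maruyama integration of the coupled E/I gating equations.

    ``dt``, ``tau_E``, ``tau_I`` in seconds; rates in Hz. Gating variables are
    clipped to [0, 1] after every step. Returns the excitatory-rate trajectory
    (n_steps x M), the post-step gating trajectories (empty unless
    ``record_gating``), and the final gating state.
    """
    M = C.shape[0]
    np.random.seed(seed)
    S_E = S_E0.copy()
    S_I = S_I0.copy()
    r_E_out = np.empty((n_steps, M))
    n_rec = n_steps if record_gating else 0
    S_E_out = np.empty((n_rec, M))
    S_I_out = np.empty((n_rec, M))
    sq = sigma * np.sqrt(dt)
    for t in range(n_steps):
        for n in range(M):
            coup = 0.0
            for p in range(M):
                coup += C[n, p] * S_E[p]
            I_E = W_E * I0 + w_plus * J_NMDA * S_E[n] + G * J_NMDA * coup - J[n] * S_I[n]
            I_I = W_I * I0 + J_NMDA * S_E[n] - S_I[n]
            r_E = transfer_rate_scalar(I_E, g_E, I_thr_E, d_E)
            r_I = transfer_rate_scalar(I_I, g_I, I_thr_I, d_I)
            r_E_out[t, n] = r_E
            dSE = -S_E[n] / tau_E + (1.0 - S_E[n]) * gamma_kin * r_E
            dSI = -S_I[n] / tau_I + r_I
            S_E[n] += dt * dSE
            S_I[n] += dt * dSI
            if sigma > 0.0:
                S_E[n] += sq * np.random.randn()
                S_I[n] += sq * np.random.randn()
            if S_E[n] < 0.0:
                S_E[n] = 0.0
            elif S_E[n] > 1.0:
                S_E[n] = 1.0
            if S_I[n] < 0.0:
                S_I[n] = 0.0
            elif S_I[n] > 1.0:
                S_I[n] = 1.0
            if record_gating:
                S_E_out[t, n] = S_E[n]
                S_I_out[t, n] = S_I[n]
        if not np.isfinite(S_E[0]):
            raise ValueError("non-finite DMF state (divergence); aborted")
    return r_E_out, S_E_out, S_I_out, S_E, S_I


@njit(cache=True)
def balloon_euler(
    r,
    dt,
    decim,
    kappa,
    gamma_f,
    tau,
    alpha,
    rho,
    V0,
    k1,
    k2,
    k3,
    s0,
    f0,
    v0,
    q0,
):
    """Euler integration of the balloon haemodynamics driven by firing rates.

    ``r`` is (n_steps x M) excitatory rate in Hz at step ``dt`` seconds. The
    BOLD readout is block-averaged over ``decim`` consecutive steps, giving an
    output of shape (n_steps // decim, M). f, v, q are floored at 1e-9; the
    number of floored samples is returned for logging.
    """
    n_steps, M = r.shape
    n_out = n_steps // decim
    B = np.zeros((n_out, M))
    s = s0.copy()
    f = f0.copy()
    v = v0.copy()
    q = q0.copy()
    ia = 1.0 / alpha
    n_floored = 0
    for t in range(n_out * decim):
        for m in range(M):
            fv = v[m] ** ia
            ds = 0.5 * r[t, m] + 3.0 - kappa * s[m] - gamma_f * (f[m] - 1.0)
            df = s[m]
            dv = (f[m] - fv) / tau
            dq = (f[m] * (1.0 - (1.0 - rho) ** (1.0 / f[m])) / rho - q[m] * fv / v[m]) / tau
            s[m] += dt * ds
            f[m] += dt * df
            v[m] += dt * dv
            q[m] += dt * dq
            if f[m] < 1e-9:
                f[m] = 1e-9
                n_floored += 1
            if v[m] < 1e-9:
                v[m] = 1e-9
                n_floored += 1
            if q[m] < 1e-9:
                q[m] = 1e-9
                n_floored += 1
            B[t // decim, m] += V0 * (k1 * (1.0 - q[m]) + k2 * (1.0 - q[m] / v[m]) + k3 * (1.0 - v[m]))
        if not np.isfinite(s[0]):
            raise ValueError("non-finite haemodynamic state; aborted")
    B /= decim
    return B, s, f, v, q, n_floored


@njit(cache=True)
def _popcount(x: int) -> int:
    c = 0
    while x:
        x &= x - 1
        c += 1
    return c


@njit(cache=True)
def subset_entropies(sigma, n_min, n_max):
    """Gaussian entropy of every variable subset, indexed by bitmask.

    Computes H[mask] = 0.5 ln((2 pi e)^k det(sigma[mask, mask])) for all masks
    whose size is 1 or in [n_min - 1, n_max]; other entries are NaN. Requires
    a positive-definite sigma (every principal submatrix then is too).
    """
    M = sigma.shape[0]
    n_masks = 1 << M
    H = np.full(n_masks, np.nan)
    idx = np.empty(M, dtype=np.int64)
    for mask in range(1, n_masks):
        k = _popcount(mask)
        if not (k == 1 or (n_min - 1 <= k <= n_max)):
            continue
        j = 0
        for i in range(M):
            if mask & (1 << i):
                idx[j] = i
                j += 1
        if k == 1:
            H[mask] = 0.5 * (LOG_2PIE + np.log(sigma[idx[0], idx[0]]))
            continue
        sub = np.empty((k, k))
        for a in range(k):
            for b in range(k):
                sub[a, b] = sigma[idx[a], idx[b]]
        L = np.linalg.cholesky(sub)
        logdet = 0.0
        for a in range(k):
            logdet += 2.0 * np.log(L[a, a])
        H[mask] = 0.5 * (k * LOG_2PIE + logdet)
    return H


@njit(cache=True)
def accumulate_oinfo(H, M, n_min, n_max):
    """O-information of every n-plet, accumulated per (region, order).

    For each subset of size n in [n_min, n_max]:
    omega = (n - 2) H(X) + sum_i [h(X_i) - H(X without i)],
    which equals TC - DTC. Returns per-(region, order) arrays of the omega sum,
    positive-omega sum/count and negative-omega sum/count (negative omegas are
    accumulated as |omega|). Exact zeros count in neither split.
    """
    n_masks = 1 << M
    sum_om = np.zeros((M, n_max + 1))
    sum_pos = np.zeros((M, n_max + 1))
    n_pos = np.zeros((M, n_max + 1), dtype=np.int64)
    sum_neg = np.zeros((M, n_max + 1))
    n_neg = np.zeros((M, n_max + 1), dtype=np.int64)
    members = np.empty(M, dtype=np.int64)
    for mask in range(1, n_masks):
        n = _popcount(mask)
        if n < n_min or n > n_max:
            continue
        j = 0
        for i in range(M):
            if mask & (1 << i):
                members[j] = i
                j += 1
        omega = (n - 2.0) * H[mask]
        for a in range(n):
            i = members[a]
            omega += H[1 << i] - H[mask ^ (1 << i)]
        for a in range(n):
            i = members[a]
            sum_om[i, n] += omega
            if omega > 0.0:
                sum_pos[i, n] += omega
                n_pos[i, n] += 1
            elif omega < 0.0:
                sum_neg[i, n] += -omega
                n_neg[i, n] += 1
    return sum_om, sum_pos, n_pos, sum_neg, n_neg
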