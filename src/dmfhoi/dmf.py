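"""Whole-brain dynamic mean-field (DMF) model with feedback inhibition control.

Each region holds an excitatory (NMDA) and an inhibitory (GABA) population
described by synaptic gating variables S_E, S_I. Regions are coupled through
the structural connectome scaled by the global coupling G. The per-region
feedback inhibitory weight J is calibrated (FIC) so that every excitatory
population fires near the 3 Hz working point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .io import Connectome, RegionTimeSeries

__all__ = [
    "DMFParameters",
    "FICWeights",
    "transfer_rate",
    "simulate_dmf",
    "calibrate_fic",
    "FICConvergenceError",
]

logger = logging.getLogger(__name__)


@dataclass
class DMFParameters:
    """DMF constants. Defaults are the standard parameter set of the model.

    Currents in nA, gains in nC^-1, shape constants in s, time constants in
    ms, rates in Hz; ``G`` and the scaling/recurrence factors dimensionless.
    """

    I0: float = 0.382          # external current, nA
    W_E: float = 1.0           # excitatory scaling of I0
    W_I: float = 0.7           # inhibitory scaling of I0
    w_plus: float = 1.4        # local excitatory recurrence
    J_NMDA: float = 0.15       # excitatory synaptic coupling, nA
    I_thr_E: float = 0.403     # excitatory transfer threshold, nA
    I_thr_I: float = 0.288     # inhibitory transfer threshold, nA
    g_E: float = 310.0         # excitatory gain, nC^-1
    g_I: float = 615.0         # inhibitory gain, nC^-1
    d_E: float = 0.16          # excitatory transfer shape, s
    d_I: float = 0.087         # inhibitory transfer shape, s
    gamma_kin: float = 0.641   # excitatory kinetic parameter
    sigma: float = 0.01        # noise amplitude, nA
    tau_NMDA: float = 100.0    # NMDA gating time constant, ms
    tau_GABA: float = 10.0     # GABA gating time constant, ms
    G: float = 0.0             # global coupling
    dt: float = 1.0            # integration step, ms

    def __post_init__(self) -> None:
        if self.tau_NMDA <= 0 or self.tau_GABA <= 0 or self.dt <= 0:
            raise ValueError("time constants and dt must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass
class FICWeights:
    """Per-region feedback inhibitory weights after calibration."""

    J: np.ndarray
    target_rate: float = 3.0
    achieved_rates: np.ndarray | None = None
    n_iterations: int = 0

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, dtype=float)
        if np.any(self.J <= 0):
            raise ValueError("FIC weights must be positive")


class FICConvergenceError(RuntimeError):
    pass


def transfer_rate(I, g: float, I_thr: float, d: float):
    """Population transfer function F(I) = g(I - I_thr) / (1 - exp(-d g (I - I_thr))).

    Total on finite inputs: at I = I_thr the removable singularity evaluates
    to the analytic limit 1/d; the expression is positive and strictly
    increasing everywhere. Accepts scalars or arrays.
    """
    I = np.asarray(I, dtype=float)
    x = g * (I - I_thr)
    dx = d * x
    small = np.abs(dx) < 1e-9
    with np.errstate(over="ignore"):
        out = np.where(small, 1.0 / d + 0.5 * x, x / (1.0 - np.exp(np.where(small, -1.0, -dx))))
    if out.ndim == 0:
        return float(out)
    return out


def _as_seed(seed) -> int:
    return int(np.asarray(seed).ravel()[0]) % (2**31 - 1)


def simulate_dmf(
    sc: Connectome,
    params: DMFParameters,
    J: FICWeights | np.ndarray,
    duration: float,
    seed: int,
    initial_gating: float = 0.001,
    return_state: bool = False,
    record_gating: bool = False,
) -> RegionTimeSeries:
    """Integrate the DMF equations and return excitatory rates at step resolution.

    Euler-Maruyama at ``params.dt`` ms with independent Gaussian increments
    sigma * sqrt(dt) per population, per region, per step; gating clipped to
    [0, 1] after every step. Identical seeds give bit-identical trajectories.
    With ``return_state`` the final (S_E, S_I) vectors are returned alongside;
    with ``record_gating`` the full gating trajectories are appended too.
    """
    Jv = J.J if isinstance(J, FICWeights) else np.asarray(J, dtype=float)
    M = sc.n_regions
    if Jv.shape != (M,):
        raise ValueError(f"J has shape {Jv.shape}; expected ({M},)")
    if duration < 1.0:
        raise ValueError("duration must be at least 1 s")
    dt_s = params.dt * 1e-3
    n_steps = int(round(duration / dt_s))
    S0 = np.full(M, float(initial_gating))
    try:
        r_E, S_E_traj, S_I_traj, S_E, S_I = _kernels.dmf_euler(
            sc.weights,
            Jv,
            params.G,
            n_steps,
            dt_s,
            params.sigma,
            _as_seed(seed),
            params.I0,
            params.W_E,
            params.W_I,
            params.w_plus,
            params.J_NMDA,
            params.I_thr_E,
            params.I_thr_I,
            params.g_E,
            params.g_I,
            params.d_E,
            params.d_I,
            params.gamma_kin,
            params.tau_NMDA * 1e-3,
            params.tau_GABA * 1e-3,
            S0,
            S0,
            record_gating,
        )
    except ValueError as err:
        raise RuntimeError(f"DMF integration diverged: {err}") from err
    rates = RegionTimeSeries(
        values=r_E,
        sampling_period=dt_s,
        kind="firing_rate_Hz",
        region_labels=list(sc.region_labels),
    )
    if record_gating:
        return rates, S_E_traj, S_I_traj, (S_E, S_I)
    if return_state:
        return rates, (S_E, S_I)
    return rates


def _mean_rates(
    sc: Connectome, params: DMFParameters, J: np.ndarray, seed: int, run_s: float, settle_s: float
) -> np.ndarray:
    rates = simulate_dmf(sc, params, J, duration=settle_s + run_s, seed=seed)
    n_settle = int(round(settle_s / rates.sampling_period))
    return rates.values[n_settle:].mean(axis=0)


def calibrate_fic(
    sc: Connectome,
    params: DMFParameters,
    target: float = 3.0,
    tol: float = 0.5,
    mean_tol: float = 0.05,
    seed: int = 0,
    eta: float = 0.005,
    max_iter: int = 100,
    run_s: float = 10.0,
    settle_s: float = 2.0,
    err_clip: float = 10.0,
) -> FICWeights:
    """Calibrate per-region feedback inhibition so excitatory rates sit at ``target`` Hz.

    Seeds J linearly from node strength (J_n = 0.75 G strength_n + 1), then
    iterates short noise-on runs, correcting J_n by ``eta`` nA per Hz of rate
    error (clipped to ``+/- err_clip`` Hz), until every region is within
    ``target +/- tol`` and the region mean is within ``+/- mean_tol``. The
    per-region step halves whenever the rate error changes sign and grows
    slowly otherwise (sign-flip damping), which keeps the update stable on the
    steep flank of the rate-vs-J curve near the network's bistable regime.
    Deterministic for a given master seed.
    """
    if target <= 0:
        raise ValueError("target rate must be positive")
    M = sc.n_regions
    J = 0.75 * params.G * sc.strength() + 1.0
    ss = np.random.SeedSequence(_as_seed(seed))
    run_seeds = [_as_seed(s.generate_state(1)) for s in ss.spawn(max_iter)]
    rates = np.full(M, np.nan)
    eta_n = np.full(M, eta)
    prev_err = np.zeros(M)
    for it in range(max_iter):
        rates = _mean_rates(sc, params, J, run_seeds[it], run_s, settle_s)
        err = rates - target
        if np.all(np.abs(err) <= tol) and abs(err.mean()) <= mean_tol:
            logger.info("FIC converged after %d iterations (mean rate %.3f Hz)", it + 1, rates.mean())
            return FICWeights(J=J, target_rate=target, achieved_rates=rates, n_iterations=it + 1)
        if it > 0:
            flip = err * prev_err < 0
            eta_n = np.where(flip, eta_n * 0.5, np.minimum(eta_n * 1.1, 10.0 * eta))
            eta_n = np.maximum(eta_n, 1e-4 * eta)
        prev_err = err
        J = np.maximum(J + eta_n * np.clip(err, -err_clip, err_clip), 1e-3)
    worst = int(np.argmax(np.abs(rates - target)))
    raise FICConvergenceError(
        f"FIC did not converge in {max_iter} iterations; worst region {worst} "
        f"at {rates[worst]:.2f} Hz (target {target} Hz)"
    )
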