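"""Balloon haemodynamics: firing rates -> BOLD-like signals.

The excitatory rate drives a vasodilatory signal s, blood inflow f, venous
volume v and deoxyhemoglobin content q per region:

    ds/dt = 0.5 r + 3 - kappa s - gamma_f (f - 1)
    df/dt = s
    tau dv/dt = f - v^(1/alpha)
    tau dq/dt = f (1 - (1 - rho)^(1/f)) / rho - q v^(1/alpha) / v

with the BOLD readout B = V0 [k1 (1 - q) + k2 (1 - q/v) + k3 (1 - v)].
Signals are band-pass filtered (0.01-0.1 Hz, zero-phase 3rd-order Bessel)
and sampled at the BOLD repetition time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from . import _kernels
from .io import RegionTimeSeries

__all__ = [
    "HemodynamicParameters",
    "HemodynamicState",
    "balloon_step",
    "balloon_equilibrium",
    "bold_readout",
    "bessel_bandpass",
    "simulate_bold",
]

logger = logging.getLogger(__name__)


@dataclass
class HemodynamicParameters:
    """Balloon constants (rates in s^-1, tau in s, the rest dimensionless)."""

    kappa: float = 0.65    # vasodilatory signal decay rate, s^-1
    gamma_f: float = 0.41  # flow-dependent elimination, s^-1
    tau: float = 0.98      # haemodynamic transit time, s
    alpha: float = 0.32    # vessel stiffness exponent (resistance of the veins)
    rho: float = 0.34      # resting oxygen extraction fraction
    V0: float = 0.04       # resting venous blood volume fraction
    k1: float = 2.77       # BOLD kinetic constants
    k2: float = 0.2
    k3: float = 0.5

    def __post_init__(self) -> None:
        if min(self.tau, self.alpha, self.V0) <= 0 or not 0 < self.rho < 1:
            raise ValueError("tau, alpha, V0 must be positive and rho in (0, 1)")


@dataclass
class HemodynamicState:
    """Per-region state vectors s (signal), f (inflow), v (volume), q (dHb)."""

    s: np.ndarray
    f: np.ndarray
    v: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        for name in ("s", "f", "v", "q"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        if np.any(self.f <= 0) or np.any(self.v <= 0) or np.any(self.q <= 0):
            raise ValueError("f, v, q must be positive")

    @classmethod
    def resting(cls, M: int) -> "HemodynamicState":
        one = np.ones(M)
        return cls(s=np.zeros(M), f=one.copy(), v=one.copy(), q=one.copy())


def _drift(state: HemodynamicState, r_E: np.ndarray, p: HemodynamicParameters):
    ia = 1.0 / p.alpha
    fv = state.v**ia
    ds = 0.5 * r_E + 3.0 - p.kappa * state.s - p.gamma_f * (state.f - 1.0)
    df = state.s
    dv = (state.f - fv) / p.tau
    dq = (state.f * (1.0 - (1.0 - p.rho) ** (1.0 / state.f)) / p.rho - state.q * fv / state.v) / p.tau
    return ds, df, dv, dq


def balloon_step(
    state: HemodynamicState, r_E, p: HemodynamicParameters, dt: float
) -> HemodynamicState:
    """One Euler update of the balloon ODEs; f, v, q floored at 1e-9."""
    if dt > 1e-3 + 1e-12:
        raise ValueError("balloon Euler step requires dt <= 1 ms")
    r_E = np.atleast_1d(np.asarray(r_E, dtype=float))
    ds, df, dv, dq = _drift(state, r_E, p)
    s = state.s + dt * ds
    f = state.f + dt * df
    v = state.v + dt * dv
    q = state.q + dt * dq
    floored = (f < 1e-9).sum() + (v < 1e-9).sum() + (q < 1e-9).sum()
    if floored:
        logger.warning("balloon state floored at 1e-9 for %d entries", int(floored))
    new = HemodynamicState(
        s=s, f=np.maximum(f, 1e-9), v=np.maximum(v, 1e-9), q=np.maximum(q, 1e-9)
    )
    if not all(np.isfinite(x).all() for x in (new.s, new.f, new.v, new.q)):
        raise RuntimeError("non-finite haemodynamic state")
    return new


def balloon_equilibrium(r_E, p: HemodynamicParameters) -> HemodynamicState:
    """Closed-form fixed point of the balloon ODEs for a constant rate drive.

    s = 0, f = 1 + (0.5 r + 3)/gamma_f, v = f^alpha,
    q = f (1 - (1 - rho)^(1/f)) / rho * v^(1 - 1/alpha).
    """
    r_E = np.atleast_1d(np.asarray(r_E, dtype=float))
    f = 1.0 + (0.5 * r_E + 3.0) / p.gamma_f
    v = f**p.alpha
    q = f * (1.0 - (1.0 - p.rho) ** (1.0 / f)) / p.rho * v ** (1.0 - 1.0 / p.alpha)
    return HemodynamicState(s=np.zeros_like(f), f=f, v=v, q=q)


def bold_readout(state: HemodynamicState, p: HemodynamicParameters) -> np.ndarray:
    """BOLD signal B = V0 [k1 (1 - q) + k2 (1 - q/v) + k3 (1 - v)] per region."""
    if np.any(state.v <= 0):
        raise ValueError("blood volume must be positive")
    return p.V0 * (
        p.k1 * (1.0 - state.q) + p.k2 * (1.0 - state.q / state.v) + p.k3 * (1.0 - state.v)
    )


def bessel_bandpass(
    ts: RegionTimeSeries, lo: float = 0.01, hi: float = 0.1, order: int = 3
) -> RegionTimeSeries:
    """Zero-phase (forward-backward) digital Bessel band-pass filter."""
    fs = 1.0 / ts.sampling_period
    if hi >= fs / 2:
        raise ValueError(f"band edge {hi} Hz at or above Nyquist {fs / 2} Hz")
    sos = sps.bessel(order, [lo, hi], btype="bandpass", output="sos", fs=fs)
    out = sps.sosfiltfilt(sos, ts.values, axis=0)
    return RegionTimeSeries(
        values=out, sampling_period=ts.sampling_period, kind=ts.kind, region_labels=ts.region_labels
    )


def simulate_bold(
    rates: RegionTimeSeries,
    params: HemodynamicParameters | None = None,
    tr: float = 3.0,
    n_points: int = 160,
    burn_in: float = 20.0,
    filter_band: tuple[float, float] = (0.01, 0.1),
    intermediate_dt: float = 1.0,
) -> RegionTimeSeries:
    """Turn a firing-rate trajectory into n_points of filtered BOLD at TR spacing.

    Integrates the balloon ODEs at the rate sampling step (1 ms), starting at
    the fixed point of the initial rates, block-averages the readout onto a
    coarse grid (``intermediate_dt`` seconds, where the band-pass is
    numerically well-conditioned), discards ``burn_in`` seconds, filters, and
    takes every (tr / intermediate_dt)-th sample.
    """
    if params is None:
        params = HemodynamicParameters()
    needed = burn_in + n_points * tr
    if rates.duration + 1e-9 < needed:
        raise ValueError(
            f"rate input covers {rates.duration:.1f} s but burn-in + BOLD needs {needed:.1f} s"
        )
    dt = rates.sampling_period
    decim = int(round(intermediate_dt / dt))
    if abs(decim * dt - intermediate_dt) > 1e-9:
        raise ValueError("intermediate_dt must be a multiple of the rate sampling period")
    stride = int(round(tr / intermediate_dt))
    if abs(stride * intermediate_dt - tr) > 1e-9:
        raise ValueError("tr must be a multiple of intermediate_dt")
    M = rates.n_regions
    eq = balloon_equilibrium(rates.values[0], params)
    B, *_, n_floored = _kernels.balloon_euler(
        rates.values,
        dt,
        decim,
        params.kappa,
        params.gamma_f,
        params.tau,
        params.alpha,
        params.rho,
        params.V0,
        params.k1,
        params.k2,
        params.k3,
        eq.s,
        eq.f,
        eq.v,
        eq.q,
    )
    if n_floored:
        logger.warning("balloon state floored at 1e-9 for %d samples", int(n_floored))
    coarse = RegionTimeSeries(
        values=B, sampling_period=intermediate_dt, kind="bold", region_labels=rates.region_labels
    )
    n_burn = int(round(burn_in / intermediate_dt))
    trimmed = RegionTimeSeries(
        values=coarse.values[n_burn:],
        sampling_period=intermediate_dt,
        kind="bold",
        region_labels=rates.region_labels,
    )
    filtered = bessel_bandpass(trimmed, *filter_band)
    sampled = filtered.values[::stride][:n_points]
    if sampled.shape[0] < n_points:
        raise ValueError("insufficient input duration after burn-in for requested BOLD points")
    return RegionTimeSeries(
        values=sampled, sampling_period=tr, kind="bold", region_labels=rates.region_labels
    )
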