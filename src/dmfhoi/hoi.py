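"""O-information analysis of region time series.

For an n-plet X = (X_1 .. X_n) the total correlation TC = sum_i H(X_i) - H(X)
and the dual total correlation DTC = H(X) - sum_i H(X_i | X_-i) are combined
into the O-information Omega = TC - DTC: positive values mark redundancy-
dominated n-plets, negative values synergy-dominated ones. Entropies are
parametric Gaussian-copula estimates, so every subset entropy follows from
the log-determinant of a submatrix of the copula correlation matrix.

``enumerate_oinfo`` sweeps all n-plets for 3 <= n <= M, memoizing the subset
entropies over the bitmask lattice, and aggregates per region m and order n:

    omega_mean[m, n] = (1 / Z_n) sum over n-plets containing m of Omega,
    Z_n = C(M - 1, n - 1),

with redundancy R[m, n] (mean positive Omega) and synergy S[m, n]
(mean |negative Omega|) over the n-plets containing m, and grand averages
over the M regions per order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

from . import _kernels
from .fit import copula_normalize
from .io import RegionTimeSeries

__all__ = [
    "CovarianceModel",
    "OInfoTable",
    "gaussian_entropy",
    "o_information",
    "enumerate_oinfo",
    "redundancy_synergy",
    "oinfo_from_timeseries",
]

logger = logging.getLogger(__name__)

_RIDGE = 1e-10
_MAX_REGIONS = 25  # 2^M entropy memo guard


@dataclass
class CovarianceModel:
    """Correlation matrix of copula-normalized signals (entropy basis)."""

    sigma: np.ndarray
    T: int = 0

    def __post_init__(self) -> None:
        s = np.asarray(self.sigma, dtype=float)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("sigma must be square")
        if np.abs(s - s.T).max(initial=0.0) > 1e-10:
            raise ValueError("sigma must be symmetric")
        s = 0.5 * (s + s.T)
        min_eig = float(np.linalg.eigvalsh(s)[0])
        if min_eig <= _RIDGE:
            logger.info("regularizing covariance: min eigenvalue %.3g, adding %.0e I", min_eig, _RIDGE)
            s = s + _RIDGE * np.eye(s.shape[0])
            if np.linalg.eigvalsh(s)[0] <= 0:
                raise ValueError("covariance not positive definite even after ridge")
        self.sigma = s

    @classmethod
    def from_timeseries(cls, ts: RegionTimeSeries) -> "CovarianceModel":
        normed = copula_normalize(ts)
        return cls(sigma=np.corrcoef(normed.values, rowvar=False), T=ts.n_samples)

    @property
    def n_vars(self) -> int:
        return self.sigma.shape[0]


@dataclass
class OInfoTable:
    """Per-(region, order) O-information aggregates for one run/participant.

    ``regions`` has one row per (region, order) with columns omega_mean,
    sum_pos, n_pos, sum_neg, n_neg and, after ``redundancy_synergy``, R, S and
    the r_defined/s_defined flags (False when no positive/negative n-plet
    contains the region, in which case the value is 0 by convention).
    """

    regions: pd.DataFrame
    M: int
    order_range: tuple[int, int]
    meta: dict = field(default_factory=dict)

    def z_n(self, n: int) -> int:
        """Number of n-plets containing a fixed region: C(M - 1, n - 1)."""
        return comb(self.M - 1, n - 1)

    def grand_averages(self) -> pd.DataFrame:
        """Order-wise averages over the M regions (omega and, if filled, R and S)."""
        cols = ["omega_mean"] + [c for c in ("R", "S") if c in self.regions.columns]
        out = self.regions.groupby("order")[cols].mean().reset_index()
        return out.rename(columns={"omega_mean": "omega"})


def gaussian_entropy(sub_sigma: np.ndarray) -> float:
    """Entropy of a k-variate Gaussian: 1/2 ln((2 pi e)^k det Sigma), nats."""
    s = np.atleast_2d(np.asarray(sub_sigma, dtype=float))
    k = s.shape[0]
    sign, logdet = np.linalg.slogdet(s)
    if sign <= 0:
        raise ValueError("covariance determinant <= 0 (rank deficient); regularize first")
    return 0.5 * (k * _kernels.LOG_2PIE + logdet)


def o_information(cov: CovarianceModel, subset) -> dict[str, float]:
    """TC, DTC and Omega (nats) of one n-plet, with a dual-route consistency check.

    Omega is computed both as TC - DTC and via the reduced entropy identity
    Omega = sum_i h(X_i) + (n - 2) h(X) - sum_i h(X_-i); the two must agree
    to 1e-9.
    """
    subset = list(subset)
    n = len(subset)
    if n < 3 or n > cov.n_vars:
        raise ValueError(f"order must be in [3, {cov.n_vars}]; got {n}")
    if len(set(subset)) != n:
        raise ValueError("subset indices must be distinct")
    sig = cov.sigma[np.ix_(subset, subset)]
    h_joint = gaussian_entropy(sig)
    h_single = [gaussian_entropy(sig[i : i + 1, i : i + 1]) for i in range(n)]
    keep = np.arange(n)
    h_minus = [gaussian_entropy(sig[np.ix_(keep != i, keep != i)]) for i in range(n)]
    tc = sum(h_single) - h_joint
    dtc = h_joint - sum(h_joint - hm for hm in h_minus)
    omega = tc - dtc
    omega_reduced = sum(h_single) + (n - 2) * h_joint - sum(h_minus)
    if abs(omega - omega_reduced) > 1e-9:
        raise AssertionError(
            f"O-information routes disagree: {omega} vs {omega_reduced}"
        )
    if tc < -1e-9 or dtc < -1e-9:
        raise AssertionError(f"negative TC/DTC on positive-definite input: {tc}, {dtc}")
    return {"tc": tc, "dtc": dtc, "omega": omega}


def enumerate_oinfo(
    cov: CovarianceModel, order_range: tuple[int, int] | None = None
) -> OInfoTable:
    """O-information aggregates over every n-plet, n in ``order_range``.

    Memoizes the subset entropies by bitmask so each of the needed subset
    entropies is computed exactly once, then accumulates the per-(region,
    order) omega sums and positive/negative splits.
    """
    M = cov.n_vars
    if M > _MAX_REGIONS:
        raise ValueError(f"enumeration guarded at M <= {_MAX_REGIONS}; got {M}")
    n_min, n_max = order_range if order_range is not None else (3, M)
    if n_min < 3 or n_max > M or n_min > n_max:
        raise ValueError(f"order range [{n_min}, {n_max}] outside [3, {M}]")
    H = _kernels.subset_entropies(cov.sigma, n_min, n_max)
    sum_om, sum_pos, n_pos, sum_neg, n_neg = _kernels.accumulate_oinfo(H, M, n_min, n_max)
    rows = []
    for n in range(n_min, n_max + 1):
        z = comb(M - 1, n - 1)
        for m in range(M):
            rows.append(
                {
                    "region": m,
                    "order": n,
                    "omega_mean": sum_om[m, n] / z,
                    "sum_pos": sum_pos[m, n],
                    "n_pos": int(n_pos[m, n]),
                    "sum_neg": sum_neg[m, n],
                    "n_neg": int(n_neg[m, n]),
                }
            )
    return OInfoTable(regions=pd.DataFrame(rows), M=M, order_range=(n_min, n_max))


def redundancy_synergy(table: OInfoTable) -> OInfoTable:
    """Fill per-(region, order) redundancy R and synergy S from the omega splits.

    R = (positive-omega sum) / N+, S = (|negative-omega| sum) / N-; when a
    region participates in no positive (negative) n-plet at that order the
    value is 0 and flagged via r_defined (s_defined) = False.
    """
    df = table.regions.copy()
    df["R"] = np.where(df["n_pos"] > 0, df["sum_pos"] / df["n_pos"].clip(lower=1), 0.0)
    df["S"] = np.where(df["n_neg"] > 0, df["sum_neg"] / df["n_neg"].clip(lower=1), 0.0)
    df["r_defined"] = df["n_pos"] > 0
    df["s_defined"] = df["n_neg"] > 0
    return OInfoTable(regions=df, M=table.M, order_range=table.order_range, meta=dict(table.meta))


def oinfo_from_timeseries(
    ts: RegionTimeSeries, order_range: tuple[int, int] | None = None
) -> OInfoTable:
    """Copula-normalize, enumerate all n-plets and fill redundancy/synergy."""
    cov = CovarianceModel.from_timeseries(ts)
    return redundancy_synergy(enumerate_oinfo(cov, order_range))
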