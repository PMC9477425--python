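"""Gaussian-copula functional connectivity and global-coupling (G) selection.

FC between two regions is the Gaussian-copula mutual information
MI = -1/2 ln(1 - rho^2) (nats), with rho the Pearson correlation of the
normal-score (copula) transformed signals. The global coupling G is chosen
on a grid by minimizing the two-sample Kolmogorov-Smirnov distance between
the pooled simulated FC values and a reference FC-value sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dmf import DMFParameters, calibrate_fic, simulate_dmf
from .hemo import HemodynamicParameters, simulate_bold
from .io import Connectome, RegionTimeSeries, RunConfig

__all__ = [
    "FCMatrix",
    "GFitResult",
    "copula_normalize",
    "pairwise_mi_fc",
    "ks_distance",
    "fit_global_coupling",
    "simulate_bold_run",
]

logger = logging.getLogger(__name__)


@dataclass
class FCMatrix:
    """Symmetric matrix of pairwise Gaussian-copula MI values (nats), zero diagonal."""

    mi: np.ndarray

    def __post_init__(self) -> None:
        mi = np.asarray(self.mi, dtype=float)
        if mi.ndim != 2 or mi.shape[0] != mi.shape[1]:
            raise ValueError("FC matrix must be square")
        if np.abs(mi - mi.T).max(initial=0.0) > 1e-12:
            raise ValueError("FC matrix must be symmetric")
        if mi.min(initial=0.0) < -1e-12:
            raise ValueError("MI entries must be non-negative")
        self.mi = mi

    def upper_values(self) -> np.ndarray:
        """Off-diagonal upper-triangle MI values as a flat sample."""
        iu = np.triu_indices_from(self.mi, k=1)
        return self.mi[iu]


@dataclass
class GFitResult:
    g_grid: list[float]
    ks_per_g: list[float]
    g_opt: float
    n_runs_per_g: int
    n_failed: dict[float, int] = field(default_factory=dict)


def copula_normalize(ts: RegionTimeSeries) -> RegionTimeSeries:
    """Rank each column to uniform scores (rank - 0.5)/T, then map to normal quantiles.

    Invariant to strictly monotone transforms of each column; idempotent up to
    rank ties. Raises on constant columns (ranks undefined).
    """
    X = ts.values
    T = X.shape[0]
    if T < 3:
        raise ValueError("need at least 3 samples for copula normalization")
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.ptp(col) == 0:
            label = ts.region_labels[j] if ts.region_labels else str(j)
            raise ValueError(f"constant column for region {label!r}: ranks undefined")
        ranks = stats.rankdata(col, method="average")
        out[:, j] = stats.norm.ppf((ranks - 0.5) / T)
    return RegionTimeSeries(
        values=out, sampling_period=ts.sampling_period, kind=ts.kind, region_labels=ts.region_labels
    )


def pairwise_mi_fc(ts: RegionTimeSeries) -> FCMatrix:
    """Pairwise Gaussian-copula MI matrix: MI(i, j) = -1/2 ln(1 - rho_ij^2) nats.

    Copula normalization is always applied internally (it is idempotent on
    already-normalized input, since ranks are preserved).
    """
    normed = copula_normalize(ts)
    rho = np.corrcoef(normed.values, rowvar=False)
    return mi_from_correlation(rho)


def mi_from_correlation(rho: np.ndarray) -> FCMatrix:
    """Closed-form Gaussian MI from a correlation matrix."""
    rho = np.asarray(rho, dtype=float)
    off = ~np.eye(rho.shape[0], dtype=bool)
    if np.any(np.abs(rho[off]) >= 1.0):
        i, j = np.argwhere(off & (np.abs(rho) >= 1.0))[0]
        raise ValueError(f"|rho| = 1 between regions {i} and {j}: infinite MI (duplicated series?)")
    mi = np.zeros_like(rho)
    mi[off] = -0.5 * np.log1p(-rho[off] ** 2)
    mi = 0.5 * (mi + mi.T)
    return FCMatrix(mi=mi)


def ks_distance(a, b) -> float:
    """Two-sample Kolmogorov-Smirnov statistic sup_x |ECDF_a(x) - ECDF_b(x)|."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS distance requires two non-empty samples")
    return float(stats.ks_2samp(a, b).statistic)


def simulate_bold_run(
    sc: Connectome,
    g: float,
    J,
    cfg: RunConfig,
    seed: int,
    dmf_params: DMFParameters | None = None,
    hemo_params: HemodynamicParameters | None = None,
) -> RegionTimeSeries:
    """One full DMF -> balloon -> filtered BOLD simulation at coupling ``g``."""
    base = dmf_params or DMFParameters()
    params = DMFParameters(**{**base.__dict__, "G": g})
    duration = cfg.dmf_burn_in + cfg.burn_in + cfg.bold_duration
    rates = simulate_dmf(sc, params, J, duration=duration, seed=seed)
    n_burn = int(round(cfg.dmf_burn_in / rates.sampling_period))
    neural = RegionTimeSeries(
        values=rates.values[n_burn:],
        sampling_period=rates.sampling_period,
        kind="firing_rate_Hz",
        region_labels=rates.region_labels,
    )
    return simulate_bold(
        neural, hemo_params, tr=cfg.bold_tr, n_points=cfg.bold_points, burn_in=cfg.burn_in
    )


def fit_global_coupling(
    sc: Connectome,
    reference_fc_values,
    cfg: RunConfig,
    seed: int = 0,
    dmf_params: DMFParameters | None = None,
    fic_kwargs: dict | None = None,
) -> GFitResult:
    """Select G on ``cfg.G_grid`` by minimizing the KS distance of FC values.

    For each G: calibrate FIC, run ``cfg.n_runs_per_G`` simulations with
    distinct seeds, pool the upper-triangle FC values of all runs, and compute
    the KS distance to the reference sample. Ties break toward smaller G.
    Diverged runs are excluded; a G with more than 50% failures is marked
    invalid (KS = NaN).
    """
    from .dmf import FICConvergenceError

    reference = np.asarray(reference_fc_values, dtype=float).ravel()
    if reference.size == 0:
        raise ValueError("reference FC sample is empty")
    if not cfg.G_grid:
        raise ValueError("G grid is empty")
    ks_per_g: list[float] = []
    n_failed: dict[float, int] = {}
    for gi, g in enumerate(cfg.G_grid):
        g_ss = np.random.SeedSequence(entropy=seed, spawn_key=(gi,))
        children = g_ss.spawn(cfg.n_runs_per_G + 1)
        fic_seed = int(children[0].generate_state(1)[0]) % (2**31 - 1)
        params = DMFParameters(**{**(dmf_params or DMFParameters()).__dict__, "G": g})
        try:
            J = calibrate_fic(sc, params, seed=fic_seed, **(fic_kwargs or {}))
        except FICConvergenceError as err:
            logger.warning("G=%.2f marked invalid: FIC calibration failed (%s)", g, err)
            n_failed[g] = cfg.n_runs_per_G
            ks_per_g.append(float("nan"))
            continue
        pooled = []
        failed = 0
        for child in children[1:]:
            run_seed = int(child.generate_state(1)[0]) % (2**31 - 1)
            try:
                bold = simulate_bold_run(sc, g, J, cfg, run_seed, dmf_params=dmf_params)
                pooled.append(pairwise_mi_fc(bold).upper_values())
            except (RuntimeError, ValueError) as err:
                failed += 1
                logger.warning("run failed at G=%.2f (seed %d): %s", g, run_seed, err)
        n_failed[g] = failed
        if failed > cfg.n_runs_per_G / 2 or not pooled:
            logger.warning("G=%.2f marked invalid: %d/%d runs failed", g, failed, cfg.n_runs_per_G)
            ks_per_g.append(float("nan"))
            continue
        ks_per_g.append(ks_distance(np.concatenate(pooled), reference))
    ks = np.asarray(ks_per_g)
    if np.all(np.isnan(ks)):
        raise RuntimeError("all G values invalid: no successful simulations")
    g_opt = cfg.G_grid[int(np.nanargmin(ks))]  # argmin scans left-to-right: ties -> smaller G
    return GFitResult(
        g_grid=list(cfg.G_grid),
        ks_per_g=ks_per_g,
        g_opt=float(g_opt),
        n_runs_per_g=cfg.n_runs_per_G,
        n_failed=n_failed,
    )
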