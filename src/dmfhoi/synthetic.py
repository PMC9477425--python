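"""Synthetic age-graded connectome cohorts and Gaussian benchmark signals.

The cohort generator plants everything the downstream analyses estimate:

* a base (young) connectome with log-normal link weights;
* a quadratic ageing law w_old = a2 w^2 + a1 w + a0 relating the young-group
  and old-group average weights;
* heterogeneous degeneration: a partition of regions into link communities,
  each with its own degeneration rate, so that link weight declines with age
  on degenerating links (quadratically in age, hence the group-mean map is
  itself quadratic in w) and stays flat where the rate is zero;
* per-subject multiplicative log-normal link noise.

The Gaussian benchmarks provide signals whose generating covariance has a
known O-information sign (independent / redundant / synergistic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hoi import CovarianceModel, o_information
from .io import GROUP_BANDS, Cohort, Connectome, RegionTimeSeries

__all__ = [
    "SyntheticCohortSpec",
    "GroundTruth",
    "random_connectome",
    "generate_cohort",
    "generate_hoi_benchmark",
]


def random_connectome(
    M: int, median: float = 50.0, log_sd: float = 1.5, seed: int = 0, labels: list[str] | None = None
) -> Connectome:
    """A dense symmetric log-normal connectome (zero diagonal).

    The default log-sd of 1.5 natural-log units emulates the heavy,
    orders-of-magnitude spread of empirical streamline counts, so that after
    max-normalization the node strengths stay well below the matrix maximum.
    """
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(M, k=1)
    ut = median * np.exp(log_sd * rng.standard_normal(iu[0].size))
    w = np.zeros((M, M))
    w[iu] = ut
    w = w + w.T
    return Connectome(
        weights=w,
        region_labels=labels or [f"R{i + 1}" for i in range(M)],
        subject_id=f"synthetic_{seed}",
    )

#: E[((age - 10)/70)^2] for age uniform on the old-group band [60, 80]
_K_OLD = (25.0 / 49.0 + 5.0 / 7.0 + 1.0) / 3.0


def _default_partition(M: int) -> list[list[int]]:
    cuts = [0, M // 3, 2 * M // 3, M]
    return [list(range(cuts[i], cuts[i + 1])) for i in range(3)]


@dataclass
class SyntheticCohortSpec:
    """Study conditions of a generated cohort.

    Group sizes default to the empirical cohort (I1: 28, I2: 46, I3: 29,
    I4: 58). ``base_weight_law`` gives (median, log-sd) of the log-normal
    link-weight distribution. ``community_rates`` scale each planted
    community's degeneration (1 = full quadratic ageing law, 0 = no decline).
    ``link_noise_cv`` is the coefficient of variation of the per-subject
    multiplicative link noise; the default 0.3 places the link-age Spearman
    correlation of fully degenerating links in the -0.25..-0.5 band.
    """

    M: int = 20
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"I1": 28, "I2": 46, "I3": 29, "I4": 58}
    )
    base_weight_law: tuple[float, float] = (50.0, 0.8)
    planted_communities: list[list[int]] | None = None
    community_rates: tuple[float, ...] = (1.0, 1.0, 1.0)
    ageing_coeffs: tuple[float, float, float] = (-0.0015, 0.9, 0.0)
    link_noise_cv: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("each group needs at least 2 subjects")
        if set(self.group_sizes) != set(GROUP_BANDS):
            raise ValueError(f"group sizes must cover {sorted(GROUP_BANDS)}")
        if self.planted_communities is None:
            self.planted_communities = _default_partition(self.M)
        covered = sorted(i for c in self.planted_communities for i in c)
        if covered != list(range(self.M)):
            raise ValueError("planted communities must partition the regions")
        if len(self.community_rates) != len(self.planted_communities):
            raise ValueError("one degeneration rate per planted community")
        if self.link_noise_cv < 0:
            raise ValueError("link_noise_cv must be non-negative")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery checks and run manifests."""

    ageing_coeffs: tuple[float, float, float]
    community_labels: np.ndarray
    slopes: np.ndarray  # per-link decline slopes s_ij
    base_weights: np.ndarray
    seed: int


def _age_phi(age) -> np.ndarray:
    """Normalized squared age (10 -> 0, 80 -> 1): the planted decline shape."""
    return ((np.asarray(age, dtype=float) - 10.0) / 70.0) ** 2


def generate_cohort(spec: SyntheticCohortSpec) -> tuple[Cohort, GroundTruth]:
    """Draw a cohort whose group-mean ageing follows the planted quadratic law.

    Weights follow w_ij(age) = base_ij (1 - s_ij phi(age)) noise_ij with
    phi(age) = ((age - 10)/70)^2 and per-link slope
    s_ij = rate_ij (1 - f(base_ij)/base_ij) / E[phi | old band], so that at
    rate 1 the expected old-group mean of each link equals f(base_ij) for the
    planted quadratic f, and links with rate 0 carry no age trend.
    """
    rng = np.random.default_rng(spec.seed)
    M = spec.M
    a2, a1, a0 = spec.ageing_coeffs

    def f(w):
        return a2 * w**2 + a1 * w + a0

    # truncated log-normal base weights: streamline-count-like, bounded tail
    # (truncation at the 99th percentile keeps extreme-leverage links out of
    # the planted quadratic's infeasible range)
    median, log_sd = spec.base_weight_law
    iu = np.triu_indices(M, k=1)
    z = rng.standard_normal(iu[0].size)
    base_ut = median * np.exp(log_sd * np.clip(z, -2.326, 2.326))
    ratio = f(base_ut) / base_ut
    slopes_ut = (1.0 - ratio) / _K_OLD
    # a slope above 1 would drive the oldest ages below zero weight; clip the
    # rare heavy-tail links at 98% total decline, but refuse a spec whose law
    # is infeasible for a non-negligible share of links
    clipped = slopes_ut > 0.98
    if clipped.mean() > 0.05:
        raise ValueError(
            "infeasible spec: ageing law drives more than 5% of realized link "
            "weights to (or below) zero; shrink the weight law or the coefficients"
        )
    slopes_ut = np.minimum(slopes_ut, 0.98)

    labels = np.empty(M, dtype=int)
    for k, com in enumerate(spec.planted_communities):
        labels[com] = k
    rate_ut = np.array(
        [
            0.5 * (spec.community_rates[labels[i]] + spec.community_rates[labels[j]])
            for i, j in zip(*iu)
        ]
    )
    slopes_ut = slopes_ut * rate_ut

    def _full(ut: np.ndarray) -> np.ndarray:
        m = np.zeros((M, M))
        m[iu] = ut
        return m + m.T

    base = _full(base_ut)
    slopes = _full(slopes_ut)

    sigma_n = np.sqrt(np.log1p(spec.link_noise_cv**2))
    region_labels = [f"R{i + 1}" for i in range(M)]
    connectomes: list[Connectome] = []
    groups: dict[str, str] = {}
    ages: dict[str, float] = {}
    for grp in sorted(spec.group_sizes):
        lo, hi = GROUP_BANDS[grp]
        for s in range(spec.group_sizes[grp]):
            sid = f"{grp}_s{s:03d}"
            age = float(rng.uniform(lo, hi))
            decline = 1.0 - slopes_ut * _age_phi(age)
            if spec.link_noise_cv > 0:
                noise = np.exp(sigma_n * rng.standard_normal(base_ut.size) - 0.5 * sigma_n**2)
            else:
                noise = 1.0
            w_ut = base_ut * decline * noise
            if np.any(w_ut < 0):
                raise ValueError("infeasible spec: decline produced negative weights")
            connectomes.append(
                Connectome(weights=_full(w_ut), region_labels=region_labels, subject_id=sid, age=age)
            )
            groups[sid] = grp
            ages[sid] = age
    cohort = Cohort(connectomes=connectomes, group_assignment=groups, ages=ages)
    truth = GroundTruth(
        ageing_coeffs=spec.ageing_coeffs,
        community_labels=labels,
        slopes=slopes,
        base_weights=base,
        seed=spec.seed,
    )
    return cohort, truth


def generate_hoi_benchmark(
    kind: str, n_vars: int = 3, T: int = 5000, seed: int = 0, loading: float = 0.9, noise: float = 0.1
) -> tuple[RegionTimeSeries, int]:
    """Gaussian signals with a known O-information sign.

    ``independent``: i.i.d. standard normals (Omega = 0). ``redundant``: a
    common latent factor with the given loading plus idiosyncratic noise
    (Omega > 0). ``synergistic``: the last variable equals the sum of the
    mutually independent others plus small noise (Omega < 0). Returns the
    series and the sign of the closed-form Omega of the generating covariance.
    """
    if n_vars < 3:
        raise ValueError("need at least 3 variables")
    rng = np.random.default_rng(seed)
    if kind == "independent":
        X = rng.standard_normal((T, n_vars))
        cov = np.eye(n_vars)
    elif kind == "redundant":
        z = rng.standard_normal((T, 1))
        X = loading * z + np.sqrt(1.0 - loading**2) * rng.standard_normal((T, n_vars))
        cov = np.full((n_vars, n_vars), loading**2)
        np.fill_diagonal(cov, 1.0)
    elif kind == "synergistic":
        X = rng.standard_normal((T, n_vars))
        X[:, -1] = X[:, :-1].sum(axis=1) + noise * rng.standard_normal(T)
        cov = np.eye(n_vars)
        cov[-1, :-1] = cov[:-1, -1] = 1.0
        cov[-1, -1] = (n_vars - 1) + noise**2
    else:
        raise ValueError(f"unknown benchmark kind {kind!r}")
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    omega = o_information(CovarianceModel(sigma=corr), list(range(n_vars)))["omega"]
    sign = 0 if abs(omega) < 1e-12 else (1 if omega > 0 else -1)
    ts = RegionTimeSeries(values=X, sampling_period=1.0, kind="gaussian_benchmark")
    return ts, sign
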