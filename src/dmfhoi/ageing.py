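"""Connectome-based ageing model.

A low-degree polynomial f is fitted between the link weights of the young-
group average connectome and those of the old-group average; applying f
element-wise to an individual young connectome yields its "synthetic aged"
counterpart, which is then simulated (DMF at the old group's coupling) and
analysed for higher-order interactions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dmf import DMFParameters, calibrate_fic
from .fit import simulate_bold_run
from .hoi import OInfoTable, oinfo_from_timeseries
from .io import Connectome, RunConfig

__all__ = [
    "AgeingPolynomial",
    "fit_ageing_polynomial",
    "apply_ageing",
    "synthetic_ageing_experiment",
]

logger = logging.getLogger(__name__)


@dataclass
class AgeingPolynomial:
    """w_old = a2 w_young^2 + a1 w_young + a0 (a2 = 0 for the linear variant)."""

    degree: int
    coefficients: tuple[float, float, float]  # (a2, a1, a0)
    fit_r2: float = float("nan")
    n_pairs: int = 0

    def __post_init__(self) -> None:
        if self.degree not in (1, 2):
            raise ValueError("degree must be 1 or 2")
        if not all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")
        if self.degree == 1 and self.coefficients[0] != 0.0:
            raise ValueError("degree-1 polynomial must have a2 = 0")

    def __call__(self, w):
        a2, a1, a0 = self.coefficients
        return a2 * np.asarray(w, dtype=float) ** 2 + a1 * np.asarray(w, dtype=float) + a0

    @classmethod
    def identity(cls) -> "AgeingPolynomial":
        return cls(degree=1, coefficients=(0.0, 1.0, 0.0), fit_r2=1.0)


def fit_ageing_polynomial(
    young_avg: Connectome,
    old_avg: Connectome,
    degree: int = 2,
    include_zeros: bool = True,
) -> AgeingPolynomial:
    """Least-squares fit of old-group weights on young-group weights.

    Fits over the upper-triangle off-diagonal weight pairs (zero-weight links
    included by default). Returns the polynomial plus R^2 and the number of
    pairs used.
    """
    if young_avg.n_regions != old_avg.n_regions:
        raise ValueError("connectome dimensions differ")
    if young_avg.region_labels != old_avg.region_labels:
        raise ValueError("region labels differ between the group averages")
    iu = np.triu_indices(young_avg.n_regions, k=1)
    x = young_avg.weights[iu]
    y = old_avg.weights[iu]
    if not include_zeros:
        keep = (x != 0) | (y != 0)
        x, y = x[keep], y[keep]
    if np.unique(x).size < degree + 2:
        raise ValueError(f"need at least {degree + 2} distinct young weights for degree {degree}")
    coef = np.polyfit(x, y, deg=degree)
    resid = y - np.polyval(coef, x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    if degree == 1:
        coefficients = (0.0, float(coef[0]), float(coef[1]))
    else:
        coefficients = (float(coef[0]), float(coef[1]), float(coef[2]))
    return AgeingPolynomial(degree=degree, coefficients=coefficients, fit_r2=r2, n_pairs=x.size)


def apply_ageing(sc: Connectome, poly: AgeingPolynomial) -> Connectome:
    """Element-wise f(w) on the off-diagonal weights; negatives clamped to 0."""
    w = poly(sc.weights)
    n_clamped = int((w < 0).sum() - (np.diag(w) < 0).sum())
    if n_clamped:
        logger.info("apply_ageing: clamped %d negative predicted weights to 0", n_clamped)
    w = np.maximum(w, 0.0)
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    return Connectome(
        weights=w,
        region_labels=list(sc.region_labels),
        subject_id=f"{sc.subject_id}_aged" if sc.subject_id else "aged",
        age=sc.age,
    )


def synthetic_ageing_experiment(
    cohort_young: list[Connectome],
    poly: AgeingPolynomial,
    g_old: float,
    cfg: RunConfig,
    seed: int = 0,
    runs_per_subject: int = 4,
    dmf_params: DMFParameters | None = None,
) -> list[OInfoTable]:
    """Age each young connectome with ``poly`` and simulate it at ``g_old``.

    For every connectome: apply the ageing polynomial, calibrate FIC at the
    old group's coupling, run ``runs_per_subject`` simulations with distinct
    seeds, and compute one O-information table per run (the full-scale
    default, 28 connectomes x 4 runs, gives 112 simulations).
    """
    if g_old <= 0:
        raise ValueError("g_old must be positive")
    base = dmf_params or DMFParameters()
    tables: list[OInfoTable] = []
    for si, sc in enumerate(cohort_young):
        aged = apply_ageing(sc, poly)
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(si,))
        children = ss.spawn(runs_per_subject + 1)
        fic_seed = int(children[0].generate_state(1)[0]) % (2**31 - 1)
        params = DMFParameters(**{**base.__dict__, "G": g_old})
        J = calibrate_fic(aged, params, seed=fic_seed)
        for ri, child in enumerate(children[1:]):
            run_seed = int(child.generate_state(1)[0]) % (2**31 - 1)
            bold = simulate_bold_run(aged, g_old, J, cfg, run_seed, dmf_params=base)
            table = oinfo_from_timeseries(bold, cfg.order_range)
            table.meta.update({"subject_id": aged.subject_id, "run": ri, "seed": run_seed})
            tables.append(table)
    return tables
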