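"""Reproducible desk-scale study recipes built from the pipeline modules.

Each function wires the package's operations into one of the study's
experiments at sizes that run in minutes on one CPU: FIC validation on a
20-region connectome, global-coupling self-recovery on a 6-region system,
and the synthetic-ageing contrast on a 10-region cohort. All randomness is
driven by a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ageing import AgeingPolynomial, fit_ageing_polynomial, synthetic_ageing_experiment
from .dmf import DMFParameters, calibrate_fic, simulate_dmf
from .fit import GFitResult, fit_global_coupling, pairwise_mi_fc, simulate_bold_run
from .groupstats import GroupComparison, compare_groups_by_order
from .hoi import OInfoTable
from .io import Connectome, RunConfig, group_average_connectome, normalize_sc
from .synthetic import SyntheticCohortSpec, generate_cohort, random_connectome

__all__ = [
    "fic_validation",
    "g_self_recovery",
    "AgeingContrastResult",
    "ageing_contrast",
]


def _sub_seed(seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0]) % (2**31 - 1)


def fic_validation(
    seed: int,
    M: int = 20,
    G: float = 2.0,
    duration: float = 60.0,
    burn_in: float = 10.0,
) -> np.ndarray:
    """Calibrate FIC on a random 20-region connectome and validate the 3 Hz contract.

    Draws a log-normal connectome, rescales it to max weight 0.2, calibrates
    the feedback inhibition at coupling ``G``, then simulates ``duration``
    seconds (noise on) after ``burn_in`` seconds of discarded transient.
    Returns the per-region time-averaged excitatory rates (Hz).
    """
    sc = normalize_sc(random_connectome(M, seed=_sub_seed(seed, 0)), "max_to_cap", 0.2)
    params = DMFParameters(G=G)
    fic = calibrate_fic(sc, params, seed=_sub_seed(seed, 1))
    rates = simulate_dmf(sc, params, fic, duration=burn_in + duration, seed=_sub_seed(seed, 2))
    n_burn = int(round(burn_in / rates.sampling_period))
    return rates.values[n_burn:].mean(axis=0)


def g_self_recovery(
    seed: int,
    g_true: float = 1.6,
    M: int = 6,
    n_runs: int = 8,
    sc_seed: int = 5,
) -> GFitResult:
    """Fit G against a reference the model itself generated at ``g_true``.

    The same 6-region connectome produces the reference FC sample (``n_runs``
    runs at ``g_true``) and is then fitted over the full grid 1.0..3.0 in 0.1
    steps with ``n_runs`` simulations per G.
    """
    sc = normalize_sc(random_connectome(M, seed=sc_seed), "strength_to_cap", 0.45)
    cfg = RunConfig(M=M, n_runs_per_G=n_runs, order_range=(3, M))
    params = DMFParameters(G=g_true)
    fic = calibrate_fic(sc, params, seed=_sub_seed(seed, 0))
    reference = np.concatenate(
        [
            pairwise_mi_fc(
                simulate_bold_run(sc, g_true, fic, cfg, seed=_sub_seed(seed, 1, i))
            ).upper_values()
            for i in range(n_runs)
        ]
    )
    return fit_global_coupling(sc, reference, cfg, seed=_sub_seed(seed, 2))


@dataclass
class AgeingContrastResult:
    """Outcome of the desk-scale synthetic-ageing contrast."""

    aged_vs_young_redundancy: GroupComparison
    aged_vs_young_synergy: GroupComparison
    control_vs_young_redundancy: GroupComparison
    control_vs_young_synergy: GroupComparison
    poly: AgeingPolynomial
    tables_young: list[OInfoTable]
    tables_aged: list[OInfoTable]

    def redundancy_gap_by_order(self) -> dict[int, float]:
        """Mean aged-minus-young grand-average redundancy per order."""
        import pandas as pd

        ga = lambda tabs: pd.concat([t.grand_averages() for t in tabs]).groupby("order")["R"].mean()
        gap = ga(self.tables_aged) - ga(self.tables_young)
        return {int(k): float(v) for k, v in gap.items()}


def ageing_contrast(
    seed: int,
    M: int = 10,
    group_sizes: dict[str, int] | None = None,
    g_young: float = 1.6,
    g_old: float = 2.8,
    runs_per_subject: int = 4,
    cap_strength: float = 0.45,
) -> AgeingContrastResult:
    """Quadratic synthetic ageing versus the identity (no-ageing) control.

    Generates an age-graded cohort, rescales every connectome by the single
    factor that brings the young-group average to max node strength
    ``cap_strength``, fits the degree-2 ageing polynomial between the young
    and old group averages, then simulates three arms over the young
    connectomes: aged (polynomial applied, coupling ``g_old``), young
    baseline (identity, ``g_young``) and control (identity, ``g_young``,
    fresh seeds). The aged group's coupling follows the old group's fitted
    value; the young arm uses a lower coupling, as the fitted group couplings
    rise with age.
    """
    spec = SyntheticCohortSpec(
        M=M,
        group_sizes=group_sizes or {"I1": 6, "I2": 2, "I3": 2, "I4": 6},
        seed=_sub_seed(seed, 0),
    )
    cohort, _ = generate_cohort(spec)
    young_avg = group_average_connectome(cohort, "I1")
    factor = cap_strength / young_avg.strength().max()

    def scaled(c: Connectome) -> Connectome:
        return Connectome(c.weights * factor, list(c.region_labels), c.subject_id, c.age)

    poly = fit_ageing_polynomial(
        scaled(young_avg), scaled(group_average_connectome(cohort, "I4")), degree=2
    )
    young = [scaled(c) for c in cohort.subjects("I1")]
    cfg = RunConfig(M=M, order_range=(3, M))
    identity = AgeingPolynomial.identity()
    tables_aged = synthetic_ageing_experiment(
        young, poly, g_old=g_old, cfg=cfg, seed=_sub_seed(seed, 1), runs_per_subject=runs_per_subject
    )
    tables_young = synthetic_ageing_experiment(
        young, identity, g_old=g_young, cfg=cfg, seed=_sub_seed(seed, 2), runs_per_subject=runs_per_subject
    )
    tables_ctrl = synthetic_ageing_experiment(
        young, identity, g_old=g_young, cfg=cfg, seed=_sub_seed(seed, 3), runs_per_subject=runs_per_subject
    )
    return AgeingContrastResult(
        aged_vs_young_redundancy=compare_groups_by_order(tables_aged, tables_young, "redundancy"),
        aged_vs_young_synergy=compare_groups_by_order(tables_aged, tables_young, "synergy"),
        control_vs_young_redundancy=compare_groups_by_order(tables_ctrl, tables_young, "redundancy"),
        control_vs_young_synergy=compare_groups_by_order(tables_ctrl, tables_young, "synergy"),
        poly=poly,
        tables_young=tables_young,
        tables_aged=tables_aged,
    )
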