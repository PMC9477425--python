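# dmfhoi

Whole-brain dynamic mean-field (DMF) simulation and higher-order
(redundancy/synergy) interaction analysis of connectome ageing.

## The problem

Structural connectomes degenerate with age: white-matter link weights
decline, heterogeneously across the brain. `dmfhoi` asks the mechanistic
question of how that degeneration reshapes the *high-order* statistical
structure of brain activity — interactions among triplets and larger
n-plets of regions, split into redundancy- and synergy-dominated sets —
rather than only pairwise functional connectivity. It is written for
computational neuroscientists who want a tested, scriptable pipeline that
runs end to end on synthetic cohorts with planted ground truth.

The pipeline:

1. **DMF simulation** (`dmfhoi.dmf`): per region, coupled excitatory
   (NMDA) / inhibitory (GABA) populations with gating dynamics
   dS_E/dt = −S_E/τ_NMDA + (1 − S_E) γ r_E + σv(t), wired by the structural
   connectome C scaled by a global coupling G; feedback inhibition control
   (FIC) calibrates each region's inhibitory weight J_n so excitatory pools
   fire near 3 Hz.
2. **Haemodynamics** (`dmfhoi.hemo`): the balloon model maps rates to
   BOLD via B = V0[k1(1 − q) + k2(1 − q/v) + k3(1 − v)], band-pass filtered
   0.01–0.1 Hz (zero-phase 3rd-order Bessel) and sampled at TR = 3 s
   (160 points = 8 min).
3. **FC and G fitting** (`dmfhoi.fit`): Gaussian-copula mutual information
   MI = −½ln(1 − ρ²) between region pairs; G selected on a 1.0–3.0 grid by
   minimizing the Kolmogorov–Smirnov distance between simulated and
   reference FC-value distributions.
4. **O-information** (`dmfhoi.hoi`): for every n-plet (3 ≤ n ≤ M),
   Ω = TC − DTC from memoized Gaussian-copula subset entropies; per-region,
   per-order redundancy R (mean positive Ω) and synergy S (mean |negative
   Ω|) with grand averages.
5. **Connectome ageing** (`dmfhoi.ageing`): a degree-2 polynomial fitted
   between young-group and old-group average weights, applied element-wise
   to young connectomes to synthesize aged ones, which are re-simulated at
   the old group's coupling.
6. **Link communities** (`dmfhoi.communities`): Spearman correlation of
   each link weight with age across a cohort, Louvain communities on |r|,
   Bonferroni pruning, and partition stability across the resolution γ.
7. **Group statistics** (`dmfhoi.groupstats`): Wilcoxon rank-sum per
   interaction order with Benjamini–Hochberg FDR.
8. **Synthetic cohorts** (`dmfhoi.synthetic`): age-graded connectome
   cohorts with a planted quadratic ageing law, planted link communities
   with per-community degeneration rates, and Gaussian benchmark signals of
   known Ω sign.

See `docs/methods.md` for the models, estimators, defaults and limitations.

## Worked example

Calibrate FIC on a synthetic 20-region connectome and verify the 3 Hz
working point:

```python
import numpy as np
from dmfhoi.dmf import DMFParameters, calibrate_fic, simulate_dmf
from dmfhoi.io import normalize_sc
from dmfhoi.synthetic import random_connectome

sc = normalize_sc(random_connectome(20, seed=1), "max_to_cap", 0.2)
params = DMFParameters(G=2.0)
fic = calibrate_fic(sc, params, seed=1)
rates = simulate_dmf(sc, params, fic, duration=70.0, seed=2)
node_rates = rates.values[10_000:].mean(axis=0)   # drop 10 s burn-in
print(f"mean rate {node_rates.mean():.3f} Hz, "
      f"range [{node_rates.min():.2f}, {node_rates.max():.2f}] Hz")
```

```
mean rate 2.958 Hz, range [2.83, 3.01] Hz
```

Every excitatory population sits near the 3 Hz spontaneous working point —
the FIC contract that makes simulations comparable across connectomes and
couplings.

Run the desk-scale synthetic-ageing contrast (10 regions, 6 young subjects,
4 runs per connectome; the aged arm uses the old group's coupling G = 2.8):

```python
from dmfhoi.experiments import ageing_contrast

res = ageing_contrast(seed=0)
print("orders with FDR-significant redundancy increase:",
      res.aged_vs_young_redundancy.significant_orders())
print("identity control:",
      res.control_vs_young_redundancy.significant_orders())
```

```
orders with FDR-significant redundancy increase: [3, 4, 5, 6, 7, 8, 9, 10]
identity control: []
```

Ageing the connectomes quadratically and simulating them at the old group's
coupling raises grand-average redundancy at every interaction order, while
the no-ageing control shows no significant order — the package's desk-scale
replication of the study's central mechanistic result.

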