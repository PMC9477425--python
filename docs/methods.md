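# Methods

`dmfhoi` implements a mechanistic pipeline for asking how structural
connectome degeneration reshapes high-order (redundant vs. synergistic)
functional interactions between brain regions. This note documents the
models, the estimators, the synthetic data the package is exercised on, and
the numerical choices that were genuinely open.

## Whole-brain dynamic mean-field model

Each of the M regions holds an excitatory (NMDA) and an inhibitory (GABA)
population, coupled through the structural connectome C scaled by a global
coupling G:

    I_E,n = W_E I0 + w+ J_NMDA S_E,n + G J_NMDA Σ_p C_np S_E,p − J_n S_I,n
    I_I,n = W_I I0 + J_NMDA S_E,n − S_I,n
    r_X,n = F_X(I_X,n) = g_X (I − I_thr,X) / (1 − exp(−d_X g_X (I − I_thr,X)))
    dS_E,n/dt = −S_E,n/τ_NMDA + (1 − S_E,n) γ r_E,n + σ v_n(t)
    dS_I,n/dt = −S_I,n/τ_GABA + r_I,n + σ v_n(t)

with the standard parameter set (I0 = 0.382 nA, W_E = 1, W_I = 0.7,
w+ = 1.4, J_NMDA = 0.15 nA, thresholds 0.403/0.288 nA, gains 310/615 nC⁻¹,
shapes 0.16/0.087 s, γ = 0.641, σ = 0.01 nA, τ_NMDA = 100 ms,
τ_GABA = 10 ms). Integration is Euler–Maruyama at dt = 1 ms with independent
Gaussian increments σ√dt per population, per region, per step; gating is
clipped to [0, 1] after every step. The noise generator is a seeded
Mersenne–Twister inside the compiled kernel, so a seed fully determines a
trajectory on every platform.

### Feedback inhibition control (FIC)

The per-region inhibitory weight J_n is calibrated so each excitatory
population fires near the 3 Hz spontaneous working point regardless of its
connectivity. J is seeded linearly from node strength
(J_n = 0.75 G strength_n + 1) and then corrected iteratively over repeated
10 s noise-on runs, J_n ← J_n + η (r̄_n − 3 Hz), with η = 0.005 nA/Hz, rate
errors clipped at ±10 Hz, and a per-region sign-flip damping of the step
(halved when the error changes sign). The damping matters: near its bistable
regime the network's rate-vs-J curve is extremely steep (≈ −100 Hz/nA at
G = 2), and a fixed step either oscillates across the jump or crawls.
Convergence requires every region within 3 ± 0.5 Hz and the region mean
within ±0.05 Hz of target (the contract checked downstream is ±0.2 Hz on the
mean over a separate 60 s validation run).

### Connectome scale and the stable coupling regime

The model's behaviour is governed by the product of G and node strength
(row sum of C). Empirically (scanned during development, at M = 6–20), the
FIC-stabilized 3 Hz state destabilizes — escaping to a saturated
high-activity attractor — once G × max-strength exceeds roughly 1.4. Since
connectome weights arrive in arbitrary streamline-count-like units, the
package offers two normalizations:

* `max_to_cap` (largest weight → 0.2): the common DMF convention, used for
  single-connectome simulations;
* `strength_to_cap` (largest node strength → 0.45): pins the dynamically
  relevant quantity, guaranteeing the whole G ∈ [1, 3] fitting grid stays in
  the stable regime. Cohort experiments apply one global factor derived from
  the young-group average, so all subjects (and their synthetic aged
  versions) share a scale, as streamline counts do.

The standalone synthetic connectome generator draws log-normal weights with
log-sd 1.5, emulating the orders-of-magnitude spread of empirical streamline
counts; heavy tails also mean max-normalization leaves node strengths well
below the cap.

## Haemodynamics and BOLD

Excitatory rates drive a balloon model per region: a vasodilatory signal s
(ds/dt = 0.5 r + 3 − κs − γ_f(f − 1)), inflow f (df/dt = s), venous volume v
(τ dv/dt = f − v^{1/α}) and deoxyhemoglobin q
(τ dq/dt = f(1 − (1−ρ)^{1/f})/ρ − q v^{1/α}/v), with readout
B = V0 [k1(1 − q) + k2(1 − q/v) + k3(1 − v)], k1 = 2.77, k2 = 0.2, k3 = 0.5.
The remaining balloon constants are not free choices of this package's
experiments; the defaults are the standard set κ = 0.65 s⁻¹, γ_f = 0.41 s⁻¹,
τ = 0.98 s, α = 0.32, ρ = 0.34, V0 = 0.04, all config-overridable and
recorded in run manifests.

Integration is Euler at 1 ms, initialized at the closed-form fixed point of
the initial rate (s = 0, f = 1 + (0.5r + 3)/γ_f, v = f^α, q from the oxygen
balance), so transients are small; 20 s are still discarded before sampling.
The readout is block-averaged to a 1 s grid, band-pass filtered at
0.01–0.1 Hz with a zero-phase (forward–backward) 3rd-order Bessel filter,
and sampled every TR (default 3 s, 160 points = 8 minutes). Filtering on the
1 s grid rather than at 1 kHz is deliberate: a digital Bessel band-pass with
edges at 10⁻⁵ of the sampling rate is numerically ill-conditioned, while the
balloon output has no appreciable energy above 0.5 Hz. Zero-phase
application avoids lag distortion of FC; note it squares the magnitude
response, so the mid-band gain is ≈ 0.88 rather than the single-pass ≈ 0.94.

## Functional connectivity and G fitting

FC between two regions is the Gaussian-copula mutual information: each
series is rank-transformed to normal scores ((rank − ½)/T → Φ⁻¹), and
MI = −½ ln(1 − ρ²) nats with ρ the Pearson correlation of the scores. This
estimator is invariant to monotone marginal transforms and needs no binning.

The global coupling is selected on the grid G = 1.0, 1.1, …, 3.0 by
minimizing the two-sample Kolmogorov–Smirnov distance between the pooled
simulated FC values (upper-triangle entries, pooled across runs; 112 runs
per G at full scale, fewer at desk scale) and a reference FC-value sample.
Pooling across runs/subjects rather than averaging FC matrices first
maximizes sample size and matches the group-level framing. Ties break toward
smaller G; a G value where FIC fails or most runs diverge is marked invalid
(NaN) rather than aborting the sweep.

## O-information across interaction orders

For an n-plet X of region signals, with H(·) the Shannon entropy:

    TC(X)  = Σᵢ H(Xᵢ) − H(X)
    DTC(X) = H(X) − Σᵢ H(Xᵢ | X₋ᵢ)
    Ω(X)   = TC(X) − DTC(X)

Ω > 0 marks redundancy-dominated n-plets, Ω < 0 synergy-dominated ones.
Entropies are parametric Gaussian-copula estimates — every subset entropy is
½ ln((2πe)^k det Σ_sub) for a submatrix of the copula correlation matrix —
with no small-sample bias correction. The enumeration over all n-plets
(3 ≤ n ≤ M) memoizes subset entropies by bitmask so each is computed once;
Ω per subset uses the reduced identity
Ω = (n − 2)H(X) + Σᵢ [h(Xᵢ) − H(X₋ᵢ)]. A ridge of 1e-10·I is added when the
correlation matrix's smallest eigenvalue falls below 1e-10 (logged); the
enumeration is guarded at M ≤ 25.

Per region m and order n, the package reports the mean Ω over the
C(M−1, n−1) n-plets containing m, the redundancy R (mean of positive Ω) and
synergy S (mean of |negative Ω|) over those n-plets (0, flagged, when no
n-plet of that sign exists), and grand averages over regions per order.
Exact-zero Ω counts in neither split.

## Connectome-ageing model

A degree-2 polynomial f is least-squares fitted between the upper-triangle
weights of the young-group average connectome and the old-group average
(all pairs including zeros by default; a flag excludes zeros). Applying f
element-wise to an individual young connectome — negatives clamped to 0,
symmetry and zero diagonal preserved — yields its synthetic aged version,
which is then simulated at the old group's coupling (4 runs per connectome
at full scale). The degree-1 variant serves as the control ageing model.

## Age-related link communities

Across a cohort, each link weight is Spearman-correlated with age (average
ranks under ties; exact permutation p-values below N = 10, t-approximation
otherwise; constant links are recorded as undefined and excluded). Louvain
community detection runs on the matrix of |r| values before any pruning
(best of 100 restarts on a deterministic seed ladder, maximal modularity at
resolution γ); non-significant links are then pruned by Bonferroni over the
M(M−1)/2 link tests. Stability across γ is reported both as the rank
correlation between label vectors (the partition-integrity coefficient as
defined) and as the adjusted Rand index; the ARI is the recommended gate
because label-id correlation is not invariant to community relabelling.

## Group statistics

Redundancy and synergy are compared between groups per interaction order
with a two-sided Wilcoxon rank-sum test on per-run grand averages (exact
enumeration of the permutation distribution for pooled sizes ≤ 12, which is
also valid under ties; tie-corrected normal approximation otherwise), with
Benjamini–Hochberg FDR across the orders of each measure separately. The
run-level sampling unit and the per-measure FDR family are documented
decisions; region-level units are available for region-resolved analyses.

## Synthetic cohort generator

The generator plants everything the analyses estimate. A base (young)
connectome has truncated log-normal weights (median 50, log-sd 0.8,
truncated at the 99th percentile so the planted ageing law stays feasible).
Subject weights follow

    w_ij(age) = base_ij · (1 − s_ij φ(age)) · noise_ij,
    φ(age) = ((age − 10)/70)²,

with multiplicative log-normal link noise (cv = 0.3) and per-link slopes
s_ij = rate_ij (1 − f(base_ij)/base_ij) / E[φ | 60–80], so that at
degeneration rate 1 the expected old-group mean of every link equals
f(base_ij) for the planted quadratic f (defaults a2 = −0.0015, a1 = 0.9,
a0 = 0). Regions are partitioned into planted communities with
per-community rates (a rate-0 community yields age-flat links); ages are
uniform within each group band (I1: 10–20, I2: 20–40, I3: 40–60, I4: 60–80),
with group sizes defaulting to 28/46/29/58. Quadratic decline in age makes
the young→old group-mean map itself quadratic in w.

Two generator constants were calibrated once, at design time, against the
study's stated structure and then frozen: cv = 0.3 places the link-age
Spearman correlation of fully degenerating links around −0.3 (band −0.25 to
−0.5), and the truncation keeps the law feasible on every draw. The noise is
i.i.d. across links and subjects; real tractography noise is spatially
correlated and heteroscedastic, ages are not uniform in empirical cohorts,
and real degeneration need not be quadratic in age — passing tests therefore
demonstrate internal consistency of the pipeline and recoverability of
planted structure, not properties of any empirical population.

Recovery of the planted ageing coefficients from the group averages is
assessed on the mean estimate across 20 generator seeds: a single cohort's
estimate carries irreducible sampling error (the old group's 58 drawn ages
alone perturb the fitted curvature by a few percent), so the bias of the
estimator, not its per-cohort scatter, is the meaningful 5% check.

The Gaussian benchmark signals (common-factor "redundant", sum-variable
"synergistic", i.i.d. "independent") come with the closed-form Ω sign of
their generating covariance and calibrate the estimator's sign decisions.

## Desk-scale experiment sizes

The bundled experiments are scaled so the whole suite runs on one CPU in
minutes, as the package's own reproducibility choice: FIC validation at
M = 20 (G = 2, 60 s validation run); G self-recovery at M = 6 (reference
generated at G = 1.6, 8 runs per G over the full 21-point grid, 5 seeds);
the ageing contrast at M = 10 (6 young + 6 old subjects, 4 runs per
connectome, orders 3–10). In the ageing contrast the young arm runs at
G = 1.6 and the aged arm at G = 2.8 — the old group's fitted coupling at
full scale — reflecting that fitted group couplings rise with age; the
contrast therefore combines connectome weakening with the higher coupling,
exactly as the full-scale synthetic-ageing experiment does. The identity
control (same connectomes, same coupling, fresh seeds) isolates the null.

## Known limitations

* No subject-level G fitting and no fitting of higher-order statistics; the
  KS target is the pairwise FC distribution only.
* The Gaussian-copula entropy family cannot express all non-Gaussian
  dependence; Ω estimates are exact only for the copula-Gaussian part.
* Louvain is a greedy heuristic; best-of-restarts modularity is
  non-decreasing in restarts but global optimality is not guaranteed.
* The DMF operating regime depends on the (unknown) empirical connectome
  scale; conclusions about G values transfer only up to that scale choice.
* No PID/Φ-ID decomposition and no redundancy-core analysis.
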