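import itertools

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from dmfhoi.communities import (
    bonferroni_prune,
    link_age_correlation,
    louvain_link_communities,
    node_strength,
    partition_stability,
    spearman_exact,
)
from dmfhoi.io import Cohort, Connectome
from dmfhoi.synthetic import SyntheticCohortSpec, generate_cohort


def planted_block_matrix(sizes, within, between, rng=None, jitter=0.0):
    M = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    A = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    if jitter and rng is not None:
        noise = rng.uniform(-jitter, jitter, (M, M))
        A = A + 0.5 * (noise + noise.T)
    np.fill_diagonal(A, 0.0)
    return np.abs(A), labels


def _cohort_from_weights(weight_fn, ages_groups):
    subs, groups, ages = [], {}, {}
    for i, (age, grp) in enumerate(ages_groups):
        sid = f"s{i}"
        w = weight_fn(age)
        subs.append(Connectome(w, [f"R{j}" for j in range(w.shape[0])], subject_id=sid, age=age))
        groups[sid] = grp
        ages[sid] = age
    return Cohort(subs, groups, ages)


class TestSpearman:
    def test_exact_matches_enumeration_n5(self, rng):
        x = rng.standard_normal(5)
        y = rng.standard_normal(5)
        rho, p = spearman_exact(x, y)
        # independent oracle: rank-then-Pearson over all 5! permutations
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        rho_oracle = stats.pearsonr(rx, ry).statistic
        count = sum(
            abs(stats.pearsonr(rx, ry[list(perm)]).statistic) >= abs(rho_oracle) - 1e-12
            for perm in itertools.permutations(range(5))
        )
        assert rho == pytest.approx(rho_oracle, abs=1e-12)
        assert p == pytest.approx(count / 120, abs=1e-12)

    def test_matches_scipy_with_ties(self, rng):
        x = np.round(rng.standard_normal(30), 1)  # induces ties
        y = np.round(rng.standard_normal(30), 1)
        rho, _ = spearman_exact(x[:8], y[:8])
        assert rho == pytest.approx(stats.spearmanr(x[:8], y[:8]).statistic, abs=1e-12)


class TestLinkAgeCorrelation:
    def test_perfect_monotone_decline(self):
        def weights(age):
            w = np.zeros((4, 4))
            w[0, 1] = w[1, 0] = 100.0 - age
            w[2, 3] = w[3, 2] = 10.0
            return w

        pairs = [(12.0, "I1"), (25.0, "I2"), (45.0, "I3"), (55.0, "I3"), (70.0, "I4"), (75.0, "I4")]
        cohort = _cohort_from_weights(weights, pairs)
        corr = link_age_correlation(cohort)
        assert corr.r[0, 1] == pytest.approx(-1.0)
        assert corr.p[0, 1] == pytest.approx(2 / 720, abs=1e-9)  # two one-sided extremes of 6!
        assert np.isnan(corr.r[2, 3])  # constant link is undefined
        assert corr.abs_r[2, 3] == 0.0  # and excluded from the graph

    def test_permutation_null_has_small_mean_abs_r(self, rng):
        """Ages shuffled against weights carry no systematic link-age trend."""
        mean_abs = []
        for seed in range(20):
            g = np.random.default_rng(seed)
            ages = g.uniform(10, 80, 50)
            base = g.lognormal(3, 0.5, (6, 6))
            base = np.triu(base, 1) + np.triu(base, 1).T

            def weights(age):
                noise = g.lognormal(0, 0.3, (6, 6))
                noise = np.triu(noise, 1) + np.triu(noise, 1).T
                return base * noise

            groups = ["I1" if a < 20 else "I2" if a < 40 else "I3" if a < 60 else "I4" for a in ages]
            cohort = _cohort_from_weights(weights, list(zip(ages, groups)))
            corr = link_age_correlation(cohort)
            mean_abs.append(np.nanmean(np.abs(corr.r[np.triu_indices(6, 1)])))
        assert np.mean(mean_abs) < 0.15

    def test_cohort_generator_planted_trend(self):
        """Noiseless degenerating links correlate perfectly (negatively) with age."""
        spec = SyntheticCohortSpec(
            M=6,
            group_sizes={"I1": 3, "I2": 3, "I3": 3, "I4": 3},
            link_noise_cv=0.0,
            planted_communities=[[0, 1, 2], [3, 4, 5]],
            community_rates=(1.0, 0.0),
            seed=7,
        )
        cohort, _ = generate_cohort(spec)
        corr = link_age_correlation(cohort)
        assert corr.r[0, 1] == pytest.approx(-1.0)
        assert corr.r[0, 2] == pytest.approx(-1.0)
        # zero-rate community: no trend at all without noise
        assert abs(corr.r[3, 4]) < 1e-9 or np.isnan(corr.r[3, 4])


class TestLouvain:
    def test_two_cliques_recovered(self):
        A, labels = planted_block_matrix([5, 5], within=0.5, between=0.0)
        res = louvain_link_communities(A, gamma=1.0, seed=0, n_restarts=10)
        assert adjusted_rand_score(labels, res.labels) == 1.0
        assert len(set(res.labels)) == 2

    def test_modularity_beats_trivial_partition(self, rng):
        A, _ = planted_block_matrix([4, 4, 4], 0.4, 0.05, rng=rng, jitter=0.02)
        res = louvain_link_communities(A, gamma=1.0, seed=1, n_restarts=10)
        assert res.modularity >= 0.0  # all-in-one partition has modularity 0

    def test_three_planted_blocks_across_seeds(self, rng):
        for seed in range(10):
            g = np.random.default_rng(seed)
            A, labels = planted_block_matrix([7, 7, 6], 0.4, 0.05, rng=g, jitter=0.03)
            res = louvain_link_communities(A, gamma=1.0, seed=seed, n_restarts=25)
            assert adjusted_rand_score(labels, res.labels) == 1.0

    def test_reproducible_given_seed(self, rng):
        A, _ = planted_block_matrix([5, 5, 5], 0.4, 0.1, rng=rng, jitter=0.05)
        a = louvain_link_communities(A, gamma=1.0, seed=3, n_restarts=10)
        b = louvain_link_communities(A, gamma=1.0, seed=3, n_restarts=10)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.modularity == b.modularity

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            louvain_link_communities(np.zeros((4, 4)), seed=0, n_restarts=2)


class TestBonferroni:
    def test_threshold_value_at_m20(self):
        M = 20
        alpha = 0.05
        assert alpha / (M * (M - 1) // 2) == pytest.approx(2.6315789e-4, rel=1e-6)

    def test_toy_pruning(self):
        M = 20
        p = np.ones((M, M))
        p[0, 1] = p[1, 0] = 1e-6   # survives 0.05/190
        p[0, 2] = p[2, 0] = 1e-3   # does not
        p[0, 3] = p[3, 0] = 0.2
        r = np.zeros((M, M))
        from dmfhoi.communities import LinkAgeCorrelation

        corr = LinkAgeCorrelation(r=r, p=p, n_subjects=50)
        mask = bonferroni_prune(corr, alpha=0.05)
        assert mask.sum() == 2  # one link, mirrored
        assert mask[0, 1] and mask[1, 0]

    def test_all_ones_empty_mask(self):
        from dmfhoi.communities import LinkAgeCorrelation

        corr = LinkAgeCorrelation(r=np.zeros((5, 5)), p=np.ones((5, 5)), n_subjects=30)
        assert bonferroni_prune(corr).sum() == 0

    def test_pruning_does_not_touch_labels(self, rng):
        """Detection runs pre-pruning: the mask never alters the partition."""
        A, labels = planted_block_matrix([5, 5], 0.5, 0.0)
        before = louvain_link_communities(A, seed=0, n_restarts=5).labels
        from dmfhoi.communities import LinkAgeCorrelation

        corr = LinkAgeCorrelation(r=A, p=np.full(A.shape, 0.5), n_subjects=30)
        bonferroni_prune(corr)
        after = louvain_link_communities(A, seed=0, n_restarts=5).labels
        np.testing.assert_array_equal(before, after)


class TestPartitionStability:
    def test_self_comparison_is_one(self, rng):
        A, _ = planted_block_matrix([5, 5], 0.5, 0.05, rng=rng, jitter=0.02)
        profile = partition_stability(A, gamma_grid=(1.0,), seed=0, n_restarts=10)
        assert profile[1.0]["ari"] == 1.0
        assert profile[1.0]["label_spearman"] == pytest.approx(1.0)

    def test_planted_blocks_stable_over_gamma(self, rng):
        A, labels = planted_block_matrix([7, 7, 6], 0.4, 0.05, rng=rng, jitter=0.03)
        profile = partition_stability(
            A, gamma_grid=(0.9, 1.0, 1.1, 1.2), seed=0, n_restarts=25
        )
        for g in (0.9, 1.0, 1.1, 1.2):
            assert profile[g]["ari"] == 1.0

    def test_ari_invariant_to_relabeling(self):
        a = np.array([1, 1, 2, 2, 3, 3])
        b = np.array([3, 3, 1, 1, 2, 2])  # same partition, permuted ids
        assert adjusted_rand_score(a, b) == 1.0
        assert stats.spearmanr(a, b).statistic != 1.0  # why ARI is the gate

    def test_grid_must_contain_reference(self, rng):
        A, _ = planted_block_matrix([4, 4], 0.5, 0.0)
        with pytest.raises(ValueError):
            partition_stability(A, gamma_grid=(0.9, 1.1), seed=0)


class TestNodeStrength:
    def test_zero_matrix(self):
        np.testing.assert_array_equal(node_strength(np.zeros((4, 4))), np.zeros(4))

    def test_single_link(self):
        A = np.zeros((4, 4))
        A[1, 2] = A[2, 1] = 0.3
        s = node_strength(A)
        np.testing.assert_allclose(s, [0.0, 0.3, 0.3, 0.0])

    def test_handshake_identity(self, rng):
        A, _ = planted_block_matrix([4, 4], 0.5, 0.1, rng=rng, jitter=0.02)
        assert node_strength(A).sum() == pytest.approx(2.0 * np.triu(A, 1).sum())
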