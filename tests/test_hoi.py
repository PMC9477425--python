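import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmfhoi.fit import copula_normalize
from dmfhoi.hoi import (
    CovarianceModel,
    enumerate_oinfo,
    gaussian_entropy,
    o_information,
    oinfo_from_timeseries,
    redundancy_synergy,
)
from dmfhoi.io import RegionTimeSeries

LOG_2PIE = np.log(2 * np.pi * np.e)


def random_correlation(n, rng):
    A = rng.standard_normal((n, n + 3))
    C = np.corrcoef(A)
    return C


class TestGaussianEntropy:
    def test_univariate_standard_normal(self):
        assert gaussian_entropy(np.array([[1.0]])) == pytest.approx(0.5 * LOG_2PIE, rel=1e-12)
        assert gaussian_entropy(np.array([[1.0]])) == pytest.approx(1.41894, abs=1e-5)

    def test_additivity_for_block_diagonal(self, rng):
        a = random_correlation(2, rng)
        b = random_correlation(3, rng)
        block = np.block([[a, np.zeros((2, 3))], [np.zeros((3, 2)), b]])
        assert gaussian_entropy(block) == pytest.approx(
            gaussian_entropy(a) + gaussian_entropy(b), rel=1e-12
        )

    def test_variance_scaling_law(self):
        s = np.eye(3)
        s2 = s.copy()
        s2[0, 0] = 4.0
        assert gaussian_entropy(s2) - gaussian_entropy(s) == pytest.approx(0.5 * np.log(4))

    def test_rank_deficiency_rejected(self):
        s = np.ones((3, 3))
        with pytest.raises(ValueError):
            gaussian_entropy(s)


class TestOInformation:
    def test_independent_variables_zero(self):
        cov = CovarianceModel(sigma=np.eye(4))
        out = o_information(cov, [0, 1, 2])
        for key in ("tc", "dtc", "omega"):
            assert out[key] == pytest.approx(0.0, abs=1e-12)

    def test_common_cause_triple_is_redundant(self):
        # equicorrelated triple: shared-source structure
        s = np.full((3, 3), 0.7)
        np.fill_diagonal(s, 1.0)
        assert o_information(CovarianceModel(sigma=s), [0, 1, 2])["omega"] > 0

    def test_sum_triple_is_synergistic(self):
        # X3 = X1 + X2 + small noise, X1 independent of X2
        eta2 = 0.01
        s = np.array(
            [
                [1.0, 0.0, 1.0],
                [0.0, 1.0, 1.0],
                [1.0, 1.0, 2.0 + eta2],
            ]
        )
        assert o_information(CovarianceModel(sigma=s), [0, 1, 2])["omega"] < 0

    def test_order_three_equals_interaction_information(self, rng):
        """For n=3, omega must equal the inclusion-exclusion interaction information."""
        C = random_correlation(5, rng)
        cov = CovarianceModel(sigma=C)
        idx = [0, 2, 4]
        sub = C[np.ix_(idx, idx)]
        h = gaussian_entropy
        ii = (
            h(sub[:1, :1]) + h(sub[1:2, 1:2]) + h(sub[2:, 2:])
            - h(sub[:2, :2]) - h(sub[np.ix_([0, 2], [0, 2])]) - h(sub[1:, 1:])
            + h(sub)
        )
        assert o_information(cov, idx)["omega"] == pytest.approx(ii, abs=1e-9)

    def test_appending_independent_variable_preserves_omega(self, rng):
        C = random_correlation(4, rng)
        big = np.eye(5)
        big[:4, :4] = C
        om_small = o_information(CovarianceModel(sigma=C), [0, 1, 2, 3])["omega"]
        om_big = o_information(CovarianceModel(sigma=big), [0, 1, 2, 3])["omega"]
        assert om_big == pytest.approx(om_small, abs=1e-10)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000), st.integers(min_value=3, max_value=6))
    def test_tc_dtc_nonnegative_property(self, seed, n):
        """TC and DTC are non-negative generalizations of mutual information."""
        rng = np.random.default_rng(seed)
        C = random_correlation(n, rng)
        out = o_information(CovarianceModel(sigma=C), list(range(n)))
        assert out["tc"] >= -1e-9
        assert out["dtc"] >= -1e-9

    def test_invalid_subsets_rejected(self):
        cov = CovarianceModel(sigma=np.eye(5))
        with pytest.raises(ValueError):
            o_information(cov, [0, 1])
        with pytest.raises(ValueError):
            o_information(cov, [0, 1, 1])


class TestEnumerateOInfo:
    def test_zn_combinatorics(self):
        cov = CovarianceModel(sigma=np.eye(20))
        table = enumerate_oinfo(cov, (3, 4))
        assert table.z_n(3) == comb(19, 2) == 171

    def test_full_order_single_subset(self, rng):
        C = random_correlation(5, rng)
        table = enumerate_oinfo(CovarianceModel(sigma=C), (5, 5))
        omegas = table.regions.query("order == 5")["omega_mean"]
        np.testing.assert_allclose(omegas, omegas.iloc[0])

    def test_matches_naive_brute_force_at_m6(self, rng):
        C = random_correlation(6, rng)
        cov = CovarianceModel(sigma=C)
        table = redundancy_synergy(enumerate_oinfo(cov, (3, 6)))
        for n in range(3, 7):
            z = comb(5, n - 1)
            for m in range(6):
                oms = np.array(
                    [
                        o_information(cov, list(s))["omega"]
                        for s in itertools.combinations(range(6), n)
                        if m in s
                    ]
                )
                row = table.regions.query("region == @m and order == @n").iloc[0]
                assert len(oms) == z
                assert row.omega_mean == pytest.approx(oms.mean(), abs=1e-12)
                pos, neg = oms[oms > 0], -oms[oms < 0]
                assert row.R == pytest.approx(pos.mean() if pos.size else 0.0, abs=1e-12)
                assert row.S == pytest.approx(neg.mean() if neg.size else 0.0, abs=1e-12)

    def test_guard_rails(self):
        cov = CovarianceModel(sigma=np.eye(5))
        with pytest.raises(ValueError):
            enumerate_oinfo(cov, (2, 5))
        with pytest.raises(ValueError):
            enumerate_oinfo(cov, (3, 6))


class TestRedundancySynergy:
    def test_split_identity(self, rng):
        """omega = omega+ - omega- must hold for the per-region sums."""
        C = random_correlation(5, rng)
        table = redundancy_synergy(enumerate_oinfo(CovarianceModel(sigma=C), (3, 5)))
        df = table.regions
        np.testing.assert_allclose(
            df["omega_mean"] * [table.z_n(n) for n in df["order"]],
            df["sum_pos"] - df["sum_neg"],
            atol=1e-10,
        )

    def test_all_redundant_system_has_zero_synergy(self):
        s = np.full((4, 4), 0.8)
        np.fill_diagonal(s, 1.0)
        table = redundancy_synergy(enumerate_oinfo(CovarianceModel(sigma=s), (3, 4)))
        assert (table.regions["S"] == 0.0).all()
        assert (~table.regions["s_defined"]).all()
        assert (table.regions["R"] > 0).all()

    def test_estimator_vanishes_on_independent_data(self):
        """Sampled-from-independence omega estimates shrink toward zero."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ts = RegionTimeSeries(values=rng.standard_normal((5000, 5)), sampling_period=1.0)
            table = oinfo_from_timeseries(ts, (3, 5))
            worst = table.regions["omega_mean"].abs().max()
            hits += worst < 0.02
        assert hits >= 19

    def test_copula_pipeline_invariant_to_marginals(self, rng):
        X = rng.standard_normal((800, 4))
        X[:, 1] += 0.7 * X[:, 0]
        ts_a = RegionTimeSeries(values=X, sampling_period=1.0)
        Y = X.copy()
        Y[:, 2] = np.exp(Y[:, 2])  # monotone distortion of one marginal
        ts_b = RegionTimeSeries(values=Y, sampling_period=1.0)
        a = oinfo_from_timeseries(ts_a, (3, 4)).regions
        b = oinfo_from_timeseries(ts_b, (3, 4)).regions
        np.testing.assert_allclose(a["omega_mean"], b["omega_mean"], atol=1e-12)
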