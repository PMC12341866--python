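import numpy as np
import pytest

import emalam as em

from conftest import random_estimate
from oracles import k2_extremes_grid, k2_extremes_lp


def _biallelic(P1_rows):
    """(M, 2) first-allele frequencies -> P blocks."""
    return [np.stack([np.asarray(row), 1.0 - np.asarray(row)], axis=1) for row in P1_rows]


class TestExtremalStats:
    def test_identical_populations_give_unit_ratios(self):
        est = em.validate_estimate(
            [[0.3, 0.7], [0.6, 0.4]], _biallelic([(0.4, 0.4), (0.7, 0.7)])
        )
        s = em.extremal_stats(est)
        assert s.u_min == s.u_max == 1.0

    def test_anchor_marker_ratios(self):
        est = em.validate_estimate(
            [[0.5, 0.5]], _biallelic([(0.01, 0.1), (0.9, 0.99)])
        )
        s = em.extremal_stats(est)
        # candidate ratios: 0.1/0.01 = 10, 0.99/0.9 = 1.1, 0.9/0.99, 0.01/0.1
        assert s.u_max == pytest.approx(10.0)
        assert s.u_min == pytest.approx(0.1)

    def test_anchor_individual_ratios(self):
        est = em.validate_estimate(
            [[0.01, 0.99], [0.99, 0.01], [0.5, 0.5]],
            _biallelic([(0.5, 0.5)]),
        )
        s = em.extremal_stats(est)
        assert s.v_min == pytest.approx(0.01 / 0.99)
        assert s.v_max == pytest.approx(99.0)

    def test_zero_denominators_follow_conventions(self):
        est = em.validate_estimate(
            [[1.0, 0.0], [0.2, 0.8]],
            _biallelic([(0.0, 0.3), (0.5, 0.0)]),
        )
        s = em.extremal_stats(est)
        assert np.isinf(s.u_max)   # p1 = 0 with p2 > 0
        assert s.u_min == 0.0      # p2 = 0 with p1 > 0 (complement allele)
        assert np.isinf(s.v_max)   # q_i2 = 0

    def test_requires_k2(self, k3_instance):
        with pytest.raises(ValueError, match="K = 2"):
            em.extremal_stats(k3_instance[0])


class TestK2Interval:
    def test_indistinguishable_populations_give_unit_interval(self):
        est = em.validate_estimate(
            [[0.3, 0.7], [0.8, 0.2]], _biallelic([(0.5, 0.5), (0.2, 0.2)])
        )
        for iv in em.k2_interval_all(est):
            assert iv.lower == pytest.approx(0.0, abs=1e-12)
            assert iv.upper == pytest.approx(1.0, abs=1e-12)

    def test_perfect_anchors_collapse_to_point(self):
        est = em.validate_estimate(
            [[1.0, 0.0], [0.0, 1.0], [0.3, 0.7]],
            _biallelic([(1.0, 0.0), (0.0, 1.0), (0.5, 0.6)]),
        )
        s = em.extremal_stats(est)
        assert np.isinf(s.u_max) and s.u_min == 0.0
        assert np.isinf(s.v_max) and s.v_min == 0.0
        for i, iv in enumerate(em.k2_interval_all(est)):
            assert iv.lower == pytest.approx(est.Q[i, 0], abs=1e-12)
            assert iv.upper == pytest.approx(est.Q[i, 0], abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_contains_starting_value(self, seed):
        est, _ = random_estimate(seed=seed, N=15, M=25, K=2)
        for i, iv in enumerate(em.k2_interval_all(est)):
            assert iv.lower - 1e-12 <= est.Q[i, 0] <= iv.upper + 1e-12

    def test_label_swap_symmetry(self, k2_estimate):
        swapped = em.apply_transform(k2_estimate, em.permutation_transform([1, 0]))
        for iv1, iv2 in zip(em.k2_interval_all(k2_estimate), em.k2_interval_all(swapped)):
            assert iv2.lower == pytest.approx(1.0 - iv1.upper, abs=1e-9)
            assert iv2.upper == pytest.approx(1.0 - iv1.lower, abs=1e-9)

    def test_identical_individuals_identical_intervals(self):
        est = em.validate_estimate(
            [[0.4, 0.6]] * 5, _biallelic([(0.3, 0.5), (0.6, 0.45)])
        )
        ivs = em.k2_interval_all(est)
        assert all(iv == ivs[0] for iv in ivs)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_lp_extremes(self, seed):
        est, _ = random_estimate(seed=seed, N=20, M=30, K=2)
        for iv, (lo, hi) in zip(em.k2_interval_all(est), k2_extremes_lp(est)):
            assert iv.lower == pytest.approx(lo, abs=1e-8)
            assert iv.upper == pytest.approx(hi, abs=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_grid_search(self, seed):
        est, _ = random_estimate(seed=seed, N=12, M=20, K=2)
        for iv, (lo, hi) in zip(
            em.k2_interval_all(est), k2_extremes_grid(est, n=300)
        ):
            assert iv.lower == pytest.approx(lo, abs=1e-3)
            assert iv.upper == pytest.approx(hi, abs=1e-3)

    def test_boundary_entries_agree_with_lp(self):
        # exact zeros in Q and P pin the feasible set; the closed form's
        # limit conventions must match the direct search
        est = em.validate_estimate(
            [[1.0, 0.0], [0.4, 0.6]],
            _biallelic([(0.3, 0.5), (0.7, 0.55)]),
        )
        for iv, (lo, hi) in zip(em.k2_interval_all(est), k2_extremes_lp(est)):
            assert iv.lower == pytest.approx(lo, abs=1e-8)
            assert iv.upper == pytest.approx(hi, abs=1e-8)


class TestInformationMonotonicity:
    def test_sharper_stats_never_widen(self, k2_estimate):
        base = em.k2_interval_all(k2_estimate)
        # append an anchor marker: u_max grows, u_min shrinks
        P1 = [blk[0, 0] for blk in k2_estimate.P] + [0.01]
        P2 = [blk[1, 0] for blk in k2_estimate.P] + [0.6]
        est2 = em.validate_estimate(
            k2_estimate.Q, _biallelic(list(zip(P1, P2)))
        )
        for iv_old, iv_new in zip(base, em.k2_interval_all(est2)):
            assert iv_new.width <= iv_old.width + 1e-12

    def test_non_extreme_additions_change_nothing(self, k2_estimate):
        s = em.extremal_stats(k2_estimate)
        # a marker with ratio strictly inside (u_min, u_max) and an
        # individual strictly inside (v_min, v_max)
        mid_ratio = np.sqrt(s.u_min * s.u_max)
        p1 = 0.5
        p2 = np.clip(mid_ratio * p1, 0.05, 0.95)
        assert s.u_min < p2 / p1 < s.u_max
        assert s.u_min < (1 - p2) / (1 - p1) < s.u_max
        mid_v = np.sqrt(s.v_min * s.v_max)
        q1 = mid_v / (1 + mid_v)
        Q_new = np.vstack([k2_estimate.Q, [q1, 1 - q1]])
        P_new = list(k2_estimate.P) + [np.array([[p1, 1 - p1], [p2, 1 - p2]])]
        est2 = em.validate_estimate(Q_new, P_new)
        base = em.k2_interval_all(k2_estimate)
        extended = em.k2_interval_all(est2)
        for iv_old, iv_new in zip(base, extended):
            assert iv_new.lower == pytest.approx(iv_old.lower, abs=1e-12)
            assert iv_new.upper == pytest.approx(iv_old.upper, abs=1e-12)
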