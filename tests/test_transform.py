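import itertools

import numpy as np
import pytest

import emalam as em
from emalam.transform import InfeasibleTransformError

from conftest import random_estimate


class TestMakeTransform:
    def test_identity(self):
        T = em.make_transform(np.eye(3))
        assert T.det == pytest.approx(1.0)
        np.testing.assert_allclose(T.S_inv, np.eye(3))

    def test_permutation(self):
        T = em.permutation_transform([1, 0])
        np.testing.assert_allclose(T.S, [[0, 1], [1, 0]])
        np.testing.assert_allclose(T.S @ T.S_inv, np.eye(2), atol=1e-14)

    def test_singular_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            em.make_transform([[0.5, 0.5], [0.5, 0.5]])

    def test_bad_row_sums_rejected(self):
        with pytest.raises(ValueError, match="sums to"):
            em.make_transform([[0.9, 0.0], [0.0, 1.0]])

    def test_inverse_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            E = rng.uniform(-0.3, 0.3, size=(3, 3))
            np.fill_diagonal(E, 0.0)
            S = np.eye(3) + E
            np.fill_diagonal(S, 1.0 - E.sum(axis=1))
            T = em.make_transform(S)
            np.testing.assert_allclose(T.S_inv.sum(axis=1), 1.0, atol=1e-8)


class TestApplyTransform:
    def test_identity_is_noop(self, k2_estimate):
        out = em.apply_transform(k2_estimate, em.identity_transform(2))
        assert out.allclose(k2_estimate, atol=1e-15)

    def test_label_swap_swaps_and_preserves_products(self):
        est = em.validate_estimate([[0.7, 0.3]], [np.array([[0.1, 0.9], [0.9, 0.1]])])
        out = em.apply_transform(est, em.permutation_transform([1, 0]))
        np.testing.assert_allclose(out.Q, [[0.3, 0.7]])
        np.testing.assert_allclose(out.P[0][:, 0], [0.9, 0.1])
        prod_before = est.Q[0] @ est.P[0][:, 0]
        prod_after = out.Q[0] @ out.P[0][:, 0]
        assert prod_before == pytest.approx(0.34, abs=1e-12)
        assert prod_after == pytest.approx(prod_before, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_scalar_products_preserved(self, seed):
        est, _ = random_estimate(seed=seed, N=10, M=12, K=3)
        T = em.random_feasible_transform(est, rng_seed=seed + 100)
        out = em.apply_transform(est, T)
        for m in range(est.M):
            np.testing.assert_allclose(
                out.Q @ out.P[m], est.Q @ est.P[m], atol=1e-10
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_roundtrip_through_inverse(self, seed):
        est, _ = random_estimate(seed=seed, N=8, M=10, K=3)
        T = em.random_feasible_transform(est, rng_seed=seed)
        out = em.apply_transform(est, T)
        back = em.apply_transform(out, em.inverse_transform(T), tol=1e-7)
        assert back.allclose(est, atol=1e-9)

    def test_infeasible_rejected_with_report(self, anchored_estimate):
        # a large shear cannot be feasible once anchors pin the feasible set
        T = em.make_transform([[1.5, -0.5], [0.0, 1.0]])
        with pytest.raises(InfeasibleTransformError) as exc:
            em.apply_transform(anchored_estimate, T)
        report = exc.value.report
        assert not report.feasible
        assert report.min_q_entry < 0 or report.min_p_entry < 0


class TestFeasibility:
    def test_identity_always_feasible(self, k2_estimate, anchored_estimate):
        for est in (k2_estimate, anchored_estimate):
            assert em.is_feasible(est, em.identity_transform(2)).feasible

    @pytest.mark.parametrize("K", [2, 3, 4])
    def test_all_permutations_feasible(self, K):
        est, _ = random_estimate(seed=K, N=6, M=8, K=K)
        for perm in itertools.permutations(range(K)):
            assert em.is_feasible(est, em.permutation_transform(perm)).feasible

    def test_report_matches_direct_recomputation(self):
        # an estimate with a vertex individual: feasibility decided by Q S sign
        est = em.validate_estimate(
            [[0.0, 1.0], [0.5, 0.5]],
            [np.array([[0.4, 0.6], [0.6, 0.4]])],
        )
        T = em.make_transform([[1.5, -0.5], [0.0, 1.0]])
        report = em.is_feasible(est, T)
        Q_direct = est.Q @ T.S
        P_direct = [T.S_inv @ blk for blk in est.P]
        assert report.min_q_entry == pytest.approx(Q_direct.min(), abs=1e-15)
        assert report.min_p_entry == pytest.approx(
            min(b.min() for b in P_direct), abs=1e-15
        )
        assert report.feasible == (
            Q_direct.min() >= -1e-9 and min(b.min() for b in P_direct) >= -1e-9
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_composition_stays_feasible(self, seed):
        est, _ = random_estimate(seed=seed, N=8, M=10, K=3)
        T1 = em.random_feasible_transform(est, rng_seed=seed)
        mid = em.apply_transform(est, T1)
        T2 = em.random_feasible_transform(mid, rng_seed=seed + 1000)
        combined = em.make_transform(T1.S @ T2.S)
        assert em.is_feasible(est, combined, tol=1e-8).feasible


class TestLikelihoodInvariance:
    @pytest.mark.parametrize("K", [2, 3, 4])
    def test_feasible_transform_preserves_loglikelihood(self, K):
        for seed in range(10):
            est, x = random_estimate(seed=seed, N=10, M=20, K=K)
            T = em.random_feasible_transform(est, rng_seed=seed + 7)
            out = em.apply_transform(est, T)
            assert em.loglikelihood(out, x) == pytest.approx(
                em.loglikelihood(est, x), abs=1e-10
            )


class TestRandomFeasibleTransform:
    def test_deterministic_in_seed(self, k2_estimate):
        T1 = em.random_feasible_transform(k2_estimate, rng_seed=42)
        T2 = em.random_feasible_transform(k2_estimate, rng_seed=42)
        np.testing.assert_array_equal(T1.S, T2.S)

    def test_anchored_estimate_pins_transform_near_identity(self, anchored_estimate):
        T = em.random_feasible_transform(anchored_estimate, rng_seed=0)
        # feasible-set diameter from the analytic module bounds the deviation
        widths = [iv.width for iv in em.k2_interval_all(anchored_estimate)]
        assert np.max(np.abs(T.S - np.eye(2))) <= max(widths) + 0.05

    def test_unconstrained_p_allows_large_moves(self):
        # identical frequencies in both populations: P constraints are vacuous
        Q = np.array([[0.5, 0.5]] * 4)
        P = [np.array([[0.5, 0.5], [0.5, 0.5]])] * 6
        est = em.validate_estimate(Q, P)
        T = em.random_feasible_transform(est, rng_seed=1)
        assert np.max(np.abs(T.S - np.eye(2))) > 0.05
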