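"""Independent reference computations used to certify the implementation.

Everything here deliberately avoids the package's own fast paths: the
log-likelihood is a naive triple loop, and the K=2 ancestry extremes are
found by searching the (a, b) parametrization of the transform family
directly — by linear programming and by a dense feasibility-filtered grid
with adaptive refinement — instead of the closed form.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import linprog

from emalam import AdmixEstimate, GenotypeMatrix


def loglik_bruteforce(est: AdmixEstimate, x: GenotypeMatrix) -> float:
    """Naive triple-loop normalized log-likelihood."""
    total = 0.0
    for i in range(est.N):
        for m in range(est.M):
            for j in range(est.P[m].shape[1]):
                c = int(x.X[m][i, j])
                if c > 0:
                    prob = sum(est.Q[i, k] * est.P[m][k, j] for k in range(est.K))
                    total += c * math.log(prob)
    return total / (2.0 * est.M * est.N)


def _k2_constraint_rows(est: AdmixEstimate):
    """A_ub x <= b_ub for the K=2 transform family S=[[1-a,a],[b,1-b]].

    Constraints on the identity branch (det = 1-a-b >= 0):
      q~_i1 >= 0:  q_i1 a - q_i2 b <= q_i1
      q~_i2 >= 0: -q_i1 a + q_i2 b <= q_i2
      p~ >= 0:     p2 a + p1 b <= min(p1, p2)   for every allele/marker
      det:         a + b <= 1
    """
    q1, q2 = est.Q[:, 0], est.Q[:, 1]
    p1 = np.concatenate([blk[0] for blk in est.P])
    p2 = np.concatenate([blk[1] for blk in est.P])
    A = np.vstack(
        [
            np.stack([q1, -q2], axis=1),
            np.stack([-q1, q2], axis=1),
            np.stack([p2, p1], axis=1),
            np.stack([p2, p1], axis=1),
            np.array([[1.0, 1.0]]),
        ]
    )
    b = np.concatenate([q1, q2, p1, p2, [1.0]])
    return A, b


def k2_extremes_lp(est: AdmixEstimate) -> list[tuple[float, float]]:
    """Exact per-individual extremes of q~_i1 via linear programming."""
    A, b = _k2_constraint_rows(est)
    out = []
    for i in range(est.N):
        q1, q2 = est.Q[i, 0], est.Q[i, 1]
        # q~_i1 = q1 (1 - a) + q2 b, so minimize/maximize (-q1) a + q2 b
        lo = linprog([-q1, q2], A_ub=A, b_ub=b, bounds=[(-50, 50)] * 2)
        hi = linprog([q1, -q2], A_ub=A, b_ub=b, bounds=[(-50, 50)] * 2)
        assert lo.status == 0 and hi.status == 0
        out.append((q1 + lo.fun, q1 - hi.fun))
    return out


def _feasible_mask(A, b, aa, bb, tol=1e-9):
    pts = np.stack([aa.ravel(), bb.ravel()], axis=1)  # (G, 2)
    vals = pts @ A.T - b  # (G, n_constraints)
    return (vals.max(axis=1) <= tol).reshape(aa.shape)


def k2_extremes_grid(
    est: AdmixEstimate, n: int = 400, refine: int = 3, refine_n: int = 60
) -> list[tuple[float, float]]:
    """Per-individual extremes of q~_i1 by feasibility-filtered grid search.

    The starting box is taken from LP bounds on a and b (padded); each
    individual's extreme is then refined by re-gridding a shrinking window
    around the best feasible point.
    """
    A, b = _k2_constraint_rows(est)
    bounds = []
    for c in ([1, 0], [-1, 0], [0, 1], [0, -1]):
        r = linprog(c, A_ub=A, b_ub=b, bounds=[(-50, 50)] * 2)
        assert r.status == 0
        bounds.append(r.fun if sum(c) > 0 else -r.fun)
    a_lo, a_hi = bounds[0], bounds[1]
    b_lo, b_hi = bounds[2], bounds[3]
    pad_a = 0.05 * (a_hi - a_lo) + 1e-6
    pad_b = 0.05 * (b_hi - b_lo) + 1e-6

    def grid_eval(alo, ahi, blo, bhi, npts):
        av = np.linspace(alo, ahi, npts)
        bv = np.linspace(blo, bhi, npts)
        aa, bb = np.meshgrid(av, bv, indexing="ij")
        mask = _feasible_mask(A, b, aa, bb)
        return aa, bb, mask

    aa, bb, mask = grid_eval(a_lo - pad_a, a_hi + pad_a, b_lo - pad_b, b_hi + pad_b, n)
    if not mask.any():
        raise RuntimeError("no feasible grid point (identity should be feasible)")
    ha = (aa[-1, 0] - aa[0, 0]) / (n - 1)
    hb = (bb[0, -1] - bb[0, 0]) / (n - 1)

    out = []
    for i in range(est.N):
        q1, q2 = est.Q[i, 0], est.Q[i, 1]

        def refine_extreme(sign):
            # sign=+1 maximizes q~_i1, -1 minimizes
            vals = q1 * (1 - aa) + q2 * bb
            vals = np.where(mask, vals, -sign * np.inf)
            idx = np.unravel_index(np.argmax(sign * vals), vals.shape)
            best = vals[idx]
            ca, cb, wa, wb = aa[idx], bb[idx], ha, hb
            for _ in range(refine):
                ga, gb, gm = grid_eval(ca - wa, ca + wa, cb - wb, cb + wb, refine_n)
                if not gm.any():
                    break
                gv = q1 * (1 - ga) + q2 * gb
                gv = np.where(gm, gv, -sign * np.inf)
                gidx = np.unravel_index(np.argmax(sign * gv), gv.shape)
                if sign * gv[gidx] > sign * best:
                    best = gv[gidx]
                ca, cb = ga[gidx], gb[gidx]
                wa = 2 * (2 * wa) / (refine_n - 1)
                wb = 2 * (2 * wb) / (refine_n - 1)
            return float(best)

        out.append((refine_extreme(-1.0), refine_extreme(+1.0)))
    return out
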