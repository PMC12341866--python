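"""Likelihood-preserving transformations of an admixture estimate.

The log-likelihood depends on (Q, P) only through the genotype
probabilities ``q_i· p_·jm^T``.  For any invertible K x K matrix S with
unit row sums, the pair ``(Q S, P (S^-1)^T)`` produces exactly the same
probabilities, hence exactly the same likelihood.  The transformed pair is
a valid parameter set whenever it stays inside the simplex constraints;
the set of such S is the feasible set of the estimate, and it is the flat
direction of the likelihood.  Permutation matrices (label switching) are
always members; generically the set has positive dimension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import AdmixEstimate, validate_estimate

__all__ = [
    "TransformMatrix",
    "FeasibilityReport",
    "InfeasibleTransformError",
    "make_transform",
    "identity_transform",
    "permutation_transform",
    "inverse_transform",
    "apply_transform",
    "is_feasible",
    "random_feasible_transform",
    "SINGULARITY_TOL",
    "FEASIBILITY_TOL",
]

#: minimum |det S| accepted as invertible
SINGULARITY_TOL = 1e-8
#: entries of the transformed (Q, P) this far below 0 still count as feasible
#: (optimizer output sits on the constraint boundary) and are clamped to 0
FEASIBILITY_TOL = 1e-9
_ROWSUM_TOL = 1e-10


@dataclass(frozen=True)
class TransformMatrix:
    """An invertible K x K matrix with unit row sums, plus its inverse.

    Unit row sums guarantee that Q S keeps unit row sums; the inverse then
    automatically has unit row sums as well, so P (S^-1)^T keeps unit
    allele sums.
    """

    S: np.ndarray
    S_inv: np.ndarray
    det: float

    @property
    def K(self) -> int:
        return self.S.shape[0]


@dataclass(frozen=True)
class FeasibilityReport:
    """Outcome of checking S against an estimate's simplex constraints."""

    feasible: bool
    min_q_entry: float
    min_p_entry: float
    violating_q: tuple[tuple[int, int], ...]
    violating_p: tuple[tuple[int, int, int], ...]
    tol: float


class InfeasibleTransformError(ValueError):
    """Raised when a transform would push the estimate off the simplex."""

    def __init__(self, report: FeasibilityReport):
        self.report = report
        super().__init__(
            f"transform infeasible: min Q entry {report.min_q_entry:.3g}, "
            f"min P entry {report.min_p_entry:.3g} (tol {report.tol:g}); "
            f"{len(report.violating_q)} Q and {len(report.violating_p)} P violations"
        )


def make_transform(S_raw, sing_tol: float = SINGULARITY_TOL) -> TransformMatrix:
    """Validate a raw matrix as a unit-row-sum invertible transform."""
    S = np.asarray(S_raw, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError(f"S must be square, got shape {S.shape}")
    rowsums = S.sum(axis=1)
    if np.any(np.abs(rowsums - 1.0) > _ROWSUM_TOL):
        bad = int(np.argmax(np.abs(rowsums - 1.0)))
        raise ValueError(
            f"row {bad} of S sums to {rowsums[bad]:.12g}, expected 1"
        )
    det = float(np.linalg.det(S))
    if abs(det) <= sing_tol:
        raise ValueError(f"S is singular within tolerance (|det| = {abs(det):.3g})")
    S_inv = np.linalg.inv(S)
    return TransformMatrix(S=S, S_inv=S_inv, det=det)


def identity_transform(K: int) -> TransformMatrix:
    I = np.eye(K)
    return TransformMatrix(S=I, S_inv=I.copy(), det=1.0)


def permutation_transform(perm) -> TransformMatrix:
    """Label-switching transform: S[k, perm[k]] = 1.

    Applying it maps population ``k`` of the input onto column ``perm[k]``
    of the output.  Permutations are feasible for every valid estimate.
    """
    perm = np.asarray(perm, dtype=int)
    K = perm.size
    if sorted(perm.tolist()) != list(range(K)):
        raise ValueError(f"not a permutation of 0..{K - 1}: {perm.tolist()}")
    S = np.zeros((K, K))
    S[np.arange(K), perm] = 1.0
    return make_transform(S)


def inverse_transform(T: TransformMatrix) -> TransformMatrix:
    return TransformMatrix(S=T.S_inv.copy(), S_inv=T.S.copy(), det=1.0 / T.det)


def _transform_arrays(est: AdmixEstimate, T: TransformMatrix):
    """Raw transformed arrays (no clamping): Q S and per-marker S^-1 P_m."""
    Q_new = est.Q @ T.S
    P_new = [T.S_inv @ blk for blk in est.P]
    return Q_new, P_new


def is_feasible(
    est: AdmixEstimate, T: TransformMatrix, tol: float = FEASIBILITY_TOL
) -> FeasibilityReport:
    """Check membership of S in the estimate's feasible set.

    S is feasible when every entry of Q S and of the transformed allele
    frequencies stays >= -tol.  Row sums are preserved automatically by the
    unit-row-sum structure, so nonnegativity is the only condition.
    """
    if T.K != est.K:
        raise ValueError(f"transform is {T.K}x{T.K} but estimate has K={est.K}")
    Q_new, P_new = _transform_arrays(est, T)
    min_q = float(Q_new.min())
    viol_q = tuple(
        (int(i), int(k)) for i, k in zip(*np.nonzero(Q_new < -tol))
    )
    min_p = np.inf
    viol_p = []
    for m, blk in enumerate(P_new):
        bmin = float(blk.min())
        if bmin < min_p:
            min_p = bmin
        for k, j in zip(*np.nonzero(blk < -tol)):
            viol_p.append((int(k), int(j), m))
    return FeasibilityReport(
        feasible=(min_q >= -tol and min_p >= -tol),
        min_q_entry=min_q,
        min_p_entry=float(min_p),
        violating_q=viol_q,
        violating_p=tuple(viol_p),
        tol=tol,
    )


def apply_transform(
    est: AdmixEstimate, T: TransformMatrix, tol: float = FEASIBILITY_TOL
) -> AdmixEstimate:
    """Apply a feasible transform, returning the equally likely estimate.

    The output is ``(Q S, P (S^-1)^T)``.  Entries in ``[-tol, 0)`` are
    clamped to 0 and rows renormalized; entries below ``-tol`` make the
    transform infeasible and raise :class:`InfeasibleTransformError`
    carrying the full feasibility report.
    """
    report = is_feasible(est, T, tol)
    if not report.feasible:
        raise InfeasibleTransformError(report)
    Q_new, P_new = _transform_arrays(est, T)
    # clamping boundary noise changes entries by <= tol, row sums stay 1
    return validate_estimate(Q_new, P_new, tol=max(10 * tol, 1e-8))


def random_feasible_transform(
    est: AdmixEstimate,
    rng_seed: int,
    n_tries: int = 200,
    initial_scale: float = 0.5,
) -> TransformMatrix:
    """Sample a non-identity member of the feasible set by rejection.

    Perturbs the identity by uniform off-diagonal noise (diagonal adjusted
    to keep unit row sums), shrinking the noise scale geometrically on
    failure.  Deterministic in ``rng_seed``.  If every try is rejected the
    identity is returned — for strongly anchored estimates the feasible set
    collapses to (numerically) a point, and that is the honest answer.
    """
    rng = np.random.default_rng(rng_seed)
    K = est.K
    scale = initial_scale
    for attempt in range(n_tries):
        E = rng.uniform(-scale, scale, size=(K, K))
        np.fill_diagonal(E, 0.0)
        S = np.eye(K) + E
        np.fill_diagonal(S, 1.0 - (E.sum(axis=1)))
        try:
            T = make_transform(S)
        except ValueError:
            scale *= 0.8
            continue
        if is_feasible(est, T).feasible:
            return T
        scale *= 0.8
    return identity_transform(K)
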