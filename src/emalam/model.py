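"""Core domain types for the admixture model.

The admixture model describes ``N`` diploid individuals as mixtures of ``K``
ancestral populations.  Individual ``i`` carries an admixture row vector
``q_i·`` on the ``K``-simplex, and population ``k`` has allele frequencies
``p_kjm`` over the ``J_m`` alleles of marker ``m``.  The probability of
drawing allele ``j`` at marker ``m`` for individual ``i`` is the scalar
product ``q_i· p_·jm^T``; diploid genotypes are two independent draws.

This module holds the validated containers (:class:`AdmixEstimate`,
:class:`GenotypeMatrix`), the normalized log-likelihood and the Shannon
entropy of an admixture row.  The additive combinatorial constant of the
log-likelihood depends only on the genotypes and cancels in every comparison
between parameter values, so it is never computed here: all likelihood
values are reported relative to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AdmixEstimate",
    "GenotypeMatrix",
    "ValidationError",
    "validate_estimate",
    "loglikelihood",
    "entropy",
    "DEFAULT_TOL",
    "FILE_TOL",
]

#: internal simplex tolerance (estimates constructed in memory)
DEFAULT_TOL = 1e-8
#: looser tolerance for file input, where values are printed with few decimals
FILE_TOL = 1e-6


class ValidationError(ValueError):
    """Raised when a (Q, P) pair violates the simplex constraints."""


def _as_p_blocks(P) -> tuple[np.ndarray, ...]:
    """Normalize P input to a tuple of (K, J_m) float arrays, one per marker.

    Accepts a 3-D array of shape (K, J, M) for the uniform-allele-count case,
    or any sequence of per-marker (K, J_m) arrays (ragged allowed).
    """
    if isinstance(P, np.ndarray) and P.ndim == 3:
        K, J, M = P.shape
        return tuple(np.asarray(P[:, :, m], dtype=float) for m in range(M))
    blocks = []
    for m, block in enumerate(P):
        arr = np.asarray(block, dtype=float)
        if arr.ndim != 2:
            raise ValidationError(
                f"marker {m}: frequency block must be 2-D (K x J_m), got shape {arr.shape}"
            )
        blocks.append(arr)
    return tuple(blocks)


@dataclass(frozen=True)
class AdmixEstimate:
    """A validated admixture-model parameter pair (Q, P).

    Q has shape (N, K): row ``i`` is the admixture vector of individual ``i``.
    P is a tuple of M arrays, one per marker, each of shape (K, J_m): row
    ``k`` holds the allele frequencies of population ``k`` at that marker.
    Rows of Q and allele rows of P lie on the probability simplex.

    Use :func:`validate_estimate` to construct one from raw arrays.
    """

    Q: np.ndarray
    P: tuple[np.ndarray, ...]

    @property
    def N(self) -> int:
        return self.Q.shape[0]

    @property
    def K(self) -> int:
        return self.Q.shape[1]

    @property
    def M(self) -> int:
        return len(self.P)

    @property
    def J(self) -> np.ndarray:
        """Number of alleles per marker, shape (M,)."""
        return np.array([blk.shape[1] for blk in self.P])

    @property
    def is_biallelic(self) -> bool:
        return bool(np.all(self.J == 2))

    def p_array(self) -> np.ndarray:
        """Stack P into a (K, J, M) array; requires a uniform allele count."""
        J = self.J
        if not np.all(J == J[0]):
            raise ValueError("ragged allele counts; cannot stack P")
        return np.stack(self.P, axis=2)

    def __eq__(self, other) -> bool:  # ndarray fields defeat dataclass eq
        if not isinstance(other, AdmixEstimate):
            return NotImplemented
        return (
            self.Q.shape == other.Q.shape
            and len(self.P) == len(other.P)
            and np.array_equal(self.Q, other.Q)
            and all(np.array_equal(a, b) for a, b in zip(self.P, other.P))
        )

    def allclose(self, other: "AdmixEstimate", atol: float = 1e-9) -> bool:
        return (
            self.Q.shape == other.Q.shape
            and len(self.P) == len(other.P)
            and np.allclose(self.Q, other.Q, atol=atol)
            and all(
                a.shape == b.shape and np.allclose(a, b, atol=atol)
                for a, b in zip(self.P, other.P)
            )
        )


@dataclass(frozen=True)
class GenotypeMatrix:
    """Diploid allele counts: per marker an (N, J_m) integer block.

    ``X[m][i, j]`` counts copies (0, 1 or 2) of allele ``j`` carried by
    individual ``i`` at marker ``m``; each row sums to 2 (diploidy).
    """

    X: tuple[np.ndarray, ...]

    def __post_init__(self):
        blocks = tuple(np.asarray(b) for b in self.X)
        object.__setattr__(self, "X", blocks)
        if not blocks:
            raise ValidationError("genotype matrix needs at least one marker")
        N = blocks[0].shape[0]
        for m, b in enumerate(blocks):
            if b.ndim != 2 or b.shape[0] != N:
                raise ValidationError(f"marker {m}: inconsistent genotype block shape")
            if not np.issubdtype(b.dtype, np.integer):
                raise ValidationError(f"marker {m}: genotype counts must be integers")
            if b.min() < 0 or b.max() > 2:
                raise ValidationError(f"marker {m}: allele counts must lie in {{0,1,2}}")
            sums = b.sum(axis=1)
            if not np.all(sums == 2):
                bad = int(np.nonzero(sums != 2)[0][0])
                raise ValidationError(
                    f"marker {m}, individual {bad}: allele counts sum to "
                    f"{int(sums[bad])}, expected 2 (diploidy)"
                )

    @property
    def N(self) -> int:
        return self.X[0].shape[0]

    @property
    def M(self) -> int:
        return len(self.X)


def _check_simplex_rows(A: np.ndarray, tol: float, what: str) -> np.ndarray:
    """Validate rows of A as simplex vectors within tol, then renormalize."""
    if A.min(initial=0.0) < -tol or A.max(initial=0.0) > 1.0 + tol:
        i, j = np.unravel_index(
            np.argmax(np.maximum(-A, A - 1.0)), A.shape
        )
        raise ValidationError(
            f"{what}: entry ({i},{j}) = {A[i, j]:.6g} outside [0, 1] beyond tol={tol:g}"
        )
    sums = A.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > tol):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ValidationError(
            f"{what}: row {bad} sums to {sums[bad]:.8g}, deviates from 1 beyond tol={tol:g}"
        )
    A = np.clip(A, 0.0, 1.0)
    return A / A.sum(axis=1, keepdims=True)


def validate_estimate(Q, P, tol: float = DEFAULT_TOL) -> AdmixEstimate:
    """Validate raw (Q, P) arrays against the simplex constraints.

    Entries must lie in [0, 1] and rows (Q rows; P allele rows per population
    and marker) must sum to 1, all within ``tol``.  Rows passing validation
    are renormalized exactly, so downstream code can rely on exact sums.

    Parameters
    ----------
    Q : array-like, shape (N, K)
    P : (K, J, M) array or sequence of M arrays of shape (K, J_m)
    tol : float
        Slack for entry range and row sums.  Use a looser value
        (:data:`FILE_TOL` or more) for rounded file input.
    """
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2:
        raise ValidationError(f"Q must be 2-D, got shape {Q.shape}")
    N, K = Q.shape
    if N < 1 or K < 1:
        raise ValidationError("need N >= 1 and K >= 1")
    blocks = _as_p_blocks(P)
    if len(blocks) < 1:
        raise ValidationError("need at least one marker (M >= 1)")
    Q = _check_simplex_rows(Q, tol, "Q")
    out = []
    for m, blk in enumerate(blocks):
        if blk.shape[0] != K:
            raise ValidationError(
                f"marker {m}: P block has {blk.shape[0]} populations, Q has {K}"
            )
        if blk.shape[1] < 2:
            raise ValidationError(f"marker {m}: need at least 2 alleles, got {blk.shape[1]}")
        out.append(_check_simplex_rows(blk, tol, f"P[marker {m}]"))
    return AdmixEstimate(Q=Q, P=tuple(out))


def loglikelihood(est: AdmixEstimate, x: GenotypeMatrix) -> float:
    """Normalized log-likelihood of (Q, P) given diploid genotypes.

    Returns ``(1 / 2MN) * sum_{i,m,j} x_ijm log(q_i· p_·jm^T)``.  The
    additive constant depending only on x is omitted, so the value is
    suited to comparisons at fixed genotypes; it is always <= 0.

    Raises
    ------
    ValueError
        If some genotype count is positive where the model probability
        ``q_i· p_·jm^T`` is zero (the estimate assigns probability 0 to an
        observed allele).
    """
    if est.N != x.N or est.M != x.M:
        raise ValueError(
            f"dimension mismatch: estimate is N={est.N}, M={est.M}; "
            f"genotypes are N={x.N}, M={x.M}"
        )
    total = 0.0
    for m in range(est.M):
        probs = est.Q @ est.P[m]          # (N, J_m)
        counts = x.X[m]
        mask = counts > 0
        if np.any(probs[mask] <= 0.0):
            i, j = np.unravel_index(
                np.argmax(mask & (probs <= 0.0)), probs.shape
            )
            raise ValueError(
                f"zero genotype probability with positive count at "
                f"individual {i}, allele {j}, marker {m}"
            )
        total += float(np.sum(counts[mask] * np.log(probs[mask])))
    return total / (2.0 * est.M * est.N)


def entropy(w, tol: float = DEFAULT_TOL) -> float:
    """Shannon entropy ``-sum_k w_k log w_k`` (natural log) of a simplex vector.

    Zero entries contribute 0 (the ``0 log 0 := 0`` convention); the result
    lies in ``[0, log K]``, minimal for point masses and maximal for the
    uniform distribution.
    """
    w = np.asarray(w, dtype=float)
    if w.min(initial=0.0) < -tol:
        raise ValueError(f"negative entry {w.min():.3g} beyond tolerance")
    if abs(w.sum() - 1.0) > max(tol, 1e-8):
        raise ValueError(f"entries sum to {w.sum():.8g}, expected 1")
    w = np.clip(w, 0.0, None)
    pos = w[w > 0.0]
    return float(-np.sum(pos * np.log(pos)))
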