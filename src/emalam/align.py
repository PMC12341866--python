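"""Label-switching alignment and mode clustering across runs.

Different runs of an admixture inference tool frequently return the same
solution with permuted population labels — the permutation special case of
the likelihood-preserving transforms.  :func:`align` finds, by optimal
assignment on a K x K cost matrix, the relabeling of one estimate that best
matches a reference, and applies it jointly to Q and P.  The cost of
matching columns is the mean absolute difference of the Q columns; P plays
no role in the cost but is permuted along, which keeps the pair consistent.

:func:`cluster_modes` groups many runs into modes: estimates whose
post-alignment distance falls below a threshold are linked, and connected
groups (single linkage) form a mode.  Modes are reported largest first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .model import AdmixEstimate
from .transform import apply_transform, permutation_transform

__all__ = ["AlignmentResult", "align", "align_distance", "cluster_modes", "MODE_THRESHOLD"]

#: default mean-absolute-Q-difference below which two runs count as one mode
MODE_THRESHOLD = 0.05


@dataclass(frozen=True)
class AlignmentResult:
    """Best relabeling of ``other`` against a reference estimate.

    ``permutation[k]`` gives the column of ``other`` that plays the role of
    the reference's population ``k``; ``aligned`` is ``other`` with that
    relabeling applied to Q and P; ``distance`` is the mean absolute Q
    difference after alignment.
    """

    permutation: tuple[int, ...]
    distance: float
    same_mode: bool
    aligned: AdmixEstimate


def _check_dims(a: AdmixEstimate, b: AdmixEstimate) -> None:
    if (a.N, a.K, a.M) != (b.N, b.K, b.M):
        raise ValueError(
            f"dimension mismatch: ({a.N},{a.K},{a.M}) vs ({b.N},{b.K},{b.M})"
        )


def align(
    reference: AdmixEstimate,
    other: AdmixEstimate,
    threshold: float = MODE_THRESHOLD,
) -> AlignmentResult:
    """Align ``other`` to ``reference`` by the best population permutation."""
    _check_dims(reference, other)
    K = reference.K
    # cost[k, l]: mean |Q_ref[:, k] - Q_other[:, l]|
    cost = np.mean(
        np.abs(reference.Q[:, :, None] - other.Q[:, None, :]), axis=0
    )
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(K, dtype=int)
    perm[rows] = cols                      # reference column k <- other column perm[k]
    # permutation transform moving other's column perm[k] into position k
    T = permutation_transform(np.argsort(perm))
    aligned = apply_transform(other, T)
    distance = float(np.mean(np.abs(reference.Q - aligned.Q)))
    return AlignmentResult(
        permutation=tuple(int(p) for p in perm),
        distance=distance,
        same_mode=distance <= threshold,
        aligned=aligned,
    )


def align_distance(a: AdmixEstimate, b: AdmixEstimate) -> float:
    """Mean absolute Q difference after optimal relabeling."""
    return align(a, b).distance


def cluster_modes(
    estimates: list[AdmixEstimate], threshold: float = MODE_THRESHOLD
) -> list[list[int]]:
    """Single-linkage grouping of runs into modes.

    Returns groups of input indices, largest group (the major mode) first;
    ties broken by smallest member index.  Invariant under input order up
    to relabeling of the groups.
    """
    n = len(estimates)
    if n == 0:
        raise ValueError("need at least one estimate")
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if align_distance(estimates[i], estimates[j]) <= threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(groups.values(), key=lambda g: (-len(g), g[0]))
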