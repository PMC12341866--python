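"""Closed-form range of equally likely ancestry proportions for K = 2.

For two ancestral populations the unit-row-sum transforms form a
two-parameter family ``S = [[1-a, a], [b, 1-b]]``, and on the branch
connected to the identity (``det S = 1 - a - b > 0``, i.e. excluding the
label swap) the feasible set is a polygon in the (a, b) plane.  The extreme
values of the transformed ancestry ``q~_i1`` over that polygon have a closed
form that depends on the starting point only through four extremal
statistics:

* ``u_min``, ``u_max`` — the smallest and largest allele-frequency ratio
  ``p_2jm / p_1jm`` over all alleles and markers (because allele frequencies
  sum to 1 at each marker, always ``u_min <= 1 <= u_max``);
* ``v_min``, ``v_max`` — the smallest and largest admixture ratio
  ``q_i1 / q_i2`` over all individuals.

The per-individual interval of equally likely ancestry in population 1 is::

    lower = q_i1 (u_max - 1)/(u_max + v_min) + q_i2 (1 - u_max)/(1 + u_max/v_min)
    upper = q_i1 (1 + v_max)/(u_min + v_max) + q_i2 (1 + v_max)/(1 + v_max/u_min)

equivalently ``lower = (q_i1 - v_min q_i2) (u_max - 1)/(u_max + v_min)`` and
``upper = (q_i1 + u_min q_i2) (1 + v_max)/(u_min + v_max)``.  Anchor markers
drive ``u_min -> 0`` / ``u_max -> inf`` and anchor individuals drive
``v_min -> 0`` / ``v_max -> inf``; in the joint limit the interval collapses
to the starting value.  When the two populations have identical frequencies
(``u_min = u_max = 1``) it is the whole of [0, 1].  Infinite statistics are
propagated by their analytic limits rather than by floating-point infinity
arithmetic.

Adding markers or individuals whose ratios are not more extreme than those
already present leaves every interval unchanged — more data of the same
quality does not restore identifiability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import AdmixEstimate

__all__ = ["ExtremalStats", "K2Interval", "extremal_stats", "k2_interval", "k2_interval_all"]


@dataclass(frozen=True)
class ExtremalStats:
    """Extreme frequency and admixture ratios of a K=2 estimate.

    ``u_min/u_max`` range over ``p_2jm / p_1jm`` (all alleles, all markers),
    ``v_min/v_max`` over ``q_i1 / q_i2`` (all individuals).  A zero
    denominator with a positive numerator contributes ``inf``; 0/0 pairs are
    skipped (they constrain nothing).
    """

    u_min: float
    u_max: float
    v_min: float
    v_max: float


@dataclass(frozen=True)
class K2Interval:
    """Equally likely range of one individual's ancestry in population 1."""

    lower: float
    upper: float
    stats: ExtremalStats

    @property
    def width(self) -> float:
        return self.upper - self.lower


def _ratio_extremes(num: np.ndarray, den: np.ndarray) -> tuple[float, float]:
    """Min and max of num/den with inf for x/0 (x>0) and 0/0 skipped."""
    num = np.asarray(num, dtype=float).ravel()
    den = np.asarray(den, dtype=float).ravel()
    keep = (num > 0.0) | (den > 0.0)
    num, den = num[keep], den[keep]
    if num.size == 0:
        return (np.nan, np.nan)
    lo, hi = np.inf, 0.0
    pos = den > 0.0
    if np.any(pos):
        r = num[pos] / den[pos]
        lo = min(lo, float(r.min()))
        hi = max(hi, float(r.max()))
    if np.any(~pos):  # positive numerator over zero denominator
        hi = np.inf
    return (lo, hi)


def _require_k2(est: AdmixEstimate) -> None:
    if est.K != 2:
        raise ValueError(f"analytic intervals require K = 2, got K = {est.K}")


def extremal_stats(est: AdmixEstimate) -> ExtremalStats:
    """Compute the four extremal ratio statistics of a K=2 estimate."""
    _require_k2(est)
    p1 = np.concatenate([blk[0] for blk in est.P])
    p2 = np.concatenate([blk[1] for blk in est.P])
    u_min, u_max = _ratio_extremes(p2, p1)
    v_min, v_max = _ratio_extremes(est.Q[:, 0], est.Q[:, 1])
    return ExtremalStats(u_min=u_min, u_max=u_max, v_min=v_min, v_max=v_max)


def _lower_bound(q1: float, q2: float, u_max: float, v_min: float) -> float:
    # lower = (q1 - v_min q2) * (u_max - 1)/(u_max + v_min), by limits at inf
    if np.isinf(u_max) and np.isinf(v_min):
        # all individuals pure population 1 and a marker fixes population 1:
        # the only feasible direction keeps q1 unchanged
        return q1
    if np.isinf(u_max):
        return q1 - v_min * q2
    if np.isinf(v_min):
        return 0.0
    denom = u_max + v_min
    if denom == 0.0:  # u_max >= 1 always, so unreachable; guard anyway
        return 0.0
    return (q1 - v_min * q2) * (u_max - 1.0) / denom


def _upper_bound(q1: float, q2: float, u_min: float, v_max: float) -> float:
    # upper = (q1 + u_min q2) * (1 + v_max)/(u_min + v_max)
    if u_min == 0.0 and np.isinf(v_max):
        return q1
    if np.isinf(v_max):
        return q1 + u_min * q2
    if u_min == 0.0:
        if v_max == 0.0:  # every individual pure population 2, frequency anchor
            return q1
        return q1 * (1.0 + v_max) / v_max
    return (q1 + u_min * q2) * (1.0 + v_max) / (u_min + v_max)


def k2_interval(est: AdmixEstimate, i: int, stats: ExtremalStats | None = None) -> K2Interval:
    """Equally likely range of ``q_i1`` for individual ``i`` (K = 2).

    The interval always contains the starting value ``q_i1`` (the identity
    transform is feasible); endpoints are clamped to [0, 1].
    """
    _require_k2(est)
    if stats is None:
        stats = extremal_stats(est)
    q1, q2 = float(est.Q[i, 0]), float(est.Q[i, 1])
    lower = _lower_bound(q1, q2, stats.u_max, stats.v_min)
    upper = _upper_bound(q1, q2, stats.u_min, stats.v_max)
    lower = min(max(lower, 0.0), q1)
    upper = max(min(upper, 1.0), q1)
    return K2Interval(lower=lower, upper=upper, stats=stats)


def k2_interval_all(est: AdmixEstimate) -> list[K2Interval]:
    """Per-individual intervals sharing one extremal-statistics pass.

    This is the band plotted against individual index when visualizing how
    wide the set of equally likely ancestry estimates is.
    """
    _require_k2(est)
    stats = extremal_stats(est)
    return [k2_interval(est, i, stats=stats) for i in range(est.N)]
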