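"""Synthetic admixture scenarios for testing and demonstration.

Two generators are provided.  :func:`simulate_fig1` builds the canonical
two-population toy scenario used throughout the documentation: 1,000
bi-allelic markers whose population-A frequencies are uniform on
[0.25, 0.75] and whose population-B frequencies add a uniform [0, 0.3]
shift (falling back to 0.5 when the shifted value leaves [0.2, 0.8]),
together with 100 admixed individuals whose ancestry follows a smooth
monotone curve spanning (0, 1).  Optional anchors can be added: two
markers with strongly differentiated frequencies, (0.01, 0.1) and
(0.9, 0.99), and two essentially unadmixed individuals, (0.01, 0.99) and
(0.99, 0.01).  Comparing the equally-likely ancestry band with and without
anchors shows how a handful of informative markers/individuals shrinks the
flat ridge of the likelihood.

:func:`simulate_general` draws arbitrary (N, M, K) instances: Dirichlet
admixture rows with a chosen concentration and uniform bi-allelic
frequencies, with optional anchors.  Genotypes are always sampled from the
model itself: the allele-1 count of individual i at marker m is
Binomial(2, q_i· p_·1m^T).

Neither generator emulates linkage disequilibrium, genotyping error or
relatedness; every marker is independent given (Q, P).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import AdmixEstimate, GenotypeMatrix, validate_estimate

__all__ = ["ScenarioConfig", "AnchorSpec", "simulate_fig1", "simulate_general"]


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of the two-population toy scenario."""

    n_individuals: int = 100
    n_markers: int = 1000
    add_anchor_markers: bool = False
    add_anchor_individuals: bool = False
    seed: int = 0
    K: int = 2
    #: steepness of the logistic ancestry curve over individuals
    curve_steepness: float = 8.0

    def __post_init__(self):
        if self.n_individuals < 1 or self.n_markers < 1:
            raise ValueError("need at least one individual and one marker")
        if self.K != 2:
            raise ValueError("the toy recipe is defined for K = 2 "
                             "(use simulate_general for other K)")


@dataclass(frozen=True)
class AnchorSpec:
    """Anchors to inject into a general simulation.

    markers: rows of per-population allele-1 frequencies, one per anchor
    marker.  individuals: admixture rows, one per anchor individual.
    """

    markers: tuple[tuple[float, ...], ...] = ()
    individuals: tuple[tuple[float, ...], ...] = ()


def _sample_genotypes_biallelic(Q: np.ndarray, P1: np.ndarray, rng) -> GenotypeMatrix:
    """Binomial genotypes; P1 is (M, K) allele-1 frequency per population."""
    probs = Q @ P1.T                      # (N, M) allele-1 probability
    counts1 = rng.binomial(2, probs)      # (N, M)
    blocks = tuple(
        np.stack([counts1[:, m], 2 - counts1[:, m]], axis=1).astype(np.int64)
        for m in range(P1.shape[0])
    )
    return GenotypeMatrix(X=blocks)


def _logistic_curve(n: int, steepness: float) -> np.ndarray:
    t = np.linspace(-0.5, 0.5, n)
    return 1.0 / (1.0 + np.exp(-steepness * t))


def simulate_fig1(config: ScenarioConfig) -> tuple[AdmixEstimate, GenotypeMatrix]:
    """The two-population toy scenario (see module docstring).

    Returns the true (Q, P) as an :class:`AdmixEstimate` together with
    genotypes drawn from it.  Bitwise deterministic in ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    M, N = config.n_markers, config.n_individuals

    pA = rng.uniform(0.25, 0.75, size=M)
    eps = rng.uniform(0.0, 0.3, size=M)
    pB = pA + eps
    pB = np.where((pB >= 0.2) & (pB <= 0.8), pB, 0.5)

    q1 = _logistic_curve(N, config.curve_steepness)

    if config.add_anchor_markers:
        pA = np.concatenate([pA, [0.01, 0.9]])
        pB = np.concatenate([pB, [0.1, 0.99]])
    if config.add_anchor_individuals:
        q1 = np.concatenate([q1, [0.01, 0.99]])

    Q = np.stack([q1, 1.0 - q1], axis=1)
    P1 = np.stack([pA, pB], axis=1)       # (M', K) allele-1 frequencies
    P_blocks = tuple(
        np.stack([P1[m], 1.0 - P1[m]], axis=1) for m in range(P1.shape[0])
    )
    est = validate_estimate(Q, P_blocks)
    x = _sample_genotypes_biallelic(est.Q, P1, rng)
    return est, x


def simulate_general(
    N: int,
    M: int,
    K: int,
    concentration: float = 1.0,
    anchor_spec: AnchorSpec | None = None,
    seed: int = 0,
    freq_range: tuple[float, float] = (0.05, 0.95),
) -> tuple[AdmixEstimate, GenotypeMatrix]:
    """Random bi-allelic admixture instance with model-drawn genotypes.

    Admixture rows are symmetric Dirichlet(concentration): concentration 1
    is uniform on the simplex, small values concentrate near the vertices
    (near-pure individuals), large values near the barycenter.  Allele-1
    frequencies are independent uniforms on ``freq_range`` per population
    and marker; the default range keeps frequencies away from 0/1 so random
    transform feasibility is nontrivial and likelihoods stay finite.
    """
    if N < 1 or M < 1 or K < 1:
        raise ValueError("need N, M, K >= 1")
    if concentration <= 0:
        raise ValueError("Dirichlet concentration must be positive")
    rng = np.random.default_rng(seed)
    Q = rng.dirichlet(np.full(K, concentration), size=N)
    lo, hi = freq_range
    P1 = rng.uniform(lo, hi, size=(M, K))

    if anchor_spec is not None:
        for row in anchor_spec.markers:
            if len(row) != K:
                raise ValueError("anchor marker row must have K frequencies")
            P1 = np.vstack([P1, np.asarray(row, dtype=float)])
        for row in anchor_spec.individuals:
            if len(row) != K:
                raise ValueError("anchor individual row must have K entries")
            Q = np.vstack([Q, np.asarray(row, dtype=float)])

    P_blocks = tuple(
        np.stack([P1[m], 1.0 - P1[m]], axis=1) for m in range(P1.shape[0])
    )
    est = validate_estimate(Q, P_blocks)
    x = _sample_genotypes_biallelic(est.Q, P1, rng)
    return est, x
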