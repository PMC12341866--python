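"""Numeric search over the feasible transform set for K >= 2.

For more than two populations no closed form for the range of equally
likely estimates is known, so the extremes are found by constrained local
optimization over S.  S is parametrized by its K(K-1) off-diagonal entries
with the diagonal set to 1 minus the off-diagonal row sum, which enforces
unit row sums by construction.  Four objectives are supported: minimize or
maximize the mean ancestry of one population over a subset of individuals,
and minimize or maximize the mean entropy of the admixture rows (low
entropy favors unadmixed-looking solutions, high entropy admixed-looking
ones).  Every returned estimate has, by construction, exactly the
likelihood of the input.

The search is SLSQP from the identity (the one transform guaranteed
feasible) plus seeded random restarts drawn by rejection near the identity.
The determinant is constrained away from zero on the side of the starting
point, so the search never crosses the singular surface into the
label-swapped branch; label switching is handled separately by alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize

from .model import AdmixEstimate, entropy
from .transform import (
    TransformMatrix,
    identity_transform,
    make_transform,
    apply_transform,
    random_feasible_transform,
)

__all__ = [
    "ObjectiveSpec",
    "OptimizerConfig",
    "OptimizationResult",
    "objective_value",
    "optimize",
    "explore",
]

ObjectiveKind = Literal["pop_min", "pop_max", "entropy_min", "entropy_max"]
_KINDS = ("pop_min", "pop_max", "entropy_min", "entropy_max")

#: two-sided exclusion zone around det S = 0
DET_TOL = 1e-6
_ENT_EPS = 1e-12  # clamp inside log for a differentiable entropy objective


@dataclass(frozen=True)
class ObjectiveSpec:
    """Which extreme of the flat likelihood ridge to look for.

    kind : 'pop_min' | 'pop_max' | 'entropy_min' | 'entropy_max'
    k    : target population index (required for pop_* kinds)
    I    : subset of individual indices averaged over (default: all)
    """

    kind: ObjectiveKind
    k: int | None = None
    I: tuple[int, ...] | None = None

    def validate(self, est: AdmixEstimate) -> "ObjectiveSpec":
        if self.kind not in _KINDS:
            raise ValueError(f"unknown objective kind {self.kind!r}; expected one of {_KINDS}")
        if self.kind.startswith("pop"):
            if self.k is None:
                raise ValueError(f"objective {self.kind!r} requires a population index k")
            if not (0 <= self.k < est.K):
                raise ValueError(f"population index {self.k} out of range for K={est.K}")
        I = tuple(range(est.N)) if self.I is None else tuple(int(i) for i in self.I)
        if len(I) == 0:
            raise ValueError("individual subset I must be nonempty")
        if min(I) < 0 or max(I) >= est.N:
            raise ValueError(f"subset indices out of range for N={est.N}")
        return replace(self, I=I)

    @property
    def maximize(self) -> bool:
        return self.kind.endswith("max")


@dataclass(frozen=True)
class OptimizerConfig:
    n_restarts: int = 10
    seed: int = 0
    max_iter: int = 500
    ftol: float = 1e-10
    constraint_tol: float = 1e-9
    restart_scale: float = 0.5
    det_tol: float = DET_TOL


@dataclass(frozen=True)
class OptimizationResult:
    transform: TransformMatrix
    estimate: AdmixEstimate
    objective_value: float
    objective_at_identity: float
    converged: bool
    n_restarts_used: int
    spec: ObjectiveSpec
    error: str | None = None


def objective_value(est: AdmixEstimate, spec: ObjectiveSpec) -> float:
    """Evaluate an objective on an estimate as-is (no transform)."""
    spec = spec.validate(est)
    rows = est.Q[list(spec.I)]
    if spec.kind.startswith("pop"):
        return float(rows[:, spec.k].mean())
    return float(np.mean([entropy(r) for r in rows]))


def _build_S(theta: np.ndarray, K: int) -> np.ndarray:
    """Off-diagonal parametrization: diagonal = 1 - off-diagonal row sum."""
    S = np.zeros((K, K))
    off = ~np.eye(K, dtype=bool)
    S[off] = theta
    np.fill_diagonal(S, 1.0 - S.sum(axis=1))
    return S


def _theta_of(S: np.ndarray) -> np.ndarray:
    K = S.shape[0]
    return S[~np.eye(K, dtype=bool)].copy()


def _smooth_objective(theta, est, spec, sign):
    S = _build_S(theta, est.K)
    rows = est.Q[list(spec.I)] @ S
    if spec.kind.startswith("pop"):
        val = rows[:, spec.k].mean()
    else:
        w = np.clip(rows, _ENT_EPS, None)
        val = float(np.mean(-np.sum(w * np.log(w), axis=1)))
    return sign * val


def _constraints(theta, est, det_tol):
    """Inequality constraints (all must be >= 0)."""
    K = est.K
    S = _build_S(theta, K)
    det = np.linalg.det(S)
    out = [est.Q @ S]  # N*K entries
    if abs(det) < 1e-12:
        # inverse undefined: report p-constraints as violated, keep det active
        p_block = [np.full(blk.shape, -1.0) for blk in est.P]
    else:
        S_inv = np.linalg.inv(S)
        p_block = [S_inv @ blk for blk in est.P]
    parts = [out[0].ravel()] + [b.ravel() for b in p_block]
    parts.append(np.array([det - det_tol]))  # stay on the identity's branch
    return np.concatenate(parts)


def _run_start(theta0, est, spec, sign, config):
    cons = [
        {
            "type": "ineq",
            "fun": _constraints,
            "args": (est, config.det_tol),
        }
    ]
    res = minimize(
        _smooth_objective,
        theta0,
        args=(est, spec, sign),
        method="SLSQP",
        constraints=cons,
        options={"maxiter": config.max_iter, "ftol": config.ftol},
    )
    return res


def optimize(
    est: AdmixEstimate,
    spec: ObjectiveSpec,
    config: OptimizerConfig | None = None,
) -> OptimizationResult:
    """Find an extreme equally likely estimate for one objective.

    Runs SLSQP from the identity and from ``config.n_restarts`` random
    feasible starts, keeps the best feasible iterate, and never returns a
    result worse than the identity.  Non-convergence of the local solver is
    reported through ``converged``; the best iterate is returned regardless.
    """
    if config is None:
        config = OptimizerConfig()
    spec = spec.validate(est)
    if est.K < 2:
        raise ValueError("optimization needs K >= 2")
    sign = -1.0 if spec.maximize else 1.0
    K = est.K

    at_identity = objective_value(est, spec)
    best_S = np.eye(K)
    best_val = at_identity
    converged = True
    n_used = 0

    starts = [np.zeros(K * (K - 1))]
    rng_seeds = [config.seed + 1 + r for r in range(config.n_restarts)]
    for s in rng_seeds:
        T = random_feasible_transform(est, rng_seed=s, initial_scale=config.restart_scale)
        starts.append(_theta_of(T.S))

    for idx, theta0 in enumerate(starts):
        res = _run_start(theta0, est, spec, sign, config)
        n_used = idx
        cand = _build_S(res.x, K)
        cvals = _constraints(res.x, est, config.det_tol)
        if cvals.min() < -config.constraint_tol:
            continue  # infeasible terminal iterate: discard
        val = sign * res.fun
        better = (val > best_val) if spec.maximize else (val < best_val)
        if better:
            best_val = float(val)
            best_S = cand
            converged = bool(res.success)

    T = make_transform(best_S)
    new_est = apply_transform(est, T, tol=max(config.constraint_tol, 1e-9) * 10)
    return OptimizationResult(
        transform=T,
        estimate=new_est,
        objective_value=float(best_val),
        objective_at_identity=float(at_identity),
        converged=converged,
        n_restarts_used=n_used,
        spec=spec,
    )


def explore(
    est: AdmixEstimate,
    specs: Sequence[ObjectiveSpec],
    config: OptimizerConfig | None = None,
) -> list[OptimizationResult]:
    """Run several objectives on one estimate; a failure in one objective
    does not abort the batch (the failed entry carries the identity and an
    error message)."""
    out = []
    for spec in specs:
        try:
            out.append(optimize(est, spec, config))
        except Exception as exc:  # noqa: BLE001 — batch isolation is the contract
            out.append(
                OptimizationResult(
                    transform=identity_transform(est.K),
                    estimate=est,
                    objective_value=float("nan"),
                    objective_at_identity=float("nan"),
                    converged=False,
                    n_restarts_used=0,
                    spec=spec,
                    error=str(exc),
                )
            )
    return out
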