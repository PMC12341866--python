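# Methods

## Model and conventions

The admixture model treats the genotype `x_ijm ∈ {0,1,2}` (copies of allele
*j* carried by individual *i* at marker *m*; counts sum to 2 over alleles)
as two independent draws from the categorical distribution with
probabilities `q_i· p_·jm^T`.  We work with the normalized log-likelihood

```
ℓ = (1 / 2MN) Σ_{i,m,j} x_ijm log(q_i· p_·jm^T)
```

and never compute the additive multinomial constant: every comparison the
package makes is between parameter values at fixed genotypes, where the
constant cancels.  Natural logarithms are used throughout, so the entropy
of an admixture row lies in `[0, log K]`.  Terms with `x_ijm = 0` are
skipped, which makes zero frequencies legal wherever the corresponding
allele is unobserved; a zero probability with a positive count is an error,
not a `-inf`.

Markers may have different allele counts: `P` is stored as one
`(K, J_m)` block per marker.  The bi-allelic case is the fast path
(`.P` files store only the first-allele frequency; the complement is
implied).

Simplex validation renormalizes rows after they pass a tolerance check:
`1e-8` for in-memory construction, `1e-6`-to-`1e-3` for file input, since
STRUCTURE and ADMIXTURE print three to six decimals.  Renormalizing after
validation means downstream code can rely on exact unit sums.

## The feasible transform set

For invertible `S` with unit row sums, `(Q S, P (S⁻¹)^T)` preserves every
genotype probability, hence the likelihood, exactly.  Unit row sums of `S`
force unit row sums of `S⁻¹`, so sum constraints survive automatically and
feasibility reduces to nonnegativity of the transformed entries.  The
feasibility check accepts entries down to `−1e-9` and clamps them to zero
afterwards — optimizer output legitimately sits on the constraint boundary,
and the clamp perturbs the likelihood by no more than the same order.
Invertibility is enforced as `|det S| > 1e-8`.

The rejection sampler for random feasible transforms perturbs the identity
with uniform off-diagonal noise (diagonal adjusted to keep row sums),
shrinking the scale by 0.8 per rejection.  It is deterministic in its seed.
When anchors pin the feasible set the sampler honestly degenerates to
(near-)identity transforms; tests use this as a diagnostic of feasible-set
size.

## The K = 2 closed form

With `S = [[1−a, a], [b, 1−b]]`, the feasible set on the branch
`det S = 1 − a − b > 0` is a polygon in `(a, b)` defined by linear
constraints, and `q̃_i1 = q_i1(1−a) + q_i2 b` is linear, so each
individual's extremes sit at polygon vertices.  Solving the two relevant
vertex systems gives

```
lower_i = (q_i1 − v_min q_i2) (u_max − 1)/(u_max + v_min)
upper_i = (q_i1 + u_min q_i2) (1 + v_max)/(u_min + v_max)
```

with `u_min/u_max` the extreme ratios `p_2jm / p_1jm` over all alleles and
markers and `v_min/v_max` the extreme ratios `q_i1 / q_i2` over
individuals.  Because allele frequencies sum to 1 at each marker,
`u_min ≤ 1 ≤ u_max` always.  The derivation was certified against two
independent searches of the `(a, b)` region — exact linear programming and
a feasibility-filtered dense grid with adaptive refinement — agreeing to
`1e-8` (LP) and about `1e-5` (grid) on random instances, including boundary
cases with exact zeros in `Q`.

**Branch restriction.**  Permutation matrices are always feasible, so the
full set of equally likely `q̃_i1` values is the union of this interval and
its label-swapped mirror.  The closed form (and the K>2 optimizer, via a
sign-fixed determinant constraint) deliberately covers only the branch
connected to the identity: label switching is a discrete, well-understood
ambiguity handled by the alignment module, and folding it into the interval
would report `[0, 1]` for every dataset with symmetric anchors, hiding the
continuous ridge that is the quantity of interest.

**Zero-ratio conventions.**  `x/0` with `x > 0` contributes `+∞` to a ratio
set, `0/x` contributes `0`, and `0/0` pairs are skipped (they constrain
nothing).  Infinite statistics propagate through the bounds by analytic
limits, not floating-point `inf` arithmetic: e.g. `u_max = ∞` gives
`lower = q_i1 − v_min q_i2`, and jointly `u_max = ∞, v_min = 0` gives
`lower = q_i1` — the anchor-collapse limit.  Doubly degenerate inputs
(a whole population absent from `Q`) resolve by the direct geometric
argument and are covered by boundary tests.  Endpoints are finally clamped
to `[0, q_i1]` and `[q_i1, 1]`, which is exact up to rounding because the
identity is always feasible.

Two consequences follow directly from the formula and are tested as
properties: sharpening any of the four statistics never widens an interval,
and adding markers or individuals with non-extreme ratios changes nothing —
more data of the same quality does not restore identifiability.

## Numeric search for K ≥ 2

No closed form is available beyond K = 2, so the extremes of four
objectives — mean ancestry of a chosen population over a subset `I`
(min/max) and mean entropy over `I` (min/max) — are found numerically.
Choices, all of them this package's own:

* **Parametrization.** The `K(K−1)` off-diagonal entries of `S`, diagonal
  `= 1 −` off-diagonal row sum, so row-stochasticity of the row sums is
  structural, not a constraint.
* **Solver.** SLSQP with all `N·K` admixture constraints, all `K·Σ J_m`
  frequency constraints, and `det S ≥ 1e-6` (the sign fixed at the starting
  point, keeping the search on the identity's branch).  Tolerances:
  objective `1e-10`, constraint violation `1e-9`, 500 iterations per start.
  The problem dimension is `K(K−1)` (6 for K = 3), so finite-difference
  gradients are cheap.
* **Multistart.** The identity (the one guaranteed-feasible point) plus 10
  random feasible restarts by default, drawn with the rejection sampler
  from a seeded stream.  Infeasible terminal iterates are discarded; the
  result is never worse than the identity, and more restarts never worsen
  it.
* **Entropy smoothing.** Inside the objective, row entries are clamped to
  `1e-12` for differentiability at the boundary; reported entropy values
  use the exact `0 log 0 = 0` convention.

At K = 2 with singleton subsets the optimizer reproduces the closed-form
endpoints to ~1e-9 on random instances (the package's own
cross-validation); the test-suite tolerance is 2e-3.

Local search cannot certify global optimality for K > 2; the multistart is
a mitigation, not a proof.  Only equally likely estimates reachable from
the given starting point are explored — solutions of higher likelihood, or
in other likelihood modes, are out of scope by construction.

## Label alignment

Runs differing only by label switching are merged by minimizing the mean
absolute difference of `Q` matrices over permutations, solved exactly as a
linear assignment on the `K×K` column-cost matrix.  `P` does not enter the
cost (ancestry bars are what is compared across runs) but is permuted
jointly so the pair stays consistent.  Mode grouping is single linkage on
pairwise aligned distances with a default threshold of 0.05 mean absolute
difference, chosen as clearly above numerical jitter between converged runs
and clearly below any substantive difference in ancestry; it is exposed as
a flag.

## Synthetic scenarios

`simulate_fig1` emulates a two-population setting with deliberately weak
differentiation: 1,000 bi-allelic markers with population-A frequencies
uniform on `[0.25, 0.75]`, population-B frequencies `p_A + ε`,
`ε ~ U[0, 0.3]`, reset to 0.5 whenever the shifted value leaves
`[0.2, 0.8]` (the fallback applies immediately, no redraw; since
`p_A ≥ 0.25` and `ε ≥ 0` only the upper edge can trigger it).  True
ancestries follow a logistic curve over the individual index spanning
(0, 1) — the curve shape is a package choice, exposed in the config, since
only its monotone smooth character matters for the demonstrations.  Optional
anchors add two markers with frequencies `(0.01, 0.1)` and `(0.9, 0.99)`
and two individuals with ancestry `(0.01, 0.99)` and `(0.99, 0.01)`.

`simulate_general` draws Dirichlet admixture rows (symmetric concentration;
1 = uniform on the simplex, small values = near-pure individuals) and
uniform allele-1 frequencies on `[0.05, 0.95]` by default — bounded away
from 0/1 so that random instances have nontrivial feasible sets and finite
likelihoods.  Genotypes are always sampled from the model itself
(`Binomial(2, q_i· p_·1m^T)` per marker).  One `numpy` generator seeded per
call threads through all draws; outputs are bitwise reproducible.

What these generators do **not** emulate: linkage disequilibrium,
genotyping error, missing data, relatedness, or estimation noise (the
"estimate" handed downstream is the true parameter pair).  Tests passing on
them show the machinery is correct under the model's own assumptions; they
do not show that a real STRUCTURE run's estimate is near the truth — the
package's purpose is precisely to quantify how non-unique such an estimate
is.

## Problem sizes and determinism

The validation pipeline (`scripts/acceptance.py`, test suite) uses 100
random instances with `N ≤ 50`, `M ≤ 100`, `K ≤ 4` for likelihood
invariance, 20–50 instances at `N = 20, M = 30` for the interval-vs-grid
comparison (400×400 starting grid, three refinement rounds), 20 instances
for the optimizer-vs-closed-form comparison, and the full 100×1000 toy
scenario for anchor shrinkage — sizes at which the grid and LP oracles are
exact enough to be meaningful while the whole validation completes in
minutes.  All randomness flows from explicit seeds; fixed-seed runs of the
simulators and the optimizer are bitwise identical.

## Known limitations

* The K = 2 interval describes the identity-connected branch only (see
  above); combine with the alignment module when the labeling itself is in
  doubt.
* The K > 2 search is local; a flat ridge with several disconnected
  feasible components would be reported only partially.
* The STRUCTURE parser targets the common outfile dialect (ancestry block
  with `:`-separated fractions, per-locus cluster frequency block) and is
  tolerant to column-width changes, but STRUCTURE's output format varies
  across versions; the pinned fixture documents the supported shape.
* Only equally likely estimates are explored — estimates of *higher*
  likelihood than the input (i.e. a better mode) are never searched for.
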