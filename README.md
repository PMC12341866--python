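# emalam

Explore the full set of equally likely estimates in the admixture model.

## The problem

Ancestry inference tools such as STRUCTURE and ADMIXTURE fit the admixture
model: each of *N* diploid individuals is a mixture over *K* ancestral
populations, described by an admixture matrix **Q** (rows `q_i·` on the
*K*-simplex) and allele-frequency matrices **P** (per population and marker,
frequencies summing to 1 over alleles).  The log-likelihood

```
ℓ(q, p | x) = C_x + (1 / 2MN) Σ_{i,m,j} x_ijm · log(q_i· p_·jm^T)
```

depends on the parameters only through the products `q_i· p_·jm^T`.  For any
invertible K×K matrix **S** with unit row sums, the pair
`(Q S, P (S⁻¹)^T)` yields exactly the same products — and whenever it stays
inside the simplex constraints it is an equally likely estimate.  The
reported point estimate is therefore one member of a whole ridge of
solutions, and the ridge can be wide: substantially different ancestry
assignments can be exactly as well supported by the data.

This package, for users of STRUCTURE/ADMIXTURE output, computes that ridge:

* **K = 2** — a closed-form per-individual interval of equally likely
  ancestry.  It depends only on four extremal statistics: the most extreme
  allele-frequency ratios `u_min ≤ 1 ≤ u_max` over markers (ratios
  `p_2jm / p_1jm`) and the most extreme admixture ratios `v_min, v_max` over
  individuals (ratios `q_i1 / q_i2`):

  ```
  lower_i = (q_i1 − v_min q_i2) (u_max − 1)/(u_max + v_min)
  upper_i = (q_i1 + u_min q_i2) (1 + v_max)/(u_min + v_max)
  ```

  Anchor markers (nearly fixed in one population) push `u_max → ∞`,
  `u_min → 0`; anchor individuals (nearly unadmixed) push `v_min → 0`,
  `v_max → ∞`; jointly they collapse the interval to a point.  Without them
  the interval can approach [0, 1] — the populations cannot be disentangled,
  no matter how many unexceptional markers are added.

* **K ≥ 2** — seeded, multistart SLSQP search over **S** for the extremes of
  a chosen objective: the mean ancestry of one population over a subset of
  individuals (min/max), or the mean Shannon entropy of the admixture rows
  (min favors unadmixed-looking solutions, max admixed-looking ones).

* **Label switching** — permutations of population labels are the discrete
  special case of **S**; an alignment module merges multiple runs by optimal
  assignment and groups them into modes.

## Worked example

```python
import numpy as np
import emalam as em

# toy scenario: 100 individuals, 1000 markers, two close populations
est, x = em.simulate_fig1(em.ScenarioConfig(seed=0))
stats = em.extremal_stats(est)
print(f"u_min={stats.u_min:.3f}  u_max={stats.u_max:.3f}  "
      f"v_min={stats.v_min:.4f}  v_max={stats.v_max:.1f}")

ivs = em.k2_interval_all(est)
i = 50
print(f"individual {i}: q1 = {est.Q[i,0]:.3f}, equally likely range "
      f"[{ivs[i].lower:.3f}, {ivs[i].upper:.3f}]")
print(f"mean band width: {np.mean([iv.width for iv in ivs]):.3f}")

anchored, _ = em.simulate_fig1(em.ScenarioConfig(
    seed=0, add_anchor_markers=True, add_anchor_individuals=True))
w = [iv.width for iv in em.k2_interval_all(anchored)[:100]]
print(f"mean band width with anchors: {np.mean(w):.3f}")

T = em.random_feasible_transform(est, rng_seed=1)
print(f"loglik before {em.loglikelihood(est, x):.6f}, "
      f"after {em.loglikelihood(em.apply_transform(est, T), x):.6f}")
```

prints

```
u_min=0.405  u_max=2.189  v_min=0.0183  v_max=54.6
individual 50: q1 = 0.510, equally likely range [0.270, 0.716]
mean band width: 0.446
mean band width with anchors: 0.110
loglik before -0.657158, after -0.657158
```

An individual estimated as a 51/49 mixture could equally well be anywhere
from 27% to 72% population-A ancestry — the likelihood cannot tell these
apart.  Adding just two strongly differentiated markers and two unadmixed
individuals shrinks the average band from 0.45 to 0.11, while a random
feasible transform leaves the log-likelihood unchanged to machine precision.

## Command line

```
emalam simulate --out-prefix toy --seed 0              # write .Q/.P/.geno
emalam interval --qfile toy.Q --pfile toy.P --out band.json
emalam optimize --qfile toy.Q --pfile toy.P --objective max_entropy \
       --seed 0 --out-prefix widest
emalam align run1 run2 run3 --out modes.json
emalam validate --qfile toy.Q --pfile toy.P
```

Inputs are ADMIXTURE `.Q`/`.P` files or a STRUCTURE output file
(`--structure`); reports are JSON with an embedded manifest.

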