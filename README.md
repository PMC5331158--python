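# ramadens

Collective nonparametric estimation of protein backbone-angle densities
(Ramachandran and pseudo-Ramachandran distributions) with tensor-product
trigonometric splines, and alignment-free protein structure clustering
built on top of it.

## Who this is for

Structural bioinformaticians and statisticians who need to estimate many
related bivariate densities of angular data at once — one per protein,
per residue class, or per sequence neighborhood — especially when some
groups have few observations, and who want the fitted coefficients as
low-dimensional features for visualization, clustering, or classification.

## The model

For groups i = 1..m with angle-pair observations x_ij, each log-density is
expanded in K shared components built from a rich tensor-product spline
basis b(x) of dimension L:

    log f_i(x) = b(x)^T Theta alpha_i + c_i,        Omega = B Theta A^T,

where Theta (L x K) holds the shared component coefficients, alpha_i the
per-group scores and c_i the normalizing constant.  Periodic directions
(phi, psi, tau) use trigonometric B-splines — sin/cos half-angle recursions
that are intrinsically smooth on the circle, so no wrap-around constraints
are needed — while the bounded pseudo-bond angle theta uses clamped cubic
B-splines.  (Theta, A) minimize the penalized likelihood criterion

    -2 l(Theta, A) + lambda * trace(Theta^T D Theta),

with D an order-a difference penalty assembled by Kronecker products, via
an alternating blockwise Newton-Raphson with SVD identifiability, and the
smoothing parameter is updated inside the loop,

    lambda <- (df(lambda) - (a - 1)) / trace(Theta^T D Theta),

replacing an AIC grid search.  Sharing the basis lets sparse groups borrow
strength; the score vectors alpha_i are directly usable features.  For
clustering, pairwise symmetrized Kullback-Leibler divergences between
fitted densities feed Ward (ward.D) hierarchical clustering, evaluated
against gold labels by NMI and ARI.  See `docs/methods.md` for details.

## Worked example

Simulate 12 groups of 75 angle pairs whose log-densities share 3 smooth
components, falling into 3 separated clusters; fit them collectively; then
recover the clusters from the fitted densities alone:

```python
import numpy as np
from ramadens import (CollectiveDensityEstimator, DirectionSpec, SyntheticSpec,
                      generate_shared_basis, pairwise_distances, ward_cluster,
                      nmi, ari)

spec = SyntheticSpec(m=12, n_i=75, K_true=3, n_clusters=3, seed=42,
                     grid_points=48)
data, truths, gold = generate_shared_basis(spec)

d = DirectionSpec(df=10)   # cubic trigonometric basis, 10 functions/direction
est = CollectiveDensityEstimator(n_components=3, dir1=d, dir2=d,
                                 grid_points=48).fit_dataset(data)
print(f"converged in {est.n_iter_} iterations, lambda = {est.lambda_:.4f}")
print(f"effective df = {est.df_:.1f}, AIC = {est.aic_:.1f}")
print(f"component energy shares (%): {np.round(est.energy_share_, 1)}")
print(f"density integrals: {np.round([f.integral() for f in est.densities()[:3]], 6)}")

D = pairwise_distances(est.densities(), data.labels)
found = ward_cluster(D, 3)
print(f"NMI = {nmi(found, gold):.2f}, ARI = {ari(found, gold):.2f}")
```

Output:

```
converged in 95 iterations, lambda = 0.0346
effective df = 89.1, AIC = 3121.3
component energy shares (%): [63.6 31.4  5. ]
density integrals: [1. 1. 1.]
NMI = 1.00, ARI = 1.00
```

The in-loop update settled at lambda = 0.035 with about 89 effective
parameters for 12 densities (rather than 12 separate 100-parameter fits);
the scree shares show two components carrying 95% of the between-group
variation; every fitted density integrates to one; and Ward clustering of
the fitted densities reproduces the generating labels exactly.

## Command line

The same pipeline is scriptable end to end:

```sh
ramadens simulate --m 12 --n-per-group 75 --seed 42 --out sim/
ramadens fit sim/angles.tsv --config config.json --out fit/
ramadens cluster fit/ -k 3 --out clusters/
ramadens evaluate clusters/labels.tsv sim/gold_labels.tsv
ramadens angles structure1.pdb structure2.pdb --mode theta_tau --out angles.tsv
```

`ramadens angles` computes (phi, psi) or (theta, tau) tables from PDB
files; all other stages exchange plain TSV/JSON, and dendrograms are
written as Newick.

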