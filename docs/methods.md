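# Methods

## The estimation problem

A protein's backbone conformation can be summarized by per-residue angle
pairs: the Ramachandran dihedrals (phi, psi), both periodic on
\[-pi, pi), or the C-alpha-trace pseudo-angles (theta, tau), where theta
(the planar bond angle at a central C-alpha) is bounded — empirically
inside (75 deg, 165 deg) — and tau (the C-alpha torsion) is periodic.  The
empirical distribution of these pairs over a chain is the protein's
(pseudo-)Ramachandran distribution.  Estimating one such bivariate density
per protein, for a collection of m proteins, is the core task; the
estimated densities and their low-dimensional coefficient representations
then drive alignment-free structure clustering.

## Model

Each log-density is an expansion in K shared components, which in turn live
in a rich tensor-product spline space of dimension L = M * N:

    log f_i(x) = b(x)^T Theta alpha_i + c_i,      i = 1..m,

with b the L fixed basis functions, Theta (L x K) the shared component
coefficients, alpha_i the group scores, and c_i = -log int exp(...) the
normalizing constant.  On a regular evaluation grid this is the low-rank
factorization Omega = B Theta A^T.

Periodic directions use trigonometric B-splines: order-1 splines are knot
interval indicators and order-nu splines combine two order-(nu-1) splines
with sin half-angle weights sin((x - x_i)/2) / sin((x_{i+nu-1} - x_i)/2).
With knots wrapped modulo the knot count these functions are intrinsically
smooth on the circle, so no seam constraints are ever imposed; restricted
to one knot interval each piece lies in the span of sin/cos half-angle
monomials (for cubic order: cos(x/2), sin(x/2), cos(3x/2), sin(3x/2)),
which the tests verify to 1e-10.  Bounded directions use ordinary clamped
cubic B-splines.  Defaults follow the protein setting: 15 basis functions
in each periodic direction, 5 in the bounded theta direction, order 4
(cubic), evaluated on a 90 x 90 cell-midpoint grid.

Roughness is controlled by an order-a difference penalty on adjacent
coefficients, a = 2 by default.  On periodic directions the stencils wrap
(cyclic penalty) so roughness is measured across the seam; a non-cyclic
variant is available.  The bivariate penalty combines the univariate ones
by Kronecker products consistent with the basis vectorization (direction-1
outer): D = D1 (x) I_N + I_M (x) D2, with Di = L_a^T L_a.  D is symmetric
positive semi-definite and annihilates the constant surface.

## Fitting

Parameters minimize -2 loglik + lambda * trace(Theta^T D Theta) by
alternating damped blockwise Newton-Raphson.  Because the model is an
exponential family, the likelihood gradient for every block is "empirical
minus expected" basis moments, with expectations computed by midpoint
quadrature on the evaluation grid; block Hessians are the corresponding
basis covariances under the current fitted densities.  Step halving (at
most 30 halvings) guarantees each accepted step does not increase the
criterion.

Two well-posedness details matter and are easy to get wrong:

- **Factorization indeterminacy.**  (Theta, A) is only identified up to an
  invertible K x K mixing, and the penalty is not invariant under it —
  without normalization the infimum of the criterion is degenerate (all
  scale pushed into A).  The optimizer therefore works on a canonical
  representative with the scale carried by Theta (columns orthogonal, norms
  the singular values of Theta A^T; A with orthonormal columns), recomputed
  by SVD after every candidate step and used inside the step-halving
  acceptance.  This makes the criterion a well-defined function of the
  product Theta A^T, gives a rigorous descent guarantee at fixed lambda,
  and reduces the m = 1, K = 1 case exactly to a standalone penalized
  log-spline fit (verified to 1e-6 sup-norm against an independent
  implementation).  The reported `Theta_` / `A_` use the opposite, more
  interpretable convention — orthonormal components with energy-carrying
  scores — which reproduces the same densities.
- **The constant direction.**  The constant coefficient vector is in the
  penalty nullspace and its effect on the log-density is absorbed by c_i,
  so it is neither penalized nor identified; it is projected out of the
  canonical state (a centered parameterization).  Left in, the optimizer
  hides amplitude there and the smoothing-parameter update diverges.

The smoothing parameter is updated inside the loop,

    lambda <- (df(lambda) - (a - 1)) / trace(Theta^T D Theta),

where df(lambda) = sum_k trace((H_k + lambda D)^{-1} H_k) is the effective
model dimension.  Before the main loop the scalar update is iterated to a
fixed point at the initial estimates, which avoids large early swings.
This replaces an AIC grid search; on synthetic fixtures the converged
lambda falls within one step of the minimizer of AIC(lambda) = -2 loglik +
2 df(lambda) on an 8-point logarithmic grid.  A `lambda_mode="aic_grid"`
fallback performs that grid search directly, warm-starting each fit from
the next-smoother solution.

Initialization maps per-group circular-KDE log-densities onto the basis by
least squares and factors the centered coefficient matrix by rank-K SVD.
Convergence is declared when the relative criterion change drops below
`tol` (1e-6) and, in auto mode, lambda has settled (relative change below
1e-4); `max_iter` = 500 is a hard cap.  Typical fits converge in 10-80
iterations.

Note on monitoring: the recorded criterion trace is evaluated at each
iteration's own lambda.  Within an iteration descent is guaranteed (the
`criterion_start_trace_` / `criterion_trace_` pair exposes it), and with
fixed lambda the whole trace is monotone; across auto-lambda iterations
the objective itself moves with lambda, so consecutive trace values may
differ by delta-lambda times the penalty trace.

## Baseline KDE

The non-collective comparator is a product-Gaussian kernel estimator with
periodic directions wrapped over +/-3 periods and bounded directions
reflected at the range limits.  Bandwidths default to a normal-reference
rule per direction, sigma_d * n^(-1/6) with sigma_d the circular standard
deviation (sqrt(-2 log Rbar)) on periodic directions, floored at 0.2 rad
for degenerate samples.

## Distances, clustering, agreement

Pairwise density distances are symmetrized Kullback-Leibler divergences,
0.5 [KL(p||q) + KL(q||p)], by cell quadrature with densities floored at
1e-12 before logarithms; Euclidean distances between score vectors are
available as a cheaper alternative.  Hierarchical clustering is Ward in
the "ward.D" dialect — the Lance-Williams recurrence applied to the raw
dissimilarities without squaring — with ties broken toward the lowest
cluster index, verified against R's hclust on a frozen fixture.  The
dendrogram is cut at the number of gold-standard classes.  Agreement with
a reference labeling uses mutual information normalized by max(H(A), H(B))
(natural logarithms, 0 log 0 = 0, identical single-cluster labelings
scoring 1) and the adjusted Rand index from binomial pair counts.  ARI is
negative on anti-correlated labelings (the independent 2x2 case gives
-0.5); it is not clamped to [0, 1].

## Synthetic data generator

`generate_shared_basis` draws from the exact model the estimator fits:
K_true random coefficient vectors are smoothed through (I + 5 D)^{-1},
orthogonalized, and scaled so each component function has unit standard
deviation over the grid; group scores scatter (sd `score_noise` = 0.3)
around `n_clusters` centroids of norm `separation` = 3 in score space.
Because components have unit spread, the separation directly sets
log-density amplitude; the defaults produce concentrated multi-basin
densities with log-density ranges around 10, emulating the concentration
of real Ramachandran basins.  Samples are drawn exactly on the grid by
cell multinomials with uniform within-cell jitter, so the truth grids are
exact under the estimator's own quadrature convention.  Default study
conditions: m = 20 groups, n_i = 75 points, K_true = 3, 3 clusters.

What the generator does not emulate: residue-level autocorrelation along
the chain (draws are i.i.d.), amino-acid- or neighbor-dependent structure,
measurement error in atomic coordinates, and heavy between-group imbalance.
Passing tests therefore demonstrate correctness of the machinery and the
statistical gain of collective estimation under the shared-basis model,
not performance guarantees on real structure corpora.  The von Mises
mixture generator provides draws from outside the fitted family for
misspecification checks.

## Backbone geometry

PDB files are parsed with Biopython (first model; altloc 'A' or blank;
residues missing any of N, CA, C skipped with a warning).  C-alpha steps
longer than 4.5 A mark chain breaks, across which no angle is computed.
Torsions follow the IUPAC sign convention (clockwise positive viewed down
the central bond), computed by the atan2 cross-product formula; they are
invariant under rigid motions and under reversing the point order, and
change sign under mirror reflection.  phi_i uses (C_{i-1}, N_i, CA_i,
C_i), psi_i uses (N_i, CA_i, C_i, N_{i+1}); theta_i is the planar angle of
three consecutive C-alphas and tau_i the torsion of four.  An idealized
helix builder (standard bond lengths/angles, constant phi/psi/omega)
provides a self-checking geometry fixture: the canonical alpha-helix
settings reproduce phi = -57 deg, psi = -47 deg exactly and give theta of
about 92 deg, tau of about 51 deg.

## Numerical choices and tie-breaks

- Quadrature: midpoint rule on cell centers; the normalizing constants use
  a max-shift before exponentiation.
- Newton systems are solved by Cholesky with a 1e-8 ridge fallback
  (theta blocks) or a 1e-8 ridge directly (score blocks).
- Degenerate lambda updates (df <= a - 1 or zero penalty trace) keep the
  previous lambda.
- SVD signs are fixed so each component's largest-magnitude loading is
  positive, making fits deterministic.
- Problem sizes in the test and acceptance runs (grids of 30-90 points per
  direction, 5-20 groups, 60-150 points per group, 20 replicates for the
  paired comparison) are chosen so the full pipeline demonstrates each
  property at comfortable statistical margins.

## Known limitations

- Ward on arbitrary non-metric dissimilarities can produce inversions
  (decreasing merge heights); heights are reported as computed.
- The effective-degrees-of-freedom formula covers the penalized Theta
  blocks only, not the unpenalized scores — consistent with the AIC it is
  compared against, but not a full model dimension.
- The bounded-direction KDE uses single reflection, adequate when the
  bandwidth is small relative to the range.
- The theta range of the pseudo-angle domain is a configuration choice
  (default 75-165 deg); points outside the configured domain are rejected
  rather than clipped.
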