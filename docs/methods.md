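# Methods

## The model

A constraint-based metabolic model consists of M metabolites, N reactions,
the M x N stoichiometric matrix S, and box bounds v_inf <= v <= v_sup on
the flux vector v (mmol gDW^-1 h^-1 in nominal units).  At steady state
internal metabolite concentrations are constant, so S v = m_dot with
m_dot = 0 unless stated otherwise, and the feasible set is the polytope

    L = { v : S v = m_dot,  v_inf <= v <= v_sup }.

Because N > M in any interesting network, L has infinitely many points, and
every downstream question ("which fluxes are plausible?", "which single
flux vector best explains enzyme data?") is a question about a
distribution over L.

## Expectation-propagation characterization of L

`FluxSpaceModel.fit()` approximates the uniform-over-L target in the
Boltzmann form

    p(v)  ∝  exp(-beta/2 ||S v - m_dot||^2) * prod_i 1[v_inf_i <= v_i <= v_sup_i]

by replacing each box indicator with a univariate Gaussian site
N(v_i; a_i, d_i).  The resulting Gaussian N(mu, Sigma) is refined by
expectation propagation: for each reaction in order, the site is removed
from the marginal (cavity), the cavity is multiplied by the exact box
indicator, and the site is re-chosen so that the marginal matches the mean
and variance of that truncated-Gaussian tilted distribution.  Sites are
updated sequentially with Sherman-Morrison rank-one covariance updates,
damped by a factor of 0.7 on the natural parameters; convergence is
declared when the largest (scale-normalized) natural-parameter change in a
sweep falls below `tol` (default 1e-6), with `max_iter = 2000` sweeps as
the budget.  Truncated-Gaussian moments are computed through
erfcx-stabilized tail formulas (`_truncnorm.py`) so that truncations a
dozen standard deviations into a tail remain exact; a cavity much wider
than the box falls back to the exact uniform limit, which also makes EP
*exact* when S is empty (marginals are then plain uniforms).

Parameters that matter:

* `beta` (default 1e10, dimensionless stiffness): weight of the quadratic
  stoichiometric energy.  The default makes S v = m_dot effectively hard;
  sampling enforces it exactly anyway (below), so beta only has to be
  large enough that the Gaussian mass off the subspace is negligible.
* `damping` 0.7, `tol` 1e-6, `max_iter` 2000: standard EP bookkeeping;
  non-convergence is reported on the results object, never silently.
* Observed exchange fluxes (e.g. a measured CO2 release rate) enter as
  additional Gaussian factors N(v_obs, sigma^2) with user-supplied small
  sigma, before EP runs.

## Exact-subspace sampling and the density p_v

The EP Gaussian restricted to the affine subspace v = v_p + K x (v_p a
particular solution, K an orthonormal null-space basis of S) has precision
K^T diag(1/d_i) K in the null-space coordinates x - only the sites
contribute, because S K = 0.  `FluxPosterior.sample()` draws from this
restricted Gaussian truncated to the box by coordinate-wise Gibbs
sampling, running one chain per requested sample in parallel (vectorized
across chains) from a common interior point found by linear programming,
for a fixed number of decorrelation sweeps (default 40).  Emitted samples
therefore satisfy S v = m_dot to machine precision and the box exactly;
both are asserted on every SampleSet.  `log_density()` evaluates the same
restricted quadratic form, unnormalized: only ratios within one posterior
are meaningful, which is all the downstream objective needs.

The parallel-chains design replaces one long thinned chain; it is what
keeps the replicated simulation studies (hundreds of posterior sample
sets per run) affordable.  Its residual bias is the finite decorrelation
length; the moment agreement with the independent Hit-and-Run oracle
(below) is the check that 40 sweeps suffice at the model sizes shipped
here.

## Hit-and-Run oracle

`hit_and_run()` draws asymptotically uniform points of L: a random
direction in null-space coordinates, the feasible chord of the box along
that direction, and a uniform step on the chord scaled by `jump` (the
fraction of the chord used per step, default 0.5).  For jump < 1 a
Metropolis reversibility check (reject when the reverse step would fall
outside the reverse proposal window) keeps the chain exactly
uniform-invariant; at jump = 1 no proposal is ever rejected.  The scaled
chain is unbiased but strongly autocorrelated (lag-1 autocorrelation near
0.9 in one dimension), so oracle comparisons in the tests use full-chord
steps, where the same chain length carries far more information; 0.5
remains the default for parity with common practice.

`moment_comparison()` reports the Pearson correlation across reactions of
marginal means and variances between any two sources (EP results object
or sample sets) plus the largest absolute mean gap.

## Predicting fluxes from enzyme abundances

Quantitative proteomics gives relative abundances E_i for the enzymes
catalyzing a subset of reactions (GPR rules map proteins to reactions:
complexes are limited by their scarcest member, AND -> min; isoenzymes
add, OR -> sum; a complex with an unquantified member is treated as
unobserved by default).  Among N_s sampled candidates the prediction is
the one minimizing

    Z = (1 / p_v) * sum_{i in obs} (E_i - |v_i|)^2,

the squared distance between observed abundances and absolute fluxes,
weighted by the posterior density of the candidate.  Densities are
exponentiated relative to the batch maximum - an order-preserving
rescaling.  Ties break to the lowest sample index.  Batch prediction over
a proteins x samples table derives per-column seeds as base_seed + column
index and records failed columns instead of dropping them.

Note the structure of the objective: the weight 1/p_v trades goodness of
fit against plausibility under the posterior.  A candidate that matches
the abundances slightly worse but sits in a higher-density region of L
can win, so the selected vector is deliberately *not* the nearest
neighbour of the abundance pattern.  This matters when interpreting the
recovery numbers below.

## Simulation-based validation

The inverse problem defines the ground truth: draw v_initial from the
posterior, build abundances through one of

* hyperbolic   E = |v / (1 - v)|,
* linear       E = k |v|, k ~ U(0.1, 3) per reaction,
* Hill         E = |v^n / (1 - v^n)|, n drawn per reaction from {2, 3, 4, 5},

then predict fluxes back from a subset of the abundances and score the
Pearson correlation between v_initial and the prediction over all N
reactions (not only observed ones - predicting the unobserved fluxes is
the point).  Flux vectors within 1e-6 of a singularity (v = 1, or
v^n = 1) are resampled, up to 100 times.  The slope k and the Hill
coefficient n are drawn once per reaction per replicate, so the enzyme
map is a fixed function within a replicate.  The incremental-inclusion
variant adds observed proteins one at a time in a seeded random order
over one fixed candidate set, tracking the correlation after every
addition; sharing the candidate set and v_initial across orders isolates
the pure ordering effect.

Problem sizes used by the shipped studies: the 15-reaction central-carbon
toy model (kernel dimension 4), N_s in {1e2, 1e3, 1e4}, 100 replicates
per condition, and 20 random inclusion orders.

## Null-space modular decomposition

An orthonormal kernel basis K (SVD, rank cut at 1e-10 of the largest
singular value) assigns each reaction a d-dimensional row vector.
Strictly coupled reactions have proportional rows; the angle between rows
(acute convention - absolute cosine - so that opposite-sign coupling
counts as coupling) is the dissimilarity for average-linkage hierarchical
clustering.  The module count at which to cut the dendrogram is a user
parameter; reactions with numerically zero rows are fully determined by
the constraints and are reported separately (module id 0) rather than
forced into a cluster.  A coverage report counts observed reactions per
module and flags uncovered modules.

## Synthetic fixtures

`random_cbm` plants modularity explicitly: parallel chains of
unit-stoichiometry reactions run from a shared source hub to per-pathway
sink metabolites (one input exchange, outputs round-robin over sinks),
and reactions beyond the chain skeleton are whole-pathway bypass
shortcuts.  Serial chain steps are strictly coupled by construction, so
each pathway is a genuine angle-zero block - that is what makes the
planted partition a fair oracle for the clustering.  A
`reversible_fraction` of internal reactions gets [-w, w] bounds instead
of [0, w]; the zero vector is always feasible.  `synthetic_proteome`
draws hidden flux vectors, maps them through the relations above,
distributes each reaction weighting onto the GPR leaves so that min/sum
evaluation reconstructs it exactly, and applies multiplicative log-normal
noise of standard deviation `noise_sd` (0 reproduces noiseless
simulations).

What the fixtures do not emulate: genome-scale size, non-unit
stoichiometry, cofactor coupling across pathways, shared isoenzymes
between reactions, absolute-vs-relative abundance calibration, and any
population structure across samples.  Passing tests therefore demonstrate
the machinery and its statistical behaviour at small scale, not
biological accuracy on real networks.

## Numerical choices and degenerate inputs

* Feasibility is checked before fitting by a maximal-margin linear
  program; an empty polytope raises immediately, and the interior point
  found is reused to start all samplers.
* Zero-width bounds (fixed fluxes) become effectively hard sites and are
  skipped during EP updates.
* Kernel dimension 0 (fully determined network) short-circuits sampling
  to the unique solution.
* Degenerate Hit-and-Run chords trigger direction resampling with a
  capped retry count.
* Site precisions are floored at 1e-12 rather than allowed to go
  negative, the standard EP safeguard.

## Known limitations

* **EP variance shrinkage.** For a direction whose exact marginal is flat
  (uniform), the EP fixed point underestimates the marginal variance: on
  the two-reaction segment polytope the sites equilibrate where the
  tilted truncation sits ~1.4 sd from the midpoint, giving marginal
  variance ~0.064 against the exact 1/12 ~ 0.083 (the test suite computes
  both).  Means are unaffected there by symmetry, and mean agreement with
  the uniform oracle is excellent across random models; variance
  agreement is weaker, consistent with EP's general tendency to
  underestimate marginal variances of boxy targets.  The exact-uniform
  limit with S empty is reproduced exactly, which isolates the effect to
  the coupling.
* **Density weighting bounds recovery.** Because Z trades fit for
  plausibility, recovery of a *randomly drawn* v_initial does not
  converge to perfection as N_s grows: the weight keeps preferring
  higher-density candidates over the closest match.  Recovery
  correlations on the toy central-carbon model span roughly 0.6-0.98
  across replicates with the hyperbolic relation (the acceptance script
  recomputes the exact spread), and the mean correlation increases with
  N_s while the median can plateau below 0.9.
* **Relation distortion.** The hyperbolic and Hill relations are
  non-affine maps between E and |v|; since Z compares the two on the same
  axis, the selected flux vector matches a distorted image of v_initial.
  Correlation survives because the maps are monotone over the sampled
  range, but exact recovery is not expected even at Z's global minimum.
* Hit-and-Run at jump 0.5 mixes slowly; treat short chains as biased-low
  information, not biased estimates.
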