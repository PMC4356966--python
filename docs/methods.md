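# Methods

## Model and conventions

The package works with the Ising density `p(σ) ∝ exp(b·σ + ½ σᵀA σ)` over
`σ ∈ {−1,+1}^n`.  The `½` quadratic-form convention is fixed throughout so
that each unordered pair `{i,j}` contributes `A_ij σ_i σ_j` exactly once;
all downstream formulas are stated consistently with it — the node-wise
conditional is `P(σ_i = +1 | σ_\i) = logistic(2(b_i + Σ_{j≠i} A_ij σ_j))`
(the factor 2 comes from the ±1 coding), and the loading construction is
`E = QΛ^{1/2}`.  Spins are ±1 everywhere in memory; files store 0/1 and the
boundary converts via `σ = 2y − 1`.

Because `σ_i² = 1`, adding `c·I` to `A` multiplies every unnormalised
weight by `e^{cn/2}` and cancels in all probabilities: the diagonal of the
connectivity matrix is not identifiable.  `shift_diagonal` uses the
*minimal* shift `max(0, −λ_min)`, placing the smallest eigenvalue at
exactly zero — any larger shift would also work, but the minimal one keeps
the spectrum well conditioned and makes the recorded `shift` value
interpretable.  Eigenvector signs are fixed by making each column's
largest-magnitude entry positive; when eigenvalues are tied within 1e-8,
only the spanned eigenspace is meaningful and tests compare projectors or
rotation-invariant functions, never individual columns.

## Latent (IRT) representation

With `A_psd = E Eᵀ`, the Gaussian identity
`exp(½‖Eᵀσ‖²) = (2π)^{-r/2} ∫ exp(σᵀEθ − ½‖θ‖²) dθ` factorises the joint
into a conditionally independent logistic (multidimensional IRT) model
`p(σ|θ)` and a latent density `f(θ) ∝ e^{−‖θ‖²/2} Π_i 2cosh(e_i·θ + b_i)`
that absorbs the partition function.  Integrating θ back out returns the
exact Ising distribution; this equivalence is the module's central
contract and is certified numerically by a Gauss–Hermite quadrature
oracle (64 nodes per dimension, tensor grids up to rank 2, networks up to
n = 20 by enumeration).  Quadrature is deliberately restricted to oracle
scale: the sampler, not quadrature, handles general rank.

`log 2cosh(x)` is evaluated as `|x| + log1p(e^{−2|x|})`, stable for
arbitrarily large couplings.

### Curie–Weiss special case

The fully connected network with every pairwise interaction equal to `a/n`
(mean-field scaling) has the rank-1 representation with tied loadings
`e_i = √(a/n)` and latent log density `−θ²/2 + n log 2cosh(√(a/n) θ)`.
Its curvature at the origin is `a − 1` for every `n`, so the latent
density is approximately normal for small `a`, flattens as `a → 1`, and
becomes bimodal for `a > 1` with modes separating as `a` grows.  The
mean-field scaling is a deliberate choice: it makes the transition occur
at `a = 1` independently of network size (an unscaled per-pair coupling
would move the transition to `a = 1/(n−1)` and change meaning with `n`).
Mode counting uses a uniform grid (≥ 2001 points spanning at least ±8
latent SDs), merges plateaus within 1e-12, and never counts boundary
points; mode-location checks use n = 10 nodes so that all modes of the
swept couplings fall well inside a [−10, 10] grid.

## Full-data-information sampler

Each Gibbs iteration draws the latent matrix exactly,
`θ_p ~ N(Eᵀσ_p, I_r)` (the main effects cancel from this conditional), and
then updates every scalar parameter by one independence MH step from its
partial conditional — likelihood × prior with the latent marginal (and
hence `Z`) omitted.  Discarding the latent marginal means the invariant
law of the parameters is a *partial* posterior, not the full posterior;
the package treats this partial posterior as the estimand and verifies
empirically that it concentrates on the truth (coverage, contraction and
recovery tests), rather than relying on the asymptotic argument that the
two posteriors share a Bayesian CLT.

For `w = b_i` the partial conditional's Bernoulli terms have logistic CDFs
with location `−θ_p·e_i` and scale ½; for `w = e_ir` location
`−(b_i + Σ_{s≠r} θ_ps e_is)/θ_pr` and scale `1/(2|θ_pr|)`, with the
response flipped when `θ_pr < 0` so every CDF is increasing (replications
with `θ_pr = 0` contribute a constant factor and are dropped).  The
order-statistic proposal draws one value from the prior and one from each
CDF and proposes the value whose rank is the total score plus one;
conditional on the realised below/above pattern, the proposal density is
the target with the prior and one observation swapped.  The acceptance
ratio is evaluated with that realised pattern — for a fixed pattern the
step is a standard MH kernel in detailed balance with the target, and the
overall kernel is a pattern-mixture of such kernels, hence invariant.
Correctness is additionally certified empirically against grid-normalised
densities (Kolmogorov–Smirnov distance of chain draws at fixed θ).

Choices that the underlying scheme leaves open:

- **Priors.**  Logistic(0, 1) on every `b_i` and `e_ir` by default: proper,
  symmetric, heavy enough not to bias moderate couplings, and in the same
  family as the observation CDFs so the prior draw is the natural
  "swapped" element of the proposal.  Normal priors are available.
- **Update granularity.**  Scalar updates, sweeping `b` then `E`
  row-major, with a fresh draw vector per parameter.  Acceptance rates are
  tracked per parameter over the recorded (post-burn-in) iterations; main
  effects typically accept near 1 and loadings substantially lower,
  matching the expected asymmetry between intercept-like and slope-like
  parameters.
- **Initialisation.**  Spectral warm start: loadings from the truncated
  eigendecomposition of the zero-diagonal scaled sufficient statistic
  `S/N`, intercepts from `arctanh` of the node means (exact under
  independence).  This is a method-of-moments-style starting value, not a
  shortcut around burn-in; a random initialisation is available and mixes
  to the same region.
- **Identifiability.**  The rank-r loadings are determined only up to
  right-rotation and sign.  Raw chains are stored unrotated; all
  quantitative comparisons use the rotation-invariant reconstruction
  `E Eᵀ` (off-diagonal), and `Chains.principal_loadings()` offers a
  deterministic reporting rotation via the eigendecomposition of the
  averaged reconstruction.
- **Seeding.**  One master seed feeds a single numpy `Generator` consumed
  in a fixed order, so identical configurations reproduce chains
  byte-for-byte.
- A non-finite MH log ratio rejects the proposal with a warning; a
  non-finite parameter state aborts the run naming the iteration.

The Curie–Weiss fit reparameterises through the tied loading `e` with
`a = n e²`, so a single order-statistic update per iteration handles all
`N·n` Bernoulli terms.

## Posterior predictive checks

`ppc_check` selects equally spaced post-burn-in draws, replicates a
dataset from each (drawing a fresh latent matrix `θ_p ~ N(Eᵀσ_p, I)` at
that draw's parameters by default — propagating latent uncertainty — with
reuse of stored θ available behind a flag), and averages the replicated
sufficient statistics into `S_rep`.  Reported are the residual `S − S_rep`
and the correlation over strictly-lower-triangle pairs; the diagonal is
excluded because it is the constant `N`.

## Synthetic data generators

The generators define the study conditions for every stochastic test.

- **Lattice** (`make_lattice`): side² nodes, 4-neighbour couplings,
  optional torus, zero fields — the near-linear-spectrum flavour that
  low-rank truncation should *not* recover.
- **Dense low-rank** (`make_dense_lowrank`): true loadings with an
  all-positive first column (general factor, entries uniform in
  (0.08, 0.38)) and zero-sum block-contrast columns (alternating-sign
  contiguous blocks, magnitudes jittered around a scale of 0.12).  The
  defaults put the leading eigenvalue near 2 at n = 30 with secondary
  components several-fold smaller — a dominant general factor with
  visible but clearly secondary contrasts, the profile of dense
  social-science networks, so that a rank-1 fit already captures most of
  the structure of `S` while higher ranks add the contrast detail.  The
  rank-recovery experiments instead pass a stronger contrast scale (0.22)
  so that the secondary component is firmly identifiable from N = 2000
  replications; with the default weak contrasts that component's
  eigenvalue (~0.3) sits near the resolution limit of that sample size,
  which is an effect-size statement about the data, not about the
  sampler.  Main effects are uniform in ±0.2.
- **Curie–Weiss** (`make_curie_weiss`): coupling `a/n` everywhere.
- **Augmented generator** (`generate_augmented`): exact Gibbs on the
  joint (σ, θ) — the only way to sample large-n models here without the
  partition function.  The default runs one independent chain per
  replication (100 alternations each), guaranteeing exchangeable rows; a
  thinned single long chain is available behind a flag.  At enumerable
  sizes its output matches exact-sampler moments within Monte-Carlo error.

What the generators do **not** emulate: real networks' missing entries,
item-level guessing/asymmetry, model misspecification (truths here are
exactly low-rank plus optional small dense noise), and sample sizes of the
order of national-assessment data.  Passing tests therefore certify the
machinery — representation, sampler, checks — under correctly specified
low-rank truth at desk scale, not robustness to misspecification.

## Problem sizes and numerical tolerances

Enumeration-based oracles are guarded at n ≤ 20 (≈10⁶ states); quadrature
oracles at rank ≤ 2.  The end-to-end experiments use n = 20, r = 2,
N = 2000 (900 iterations, 250 burn-in) for recovery; n = 30, r = 3,
N = 2000 (450 iterations, 150 burn-in, 60 predictive replications) for the
predictive checks; and 10⁴ post-burn-in draws for chain-vs-grid
certification — sizes at which the posterior is informative while a full
test run stays in the minutes range.  Exact identities are asserted at
1e-10…1e-12, quadrature equivalences at 1e-6, spectral round trips at
1e-8, and stochastic checks at conventional 3–4 SE bounds (KS < 0.05 for
10⁴ dependent-but-high-acceptance draws).

## Known limitations

- Rank selection is the user's: no scree-elbow automation.
- No adaptive MH tuning, tempering, structured/regularising priors, or
  convergence diagnostics beyond acceptance rates and raw traces.
- The partial posterior's finite-sample spread is not guaranteed to match
  the full posterior's; agreement is verified empirically at the tested
  sample sizes only.
- Potts/multi-category states, mixed discrete-continuous models and
  incomplete networks are out of scope.
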