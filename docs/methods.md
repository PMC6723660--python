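# Methods

## Model

Let `x ∈ R^{d+1}` be a gene-expression vector with a leading bias component
fixed at 1, and `y ∈ {−1, +1}` the drug-response label (+1 sensitive,
−1 resistant).  The model assumes a true linear rule `y = sign(βᵀx)` whose
observed labels have been flipped independently with probability ε:

    p(y | β, ε, x) = ε (1 − H(y βᵀx)) + (1 − ε) H(y βᵀx),

with `H(t)` the Heaviside step (defined as ½ at t = 0, the limit of the
steep sigmoid).  Because this likelihood is a function of the *sign* of the
margin only, the posterior depends on the data only through which samples a
candidate hyperplane misclassifies; rescaling β changes nothing, and
outliers carry no extra leverage.

Sparsity comes from a spike-and-slab prior: per-gene indicators
`z_j ∈ {0, 1}` with `β_j = 0` exactly under the spike and
`β_j ~ N(0, σ_j²)` under the slab.  The bias indicator is fixed to 1 — a
classifier needs its intercept, and this removes an unidentifiable
hyperparameter from the prior.  The indicators follow a Markov random field
over the gene network `G = (V, E)` with edge weights ω(u,v) ≥ 0:

    log p(z | G, λ, γ) = λ Σ_j z_j − γ zᵀ L z + const,

where `L` is the degree-normalized Laplacian: `L(u,u) = 1` for connected
nodes (0 for isolated ones) and `L(u,v) = −ω(u,v)/√(d_u d_v)` across edges,
with weighted degrees `d_u = Σ_v ω(u,v)`.  Since `zᵀLz` measures the
degree-normalized disagreement of z across edges, the **negative** sign
makes γ a smoothing penalty: network neighbours prefer to be included or
excluded together.  (A positive-sign variant, which would reward
disagreement, is available through `coupling_sign=+1` for comparison
experiments; the package default is the smoothing sign, which is the only
one consistent with the prior's stated purpose.)  Isolated genes feel only
the λ term, so genes absent from the network are handled by adding them as
isolated nodes.  Where the linear and matrix forms of the edge penalty
disagree on the degree normalization, the Laplacian (√(d_u d_v)) form is
used, because all computations go through `L`.

The flip rate carries a Beta(a₀, b₀) prior, truncated to [0, ½]: flip rates
above one half merely relabel the classes, so the identifiable range is
capped.  Defaults a₀ = 1, b₀ = 8 (prior mean 1/9) follow the evaluation
protocol of the drug-response setting this package implements.

## Expectation propagation

The posterior over (β, z, ε) is approximated by

    Q(β, z, ε) = N(β; m, V)  ×  Π_j Bern(z_j; p_j)  ×  Beta(ε; a, b)

with **full covariance** V.  Three factor groups become EP sites:

* **Likelihood sites** (one per observation): scalar Gaussian sites acting
  along the direction `a_i = y_i x_i`.  The tilted moments of the margin
  against the mixture factor `ε̄ + (1−2ε̄)H(u)` are closed-form (probit-style
  α/κ corrections with the noise floor ε̄ taken from the current Beta mean);
  the rank-one covariance update uses Sherman–Morrison.
* **Spike-and-slab sites** (one per gene): Gaussian × Bernoulli sites.  The
  tilted distribution mixes the slab branch (Gaussian algebra) with the
  spike branch (point mass at zero); its matched mean/variance and the
  slab-vs-spike log evidence update the Gaussian site and the z-site
  respectively.
* **Edge sites** (one per network edge): Bernoulli-pair sites for the
  coupling `exp(c_uv z_u z_v)` with `c_uv = 2γ ω(u,v)/√(d_u d_v)`; the
  exact pairwise tilted marginals give the messages.

The per-gene field `λ − γ L_jj`, the Gaussian slab on the bias, and the Beta
prior on ε are exponential-family factors and stay exact.  Once per sweep
the Beta factor is refreshed from the per-observation posterior
responsibilities of having been flipped, `q_i = ε̄(1−Φ)/Z`, giving
`a = a₀ + Σ q_i`, `b = b₀ + Σ (1−q_i)` — a closed-form update that keeps the
ε estimate conjugate.

Numerical choices:

* damping 0.5 on natural parameters (the standard cure for EP oscillation
  with MRF-coupled sites), tolerance 1e−4 on the maximum absolute change of
  any mean, variance, inclusion probability or the ε mean, max 200 sweeps;
* sites are swept in random order, reshuffled every sweep; each of the three
  site groups draws its order from an **independent seeded stream**, so the
  sweep order of one group is invariant to the sizes of the others (this is
  what makes the γ = 0 fit bit-identical to the fit on the edgeless
  network — the SBC reduction);
* a site whose cavity would have non-positive variance is skipped that sweep
  and counted in `skipped_updates`, not clamped — skips surface pathologies
  instead of hiding them;
* the covariance is recomputed exactly from the site parameters at the end
  of every sweep, so Sherman–Morrison round-off cannot accumulate;
* non-convergence is reported through the `converged` flag and never raised:
  hyperparameter grid search has to survive hard settings.

Prediction uses the Gaussian-approximate predictive integral

    p(y = +1 | x) = E[ε] + (1 − 2 E[ε]) Φ_N( m_x / s_x ),

with `m_x` the posterior-mean margin and `s_x²` the predictive variance
`xᵀVx`.  Degenerate `s_x = 0` with zero margin returns ½; ties at the 0.5
decision threshold are labelled +1.

### Known limitation: small-sample bias of EP inclusion marginals

On tiny instances (d ≤ 3, n ≤ 8) where the posterior can be computed
exactly, EP's inclusion marginals and predictive probabilities typically
deviate from the exact values by a few hundredths, but on diffuse posteriors
(weak sparsity field, noisy labels) the deviation can reach ≈ 0.1–0.2.  The
mechanism is structural: the single Gaussian over β must blend the spike and
slab branches, so the spike-branch evidence is read off a Gaussian fitted to
the posterior bulk — the classic under/over-confidence of single-Gaussian EP
for mixture posteriors.  Four factorizations were evaluated against the
brute-force oracles (fully factorized Gaussian; full-covariance with
spike-and-slab sites; a product parameterization β_j = z_j·w_j with direct
data-to-z messages; and full-rank sites with exact per-site enumeration over
z): all converge to damping-independent fixed points with the same order of
deviation, and the full-covariance spike-and-slab formulation — the one this
package ships — had the best predictive accuracy and the most robust
convergence.  The two independent oracles agree with each other at the
Monte-Carlo noise level on every fixture, which is the evidence that the
deviation is a property of EP, not an implementation error.  For the
package's intended use — ranking genes and sub-networks by relative
inclusion — this calibration bias is immaterial, as the parameter-recovery
results below show; for exact posterior probabilities at toy sizes, use
`nbsbm.oracle`.

## Reference posteriors (oracles)

`exact_posterior_small` (guard: d ≤ 10, n ≤ 12) enumerates all 2^d
inclusion vectors; per configuration the ε-integral is a 64-node
Gauss–Legendre quadrature against the truncated Beta prior on [0, ½]
(the likelihood is a polynomial ε^k (1−ε)^{n−k} in ε given the error count,
so the quadrature is effectively exact), and the β-integral is Monte Carlo
from the slab prior with common random numbers across configurations.
Standard errors come from 10 independent batches.

`gibbs_sample` (guard: d ≤ 50) is a blocked Gibbs sampler over (z_j, β_j)
pairs, the bias, and ε.  Because each observation's likelihood factor
switches between ε and 1−ε at a single breakpoint along any one coordinate,
the univariate conditional of β_j is a piecewise Gaussian: the sampler
enumerates the inter-breakpoint intervals, weights each by its error count
and slab mass, picks an interval, and draws a truncated normal within it.
This marginalizes the per-sample flip indicators analytically (the error
count of the current state still drives the conjugate truncated-Beta update
of ε) and lets the chain cross decision boundaries that a naive
auxiliary-indicator scheme would freeze.  Burn-in defaults to 20% of the
iterations; summaries carry batch-means standard errors.

The two oracles are algorithmically independent — different integration
strategies, different code paths — and their agreement on shared fixtures
is the foundation of the EP validation.

## Training pipeline and evaluation protocol

* **Standardization**: per-gene zero mean, unit *population* standard
  deviation on training data (this is what makes the default unit slab
  variances scale-appropriate); zero-variance genes are flagged and set to
  0; statistics are replayed at test time, and genes missing from new data
  are imputed at the standardized mean (0).
* **Grids**: λ takes 500 log-even values on [e⁻⁵, e²], γ on [e⁻⁵, e¹]
  ("evenly" is read in the log domain since the endpoints are e-powers
  spanning orders of magnitude; linear spacing is a config option).
  Selection minimizes the training error rate; ties break toward larger λ,
  then larger γ — the sparser, smoother model.  Because a full 500 × 500
  joint search is a quarter-million EP fits, the CLI defaults to a budgeted
  coarse-to-fine search (25 × 25 coarse grid, then the full-grid points in
  the winning cell); the exhaustive joint grid remains available
  (`--full-grid`).  An inner-CV selection mode was considered and left out:
  training-error selection is the protocol this package implements.
* **Cross-validation**: stratified 5-fold × 5-repeat by default, folds
  reshuffled per repeat from the seed.  Stratification is necessary, not
  cosmetic: with five resistant lines out of sixteen, unstratified folds can
  be single-class and AUC undefined.  Standardization and hyperparameter
  selection run inside each training fold; nothing from a test fold touches
  training.
* **ROC/AUC**: AUC is Mann–Whitney concordance (ties half); mean ROC curves
  come from vertical averaging on a fixed 101-point FPR grid with median and
  interquartile bands.
* **Method comparison**: matched per-fold AUCs are compared with the
  Wilcoxon **signed-rank** test (the paired test; the rank-sum test is kept
  for unpaired comparisons).  Zero differences are dropped; for ≤ 25
  non-zero pairs the exact sign-flip distribution is computed by
  convolution over midranks (doubled to stay integral under ties), which the
  stock implementations do not provide in the presence of ties; beyond 25
  pairs the normal approximation is used.

## Synthetic data

The generator mirrors the modular structure of disease-specific driver
networks: a planted-partition graph (`n_modules × module_size`, within- and
between-module edge probabilities 0.3 / 0.02 by default — average degree of
order 4–5, comparable to curated signaling networks), expression i.i.d.
standard normal, and a ground-truth classifier supported on whole modules
with weights ±effect_size (default 1.0, a one-standard-deviation shift per
informative gene).  The intercept is the negated median margin, giving exact
class balance; labels then flip independently at `flip_rate` (default 0.1).
An optional within-module equicorrelation (`within_module_rho`) adds
correlated expression for robustness experiments.  IC50-based labelling uses
the 200 nM convention: strictly below threshold is sensitive (+1); the
boundary value counts as resistant (a documented convention — the rule's
source leaves the boundary unstated).

Because the generator implements the model's own assumptions exactly,
recovery results measure inference quality, not model misfit.  What passing
synthetic tests do *not* establish: robustness to the quantile effects,
batch structure and gene–gene correlation of real microarray/RNA-seq data,
or to misspecified networks — those require the real datasets this package
deliberately does not bundle.

## Problem sizes used in the shipped checks

The test suite and the acceptance script validate EP against the exact
oracle on 20–24 instances with d ∈ {2, 3}, n ∈ {6, 8} (40 000 Monte-Carlo
draws, 8 000 Gibbs iterations), run parameter recovery on 6 modules × 10
genes with n = 120 over 10 seeds, the network-benefit comparison at n = 60
over 10 seeds with γ tuned on a 5-point log-even grid, and the CV protocol
on a 12-gene, 60-sample instance.  These sizes were chosen so that the full
pipeline — including both oracles — re-runs from scratch in a few minutes
on a single core.
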