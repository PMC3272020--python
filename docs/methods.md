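# Methods

## Model and assumptions

`dmmix` treats a count matrix `X` (N samples × S taxa, non-negative
integers) as multinomial draws from latent per-sample community
compositions, which are themselves drawn from a finite mixture of Dirichlet
distributions. The model assumes (i) reads are sampled with replacement
from the community, so within-sample noise is exactly multinomial in the
library size `J_i`; (ii) each sample derives from exactly one metacommunity;
(iii) between-sample variation within a metacommunity is Dirichlet, i.e.
fully described by a mean composition `m_k` and a single precision `θ_k`
(no taxon-specific covariance beyond the simplex constraint); and (iv) taxa
are exchangeable a priori under the Gamma hyperprior. Sparsity is handled
naturally: a zero count contributes `Γ(α_j + 0)/Γ(α_j) = 1` to the evidence
ratio, and all-zero samples have evidence 1 (they are accepted with a
warning and carry no information about Θ).

All evidence arithmetic is in log space through `gammaln`; no Gamma value is
ever exponentiated, so library sizes of 10⁴⁺ reads are routine. The
multinomial coefficient is included in reported evidences by default, making
them true probabilities that sum to one over count space (the normalisation
test exploits this); it is constant in the parameters, so including it
changes no fit and no model comparison at fixed data, and the convention is
recorded in the model-file metadata.

## Fitting

The maximum-posterior fit (MPE) maximises the dataset log evidence plus the
log Gamma(η, ν) hyperprior over each `α_kj`, via EM:

- **E-step** — responsibilities `z_ik ∝ π_k p(x_i | α_k)`, log-sum-exp
  stabilised.
- **M-step, weights** — closed form `π_k = (1/N) Σ_i z_ik` (a uniform prior
  on π is assumed).
- **M-step, components** — BFGS over `λ_k = log α_k` of the
  responsibility-weighted log evidences plus hyperprior terms, with the
  analytic gradient
  `α_j [Σ_i z_ik(ψ(α_j + x_ij) − ψ(α_j) + ψ(θ) − ψ(θ + J_i))] + η − ν α_j`,
  warm-started from the previous iterate. Target gradient sup-norm 1e-5
  (`optimizer_grad_tol`); non-convergence returns the best iterate with a
  warning flag rather than failing.

Convergence is declared when the relative change of the exact log posterior
falls below `em_rel_tol` (default 1e-6), capped at 250 EM cycles. The
`lower_bound_trace` records the exact log posterior (dataset log evidence
plus log hyperprior) after each full cycle: this is the quantity EM provably
never decreases, and the monotonicity invariant is asserted on it. The
entropy-free expected complete-data objective (`expected_log_posterior`) is
kept as the documented per-step EM objective but can dip by optimiser noise
near convergence, so it is not the traced quantity.

Initialisation (a genuinely open choice) defaults to k-means with k-means++
seeding on row-normalised relative abundances, giving hard initial
responsibilities; `random_soft` draws responsibility rows from a symmetric
Dirichlet instead. Initial `λ` per component is
`log(max(weighted mean relative abundance × S/2, 1e-6))` — scale-aware and
finite for absent taxa. Ties (k-means and responsibility argmax) break to
the lowest index for determinism; identical config and seed reproduce the
fit bitwise. When K exceeds N, k-means is impossible and the fit falls back
to the random-soft initialisation with a warning. Components that lose all
responsibility (< 1e-8 total) are retained with hyperprior-dominated
parameters (`α → η/ν`) and flagged.

Hyperprior defaults are η = ν = 0.1 (mean 1, vague): the Gamma hyperprior's
role is numerical — it keeps `α` for never-observed taxa finite and positive
— and the source work prints no values, so the defaults are deliberately
weak, config-exposed, and recorded in every output. `n_restarts` defaults
to 1 because the k-means initialisation is already deterministic and
effective on count mixtures; restarts derive their seeds from the run seed.

## Model selection

The Laplace approximation evaluates
`log p(X|K) ≈ log posterior(Θ*) + (P/2)·log 2π − ½·log det H`, with `H` the
analytic Hessian of the negative expected log posterior at the MPE,
responsibilities frozen at their converged values (this matches the surface
EM maximised; the z-dependence of Θ is not differentiated through). `H` is
block diagonal: per-component dense S×S λ-blocks with digamma/trigamma
curvature plus the `ν·exp(λ)` hyperprior diagonal, and by default an
additional (K−1)-dimensional block for softmax-reparameterised weights,
`N(diag(π) − ππᵀ)` on the free coordinates; `P = K·S + K − 1` counts exactly
the parameters present (the weight block can be disabled, restricting `P` to
`K·S`; both conventions are labelled in the output). The negative of the
approximate log evidence is reported so a better fit is a smaller number.
Log determinants come from an eigendecomposition with eigenvalues floored at
1e-10; indefinite or near-singular Hessians flag the result instead of
raising, so a `select_k` sweep always completes. AIC/BIC are deliberately
not used for selection.

Credible intervals use `σ_kj = sqrt([H⁻¹]_kj,kj)` on the λ scale; the
interval endpoints `exp(λ ± 2σ)` are mapped to relative abundance by
renormalising against the component's other parameters and reported in
percent. The λ-scale endpoint transform (rather than a direct
abundance-scale variance) keeps endpoints inside [0, 100] by construction.

## Metacommunity summaries and classification

Hard cluster assignment takes the argmax responsibility (ties to the lowest
index). The difference-to-reference statistic for component k is
`d_k = 100·Σ_j |m_kj − m_ref,j|`, ranging 0–200%; per-taxon contributions
`c_j = 100·Σ_k |m_kj − m_ref,j|` are ranked with a cumulative share column.
A component's "posterior mean" is `m_k = α_k/θ_k` at the MPE; a class-level
mean is the weight-averaged `Σ_k π_k m_k`. Component sets from different
fits are matched greedily by Bray–Curtis distance between mean vectors
(smallest distance claimed first, one-to-one when |A| ≤ |B|); the full
distance matrix is always returned so the greedy choice can be audited.
Percentages are rounded only at presentation.

The generative classifier fits one mixture per class (each K selected by
Laplace evidence in 1..k_max), sets class priors to observed frequencies,
and scores new samples in log space. Leave-one-out validation refits every
fold, by default re-running K selection per class per fold; a fast mode
reuses the full-data K and is labelled in the output. The classification
threshold comparison is `≥`. ROC curves sweep thresholds from above the
largest observed sample probability down to 0, stepping at each distinct
probability with the `≥` rule, so they start at (0, 0) and end at
(100, 100); AUC is the trapezoidal area. Multi-class data use the same
structure with one mixture per class; binary-only outputs (ROC, thresholded
confusion) require a designated positive class.

## Synthetic data

The generator draws exactly the chain the model assumes: component ~ π,
composition ~ Dirichlet(θ_k m_k), library size from a configurable law,
counts ~ Multinomial. The default library-size law is log-normal with
median 1600, σ = 0.8, truncated to [50, 11000] — emulating the spread of
real 454-era amplicon surveys (tens to ~10⁴ reads, median ~1600). Sparsity
is emergent from small θ and skewed means rather than zero-inflation, so
generated data stay inside the model class; consequently the tests
demonstrate correct recovery *within* the model, not robustness to real-data
violations such as sequencing error, taxonomic misclassification, or
covariance structure the Dirichlet cannot express.

Benchmark specs fix the study conditions used throughout the tests and the
acceptance script:

- **K=1**: S = 10, N = 100, θ = 50, dominated rank-abundance mean
  `m ∝ exp(−0.8 j)` (top taxon ~55%, the shape typical of gut genus
  tables). At these N and θ the sampling error of the mean is ~0.02 L1,
  comfortably inside the 0.03 recovery tolerance; a flat mean would put the
  expected error at the tolerance itself.
- **K=2**: S = 20, N = 200, θ = (50, 50), equal weights, disjoint top-5
  taxa per component.
- **K=3**: S = 12, N = 150, θ = 100 each, equal weights, disjoint top-4
  taxa.
- **Two-class**: single-component classes, S = 10, θ = 100, disjoint top-3
  taxa, 20 samples per class.

`recovery_report` matches fitted to true components by Hungarian assignment
on L1 mean distance before scoring.

## Problem sizes and numerical choices

The acceptance script (`scripts/acceptance.py`) uses: exhaustive
normalisation over S ≤ 3, J ≤ 6 (50 count vectors, tolerance 1e-10); 10⁵
Monte-Carlo Dirichlet draws (3 SE agreement); a 10-sample two-taxon fit for
the quadrature comparison (Laplace is asymptotic — at this size it agrees
with adaptive quadrature to ~3%, within the 5% band; much smaller datasets
leave the posterior visibly non-Gaussian); 5 seeded K=1 recovery runs
(averaged to suppress Monte-Carlo noise in the reported error); and 20
seeded model-selection runs per scenario. Everything derives its randomness
from the `--seed` argument. The full run takes on the order of half a
minute on one core.

## Known limitations

- The Laplace approximation degrades for tiny N or strongly multimodal
  posteriors; flagged Hessians (floored eigenvalues) signal when the
  reported evidence is unreliable.
- EM finds local optima; well-separated mixtures are recovered reliably
  from the k-means start, but overlapping components may need
  `n_restarts > 1`.
- The per-fold K re-selection makes exact leave-one-out quadratic in N
  times the cost of a selection sweep; use the fast mode for large N.
- BIOM support covers the JSON (1.0) dialect only.
- No phylogeny-aware distances, ordination, or diversity indices; the
  package emits TSVs that downstream tools can ordinate or plot.
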