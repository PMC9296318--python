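# Methods

## Model and likelihood

A measurement is modelled as a draw from a two-component mixture of
generalized-exponential (GE) distributions,

    f(x; Ω) = Σᵤ πᵤ λᵤ θᵤ (1 − e^{−θᵤx})^{λᵤ−1} e^{−θᵤx},
    F(x; Ω) = Σᵤ πᵤ (1 − e^{−θᵤx})^{λᵤ},

with Ω = (λ₁, θ₁, λ₂, θ₂, π₁), shapes and rates positive, π₁ ∈ (0, 1).
The GE family is flexible on (0, ∞): λ < 1 gives a density unbounded at the
origin (common for trace concentrations), λ = 1 the exponential, λ > 1 a
unimodal density with interior mode.

A record is either *observed* (value x) or *left censored* (known only to
lie below its detection limit L).  Every censored record stores its own
limit, and the censored likelihood factor is the component CDF at that
limit.  When all limits coincide this reduces to the single
`(1 − e^{−θL})^{λk}` factor of the common-limit formulation; with several
limits (both bundled datasets have them) the per-record form is the only
one that is defined at all.

Three labeling regimes are supported by `loglik` and the fitters:

* **fully labeled** — component membership known for every record; the
  likelihood factorizes over components and the mixing weight enters only
  through the counts (`loglik_labeled`);
* **unlabeled** — each observed record contributes the mixture density,
  each censored record the mixture CDF at its limit (`loglik_mixture`);
* **partially labeled** — e.g. censored records allocated by which of two
  detection limits produced them, observed records left unlabeled.

## Synthetic data

`synthetic_data.simulate` draws n labeled values from the mixture (a
uniform draw against π₁ selects the component, inverse-CDF sampling inside
the component), then censors.  Two limit modes:

* **quantile** (default): the limit is the k-th pooled order statistic with
  k = round(censor_rate · n); the k smallest values become nondetects, so
  the censored count is exact in every replication.  This makes Monte-Carlo
  cells with a *target censoring rate* well defined.
* **fixed**: a user-supplied limit; the censored count is then binomial —
  the mode that mimics a real instrument.

True labels are retained on censored records so the labeled likelihood has
its per-component censored counts.  What the generator does **not**
emulate: serial correlation (weekly monitoring data are autocorrelated),
measurement error above the limit, covariates/seasonality, and
batch-varying detection limits within one simulated sample.  Passing tests
therefore demonstrate correctness of the estimators under the stated
sampling model, not robustness to those real-data features.

Default study conditions follow the canonical parameter sets
S1 = (0.5, 1.2, 0.75, 1.5, 0.45), S2 = (0.5, 1.2, 1.5, 3.0, 0.45),
S3 = (1.0, 2.4, 0.75, 1.5, 0.45).

## Priors

`make_prior` builds "prior-means" hyperparameters: each Gamma prior has
rate c and shape c·s·(true value), hence mean s·(true value); the Beta
prior on π₁ is Beta(c·s·π₁, c·(1 − s·π₁)).  s = 1 centres every prior on
the truth (the main prior), s = 1.2 / 0.8 shift all prior means by ±20 %
for sensitivity analysis.  The concentration default c = 2 is weakly
informative: correct mean, prior variance of order the parameter squared,
so the prior contributes the weight of roughly two pseudo-observations.

## Classical estimation

**Labeled MLE.**  π̂₁ = (k₁+m₁)/n in closed form.  Per component, the score
in λ solves exactly to λ(θ) = −m / (A(θ) + C(θ)) with
A = Σ_obs log(1 − e^{−θx}) and C = Σ_cens log(1 − e^{−θL}); the remaining
one-dimensional profile in log θ is maximized by bounded scalar search and
polished with safeguarded Newton steps on the full (λ, θ) system using the
analytic gradient and Hessian, leaving the score below 1e−6.  The inverse
observed information at the optimum is returned for downstream use.

**EM.**  For unlabeled data, responsibilities use the component *density*
for observed records and the component *CDF at the limit* for censored
records — the correct ingredient for left censoring (a survival-function
term would describe right censoring).  The M-step updates π by the mean
responsibility and each component by the same profile-plus-Newton fit with
fractional weights.  Convergence: maximum absolute parameter change below
1e−6 or 500 iterations.  The observed-data log-likelihood is recorded every
iteration and is nondecreasing (asserted in tests).  Initialization
default: records split at the median of values/limits, λ = 1,
θ = 1/submean, π = ½; the simulation harness instead starts EM at the
generating values so that its cells measure estimation error rather than
initialization robustness.

Degenerate trajectories — a component weight collapsing, or a component
estimate running away beyond [1e−6, 1e6] (possible on tiny unlabeled
samples where one component seizes a few nearly-identical points) — raise
`DegenerateComponentError` naming the component; the harness counts these
as failed replications and never imputes them.

**k components.**  `fit_k_gem` generalizes the same EM to any k (k = 1 is
a plain censored GE fit), with optional jittered restarts; 3k − 1 free
parameters feed the information criteria.

## Lindley approximation

For a posterior ∝ exp(l(Ω) + H(Ω)), the posterior expectation of a smooth
W(Ω) expands around the MLE as

    E[W] ≈ W(Ω̂) + ∇W′ Σ D + ½ tr(∇²W Σ) + ½ ∇W′ Σ q,
    q_k = Σ_{ij} T_{ijk} Σ_{ij},

with Σ the inverse observed information, D = ∇H, and T the third-derivative
tensor of l, all at Ω̂.  SELF estimates take W = Ωᵢ; ELF estimates take
W = 1/Ωᵢ (∇W = −Ωᵢ⁻² eᵢ, ∇²W = 2Ωᵢ⁻³ eᵢeᵢ′) and invert the result.  One
generic kernel (`lindley_correction`) implements the expansion; a constant
W receives zero correction by construction.

Because the labeled log-likelihood separates into a π₁ term plus one term
per component, Σ and T are block structured and **all derivatives are
closed form** (the building block is log(1 − e^{−θx}) and its first three
θ-derivatives).  A Richardson-extrapolated finite-difference tensor
(`third_tensor_fd`) serves as an independent cross-check in the tests, not
as the primary path.

Regime of validity: the correction is O(1/n) (verified empirically with
log-log slope −1), so the approximation is accurate when the likelihood
dominates and the MLE is interior and moderate.  It degrades for very small
component counts, for MLEs far from the prior centre, and — less obviously
— for *strong* priors: the expansion keeps the prior only through its
gradient at the MLE, so a sharply curved prior is linearized and
overshoots.  Estimates that leave the parameter domain raise rather than
clip.

## Conditional-draw importance sampler

With labels known, the posterior kernel factorizes into

    π₁   ~ Beta(k₁+m₁+μ₁, k₂+m₂+τ₁)                         (exact)
    θᵤ   ~ Gamma(mᵤ+μ₃ᵤ, τ₃ᵤ + Σ_obs x)                     (proposal)
    λᵤ|θᵤ ~ Gamma(mᵤ+μ₂ᵤ, κ₁ᵤ(θᵤ)),  κ₁ᵤ = τ₂ᵤ − A_ᵤ(θᵤ)

times a residual factor from the censored records and the (λ−1)-power of
the density.  Draws are i.i.d. across iterations; estimates are
self-normalized importance-sampling averages.  The log-weight is the log
posterior kernel minus the log proposal density:

    log w = Σᵤ [ λᵤ C_ᵤ(θᵤ) − A_ᵤ(θᵤ) − (mᵤ+μ₂ᵤ) log κ₁ᵤ(θᵤ) ] + const.

The last term — the θ-dependent normalizer of the λ proposal — is
essential: without it the weighted average targets a different (biased)
distribution.  With it, the sampler's SELF estimates match exact 2-D
quadrature of the block posterior to Monte-Carlo accuracy (asserted in the
tests).  At 0 % censoring the weight is λ-free, i.e. the λ-coordinate is
integrated exactly.

Defaults m = 11 000 draws with the first m₀ = 1 000 discarded.  For this
sampler the discard is a no-op thinning (draws are independent); it is kept
so that runs are comparable with burn-in-style workflows, and because the
*augmented* sampler below genuinely needs it.

Known limitation: the θ proposal ignores the (λ−1)-density term, so its
centre drifts away from the posterior as mᵤ grows; the importance weights
are heavy-tailed (for uncensored components, provably infinite-variance
from the small-θ tail, which censored-record factors temper).  In practice
the effective sample size is comfortable for small datasets but can
collapse to a handful of draws at n ≈ 200, inflating the Monte-Carlo noise
of SELF/ELF estimates.  `estimate` warns when ESS < 10.  ELF ≤ SELF
coordinate-wise on every run (weighted harmonic–arithmetic mean
inequality).

**Data augmentation** (`sample_posterior_augmented`): for unlabeled data,
each sweep draws labels from the current responsibilities (CDF-at-limit
for censored records), then performs one labeled conditional draw.  The
label chain is Markov, so the burn-in discard is real here; retained label
allocations are exposed for diagnostics.

## Simulation harness

`run_cell` fixes (parameter set, n, censoring rate, prior, method),
replicates simulate-and-fit R times, and reports per coordinate: ARE
(mean of estimate/true), MSE (mean squared error), SMSE (MSE/true), each
with Monte-Carlo standard errors, plus failure counts.  Per-replication
seeds derive deterministically from the cell's base seed, so any cell is
bit-reproducible, and two cells sharing a base seed see *identical
underlying samples* — which the test suite exploits as a common-random-
numbers pairing when comparing censoring rates.

Desk-scale defaults used by the tests and the acceptance script: R = 2000
replications for MLE/EM/Lindley cells, R = 500 with 2 000 retained draws
for sampler cells.  These keep the full suite within minutes while the
cell means carry Monte-Carlo errors small enough for the stated checks;
the harness accepts any larger R and m for full-scale runs.

Findings worth knowing before interpreting such tables:

* the unrestricted MLE/EM of a GE *shape* parameter from ~7–15 observed
  records is strongly heavy-tailed — small-sample MSEs are dominated by
  rare large λ̂ excursions rather than by the bulk;
* with priors centred on the truth, Bayes estimates can *gain* accuracy as
  censoring increases (less likelihood information ⇒ harder shrinkage
  toward a prior that happens to be correct), so "MSE grows with
  censoring" is not a universal law across estimators;
* the sampler's ESS collapse at larger n can make its MSE non-monotone in
  n even though the posterior itself concentrates.

## Model selection and real-data workflows

AIC = 2p − 2ℓ̂ and BIC = p ln n − 2ℓ̂ with p = 3k − 1.  The KS statistic
substitutes nondetects by their detection limits (the simple, reproducible
convention of nondetect statistics) and compares against the fitted CDF via
the asymptotic Kolmogorov reference; `detected_only=True` drops nondetects
instead.  The k-vs-k′ likelihood-ratio test uses the χ² reference with
3·Δk degrees of freedom and always carries a `boundary_caveat`: mixture
order testing is non-regular (the null sits on the boundary), making the
reference conservative — confirmed by the null-calibration test.

`fit_detected_only` fits the mixture to the detected values alone and is
provided for comparability with published detected-only analyses of the
bundled manganese data; it deliberately discards the nondetect information
and is not recommended for inference — the full censored likelihood
(`mle_partial`, `em_fit`) is the package's default path.  Bayes fits on
real data default to an empirical prior centred at a pilot full-likelihood
estimate (concentration 2), since no external prior information ships with
the datasets.

## Numerical choices

* log(1 − e^{−t}) via the expm1/log1p split at t = log 2; derivative
  ratios e^{−t}/(1 − e^{−t})^k computed in log space — stable from
  θx ≈ 1e−12 to θx ≈ 700.
* Profile objective returns +∞ once every censored/observed log-CDF term
  underflows (θ beyond any plausible scale); component estimates outside
  [1e−6, 1e6] raise as degenerate.
* Weights normalized with log-sum-exp; ELF inversions through zero raise.
* Mixture-order label convention: labeled data keep their labels; the
  study harness fits in labeled mode, so no relabeling is needed.  For
  unlabeled EM started from user inits, components are reported in the
  order given (callers comparing against a truth should match by fitted
  mean when components are separated).
* `CensoredDataset` validates flags/limits/labels at construction; CSV
  round-trips are bit-exact (`%.17g` write, round-trip float parsing).
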