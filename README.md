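# gemix

Two-component generalized-exponential (GE) mixture modelling for
positive-valued concentration data with **lower detection limits** —
measurements reported only as "below L" (nondetects / left-censored
records), as routinely produced by environmental monitoring of air, water
and biological samples.

Substituting nondetects by the detection limit (or half of it) biases both
location and spread; and a single standard distribution often cannot
describe data pooled from heterogeneous sources (several wells,
laboratories, seasons).  `gemix` addresses both problems at once with the
mixture

```
F(x; Ω) = π₁ (1 − e^{−θ₁x})^{λ₁} + (1 − π₁)(1 − e^{−θ₂x})^{λ₂},   x > 0,
```

a weighted pair of generalized-exponential distributions (shape λᵤ > 0,
rate θᵤ > 0; λ = 1 recovers the exponential).  A censored record enters the
likelihood through the component CDF at its own detection limit, an
observed record through the density, so several distinct limits in one
dataset are handled exactly.

## Estimators

* **Labeled maximum likelihood** — when component membership is known, π̂₁
  is closed-form and each component reduces to a one-dimensional profile
  optimization in θ.
* **EM** — for unlabeled samples; censored records contribute the
  CDF-at-limit to the E-step responsibilities.
* **Lindley approximation** — second-order expansion of the posterior mean
  around the MLE using the inverse observed information and analytic
  third derivatives, under squared-error (SELF) and entropy (ELF) losses.
* **Conditional-draw importance sampling** — Beta/Gamma proposals from the
  conjugate-like blocks of the posterior, self-normalized importance
  weights, SELF (weighted mean) and ELF (reciprocal weighted mean of
  reciprocals) estimates; a data-augmentation variant imputes labels for
  unlabeled data.

Around these sit a Monte-Carlo evaluation harness (ARE / MSE / scaled-MSE
tables over sample size, censoring rate, priors and mixing weights) and
model-selection tools (AIC, BIC, a censoring-aware Kolmogorov–Smirnov
statistic, and nested likelihood-ratio tests over k-component fits).

Two small environmental datasets ship with the package: weekly ammonium
concentration in precipitation (102 records, 46 nondetects under four
different limits) and manganese in groundwater from five wells (25 records,
6 nondetects under two limits) — `load_dataset("ammonium")` /
`load_dataset("manganese")`.

## Worked example

```python
from gemix import S1, SimConfig, simulate, mle_labeled

sim = simulate(SimConfig(S1, n=200, censor_rate=0.2, seed=42))
print(sim)                       # CensoredDataset(n=200, censored=40)
fit = mle_labeled(sim)
o = fit.omega_hat
print(f"lam1={o.comp1.lam:.4f} theta1={o.comp1.theta:.4f} "
      f"lam2={o.comp2.lam:.4f} theta2={o.comp2.theta:.4f} pi1={o.pi1:.4f}")
# lam1=0.4158 theta1=1.2997 lam2=0.9011 theta2=1.6114 pi1=0.4550
```

The simulated truth is S1 = (λ₁, θ₁, λ₂, θ₂, π₁) = (0.5, 1.2, 0.75, 1.5,
0.45); at n = 200 with 20 % of records censored, the labeled MLE recovers
each parameter to within its sampling noise (π̂₁ = 91/200 is exact
bookkeeping).

The same fits run from the shell:

```sh
$ gemix evaluate manganese --method mle
loglik=-90.2269 aic=190.4539 bic=196.5483 ks=0.1934 ks_p=0.2704
```

i.e. the full-likelihood ML fit of the mixture to the manganese data has
log-likelihood −90.23; AIC/BIC then follow as 2·5 − 2·loglik and
5·ln n − 2·loglik, and the KS statistic (nondetects substituted at their
limits) is 0.193 with p = 0.27 — no evidence against the fitted mixture.
`gemix fit`, `gemix simulate`, `gemix simstudy`, and `gemix select-k` cover
the remaining workflows; see `--help`.

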