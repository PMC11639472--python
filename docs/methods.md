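# Methods

## Model

The NE_Fr law arises from a ratio-type generator applied to the Fréchet
(inverse Weibull) baseline `G(z) = exp(-α z^-β)`:

```
F(z) = 1 - [ (1 - G²) / (1 - λ̄ G²) ]^λ ,   λ̄ = 1 - λ,   α, β, λ > 0.
```

Since `G² = exp(-2α z^-β)`, the generator effectively doubles the Fréchet
scale; `λ = 1` recovers Fréchet(2α, β) exactly, with no special-casing in
the code (`λ̄ = 0` makes the denominator 1). The survival function satisfies
`S(z) z^{βλ} → (2α/λ)^λ`, so the **tail index is `βλ`** and `E[Z^r]` exists
iff `r < βλ`. This single fact drives every existence guard in the package:
mean and Lorenz/Bonferroni curves need `βλ > 1`, the variance `βλ > 2`, the
entropy integral `∫ f^ρ` needs `ρ(βλ + 1) > 1`.

### Parameters

| parameter | role | typical range in the bundled studies |
|---|---|---|
| `α > 0` | scale-type (units of `z^β`) | 0.3 – 9 |
| `β > 0` | Fréchet shape; sets tail weight jointly with λ | 0.06 – 4 |
| `λ > 0` | extra shape from the generator | 0.3 – 30+ |

`λ̄ = 1 - λ` is derived storage, never an independent parameter.

## Numerical evaluation

All distribution functions run on the log scale. The two recurring factors
`A = 1 - e^{-w}` and `D = 1 - λ̄ e^{-w}` (with `w = 2α z^{-β}`) are evaluated
as `log A = log(-expm1(-w))` for `w < log 2` and `log1p(-e^{-w})` above, and
`log D = log1p((λ-1) e^{-w})`. The second identity matters: on the flat
large-λ likelihood ridge (see below) `(λ-1)e^{-w}` is order one while `λ` is
huge, and the naive `log(λ + λ̄ A)` loses the entire answer to float64
rounding (verified against 40-digit arithmetic). With these identities the
contract "no NaN for `z ∈ [1e-12, 1e12]`" holds across the test panel.

The quantile is closed-form; sampling is inverse-transform from
`numpy.random.Generator`, so it is exact and reproducible.

## Series versus quadrature

The density admits the classical double-series representation
`f(z) = Σ_{i,j} ϖ_{i,j} z^{-β-1} exp(-2(i+j+1)α z^{-β})` from expanding
`(1-λ̄x)^{-(λ+1)}` and `(1-x)^{λ-1}`; the expansion fixes the coefficient as
`ϖ_{i,j} = 2λ²αβ (-1)^j [Γ(λ+1+i)/(Γ(λ+1) i!)] C(λ-1, j) λ̄^i`. Moments,
incomplete moments, conditional moments and the `∫ f^ρ` entropy integral all
reduce to sums of `coefficient × kernel(i+j)` with gamma-function kernels.

Every such functional has **two routes**:

- **quadrature** (authoritative): substitute `z = Q(u)` and integrate over
  the unit interval — e.g. `E[Z^r] = ∫₀¹ Q(u)^r du`,
  `∫₀^t z^s f dz = ∫₀^{F(t)} Q(u)^s du`, `∫ f^ρ dz = ∫₀¹ f(Q(u))^{ρ-1} du`.
  This needs no convergence conditions beyond existence of the integral.
- **series** (for fidelity with the analytic development): the double sum is
  evaluated with the kernel cached over the diagonal index `s = i + j`,
  plain accumulation with early stopping (`term_tol = 1e-12`, cap
  `max_index = 200` per index), and a **Levin u-transform** fallback (first
  40 terms, float64) when the cap binds. The transform handles both the
  slowly convergent monotone tails that appear for `λ < 1` (coefficients
  decay like `j^{-λ}`) and the alternating, Abel-summable boundary `λ = 2`
  where `|λ̄| = 1` and classical convergence fails. A `TruncationWarning`
  is raised when the transform's stability proxy exceeds `1e-5` relative.

Measured against quadrature, the series route agrees to ≤ 3e-8 relative
across the test panels, far inside the 1e-5 / 1e-4 tolerances the tests
assert. Generalized incomplete gammas with non-positive first argument
(needed because the lower moment range exists for every order `s`) use the
downward recurrence `Γ(a,x) = (Γ(a+1,x) - x^a e^{-x})/a`.

The printed-analytics ambiguity in the coefficient's δ symbol is exposed via
`SeriesControl.delta_convention`; only the derived "mixed" reading
reproduces quadrature, and it is the default.

`mgf_as_written(t)` is the Laplace transform `∫ e^{-tz} f dz` — with a
power-law tail, `E[e^{tZ}]` diverges for every `t > 0`, so the decaying
kernel is the only version that defines a finite transform; it is 1 at
`t = 0` and monotone nonincreasing.

## Estimation

Four estimators share one optimization harness: Nelder–Mead on
`(log α, log β, log λ)` (positivity for free), multistart (default 12:
a Fréchet probability-plot regression start, a median-matching heuristic
over a λ grid, plus seeded jitter), tolerances `1e-8` on parameters and
`1e-10` on the objective, objective values outside `|log θ| ≤ 30` rejected.
`fit(..., init=[...], starts=0)` runs a purely local search from explicit
starting triples. The analytic score matches central finite differences to
~1e-10 relative and a symbolic-differentiation oracle exactly; standard
errors (MLE only) come from the inverse observed information, obtained by
central differences of the analytic score and symmetrized.

**The flat-λ ridge.** For some samples the profile `-2 logL` over λ
decreases monotonically toward an asymptote as `λ → ∞` (with `α̂` growing
and `β̂` shrinking along the ridge): the MLE then sits at the boundary and
only the attained likelihood, not `λ̂`, is well determined. The bundled
Pakistan COVID sample is such a case — fits report enormous `λ̂` with an
even larger standard error, and the fitted likelihood is slightly *better*
than published stopping points on the same ridge. This is a property of the
model, not of the optimizer; it is why `SE(λ̂) > λ̂` in the bladder-cancer
fit as well.

Distance estimators: LSE/WLSE minimize (weighted) squared deviations of
`F(z_(i))` from plotting positions `i/(n+1)`, weight
`(n+1)²(n+2)/[i(n-i+1)]`; ADE minimizes the classical Anderson–Darling
statistic `A² = -n - (1/n) Σ (2i-1)[log F(z_(i)) + log(1-F(z_(n+1-i)))]`
(log arguments clipped at 1e-300). They report no standard errors.

## Goodness of fit

`criteria()` reports `τ1 = -2 logL`, AIC, AICc, BIC, HQIC (exact arithmetic
identities off `τ1`), the Cramér–von Mises statistic
`W² = 1/(12n) + Σ[F(z_(i)) - (2i-1)/(2n)]²`, the asymptotic one-sample KS
p-value against the fitted cdf (no estimated-parameter correction), and
`A²`. `W²`/`A²` share code with the distance objectives, so the GoF layer and
the estimators can never drift apart. Descriptives use the `n-1` standard
deviation, moment skewness `m₃/m₂^{3/2}` and **excess** kurtosis
`m₄/m₂² - 3` (the convention that reproduces the bundled samples' published
summary rows). The scaled TTT transform
`T(i/n) = [Σ_{j≤i} z_(j) + (n-i) z_(i)] / Σ z_(j)` is provided as the hazard
shape diagnostic.

## Monte-Carlo study

`run_scenario` draws replicated samples by inverse transform with seeds
spawned as `SeedSequence(master, spawn_key=(n, rep))`, so all methods see
identical samples (a paired design — smaller between-method comparison
variance, unbiased marginal summaries) and every cell is bitwise
reproducible. Each replication's optimizer starts at the true parameters:
the study measures recovery of the local optimum near the truth, which is
the published design for this model family. Summaries are per-parameter
mean, signed relative bias `mean/truth - 1`, and MSE; failed fits are
counted in `n_failed`, never silently dropped.

**Known behavior, not a bug:** in the heaviest-tailed scenario
(`βλ = 0.12`) a few percent of small-`n` replications genuinely have their
likelihood optimum in a degenerate corner (`α ~ 10^10`, `β ~ 30`,
`λ ~ 0.005`) because single sample values can reach `10^20`; those cells'
MSEs are then dominated by the escapes. At `n = 250` the near-truth mode
dominates and a single full-replication cell (1000 replications, as in the
published design; `scripts/acceptance.py` runs exactly this in ~20 s) lands
within Monte-Carlo error of survey-grade values.

`rank_methods` ranks methods by MSE within each (scenario, n, parameter)
cell, averaging ranks on ties, and totals per method. Applied to the bundled
published MSE grid the totals are 207/717/510/366 over 180 cells
(MLE < ADE < WLSE < LSE); the bundled published rank table, which uses one
rank per (scenario, n) cell, sums to 70/240/167/122 with the same ordering.
The two are *not* exactly consistent with each other (the rank table
contains ties where the MSE grid differs and one row whose ranks sum to 9);
both ship verbatim and both routes are exposed.

## What the synthetic generator does and does not emulate

`nefr_rvs` draws exactly from the model, so simulation studies test the
estimation machinery under the model's own idealized conditions:
i.i.d. sampling, no censoring, no measurement rounding, no covariates.
Passing recovery tests therefore demonstrates correctness of the estimators
and their implementation — not robustness to the misspecification, ties and
truncation that real surveillance data (like the bundled integer-valued
COVID counts) exhibit. Censored-data estimation is out of scope.

## Limitations

- The λ direction of the likelihood can be unbounded (ridge); point
  estimates of λ from real data should be read with their standard errors.
- Series evaluation beyond `λ ≈ 2.5` relies on analytic continuation via
  the Levin transform and warns when unstable; use quadrature there.
- KS/CvM/AD p-values ignore parameter estimation (no Lilliefors-type
  correction), matching standard reporting practice for these comparisons.
- Small-sample Monte-Carlo cells in infinite-mean scenarios are dominated
  by genuine far-mode escapes; interpret their MSEs accordingly.
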