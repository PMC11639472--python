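# nefr — the new extended Fréchet lifetime distribution

`nefr` implements the **new extended Fréchet (NE_Fr)** distribution, a
three-parameter heavy-tailed model for positive durations — remission times,
epidemic daily counts, failure times — together with everything needed to
use it in practice: closed-form quantiles and random generation, moments and
entropies, four classical estimators, goodness-of-fit criteria, and a
Monte-Carlo harness for comparing the estimators.

It is written for applied statisticians and epidemiologists who fit
parametric lifetime models to skewed data where the classical Fréchet
(inverse Weibull) is too rigid.

## The model

Insert the Fréchet cdf `G(z) = exp(-α z^-β)` into a ratio-type generator
with extra shape `λ > 0` (writing `λ̄ = 1 - λ`):

```
F(z; α, β, λ) = 1 - [ (1 - e^{-2αz^{-β}}) / (1 - λ̄ e^{-2αz^{-β}}) ]^λ ,   z > 0
```

Key facts the package is built around:

- **Fréchet special case** — at `λ = 1` the model is exactly Fréchet with
  scale `2α` and shape `β`.
- **Tail index `βλ`** — the survival function behaves like
  `(2α/λ)^λ z^{-βλ}`, so `E[Z^r]` exists iff `r < βλ`. Many interesting
  parameter regions have no mean; quantile-based summaries (Bowley skewness,
  Moors kurtosis) are therefore first-class citizens.
- **Closed-form quantile** —
  `Q(p) = { -(1/2α) log[ (1-(1-p)^{1/λ}) / (1-λ̄(1-p)^{1/λ}) ] }^{-1/β}`,
  which gives exact inverse-transform sampling.
- **Hazard repertoire** — decreasing or upside-down (unimodal) hazards,
  matching TTT plots of the bundled healthcare datasets.

Estimation: maximum likelihood (with analytic score and observed-information
standard errors), ordinary/weighted least squares on the probability plot,
and the Anderson–Darling minimum-distance estimator, all via multistart
Nelder–Mead on log-parameters.

## Worked example

```bash
python examples/fit_real_data.py
```

```
sample: bladder_cancer, n=128, range [0.08, 79.05]
NE_Fr MLE: alpha=4.845 (SE 1.067)  beta=0.154 (SE 0.052)  lam=32.09 (SE 35.86)
NE_Fr:   -2logL=821.902  AIC=827.902  BIC=836.458  KS p=0.918  W2=0.045  A2=0.307
Fréchet: -2logL=888.002  AIC=892.002  BIC=897.706  KS p=0.013
```

The three-parameter fit improves `-2 logL` by ~66 units over the Fréchet
baseline and lifts the Kolmogorov–Smirnov p-value from 0.013 to 0.918: the
extended model describes these remission times dramatically better. Note
`SE(λ̂) > λ̂` — the likelihood is nearly flat in the `λ` direction, so the
fit quality is sharply determined but `λ̂` itself is not.

Other entry points: `examples/distribution_basics.py` (distribution
functions and quantile summaries), `examples/moments_and_entropy.py`
(series vs quadrature moments, mean residual life, Lorenz curve, the four
entropies), `examples/estimator_comparison.py` (a small Monte-Carlo rank
comparison), and a thin CLI:

```bash
nefr props --alpha 0.4 --beta 0.4 --lam 0.9
nefr fit --fixture bladder_cancer --method mle
nefr gof --fixture who_covid_deaths --format csv
nefr simulate --alpha 0.3 --beta 0.4 --lam 0.3 --n-grid 50,100 --reps 200 --seed 1
```

## Bundled data

Three published healthcare samples ship as plain-text fixtures
(`load_fixture(...)`): bladder-cancer remission months (n=128), daily
COVID-19 confirmed cases in Pakistan (n=36), and WHO-reported COVID-19
deaths for one day across 104 reporting units. The published Monte-Carlo
summary grid and its method-rank table also ship as tidy CSVs
(`load_simulation_table()`, `load_printed_ranks()`).

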