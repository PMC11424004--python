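# hmbfit

Evolutionary rates — substitution rates, rates of body-size change,
speciation rates, extinction rates — routinely appear to accelerate
toward the present.  A rate, however, is a ratio of an amount of change
to an elapsed time, and any time-independent noise in the numerator gets
divided by the interval: plotting such a ratio against its own
denominator manufactures a hyperbola that looks exactly like a rate
speed-up at short time scales.  `hmbfit` is a toolkit for asking, for a
given rate-versus-time dataset, *how much of the apparent pattern is that
artifact* — aimed at comparative biologists, macroevolution researchers,
and anyone fitting trends to ratio data.

## The model

The observed rate at interval length *t* is decomposed as

    r(t) = h/t + m·t + b

where *h* ≥ 0 is the hyperbolic component (the signature of
time-independent numerator noise, in trait units), *m* a linear trend
(trait units · t⁻²), and *b* a constant base rate (trait units · t⁻¹).
All seven non-empty subsets of {h, m, b} are fitted by least squares on
the log scale (log1p when zero rates are present), converted to
likelihoods via σ̂² = RSS/n and log L = −0.5·n·log σ̂², and ranked by
AIC.  Around the best fit the package provides:

- **likelihood-rim confidence regions** (chi-square offset sampling, the
  1.92-log-likelihood-unit rule for one parameter) and per-component
  contribution bands through time;
- a **numerator-shuffling randomization null** with OO/OR/RR R²
  comparisons and percentile p-values — if shuffled change predicts your
  data almost as well as the real fit, the pattern is mostly noise;
- **pure-birth (Yule) simulations** with the crown-clade MLE
  λ̂ = (n−2)/Σxᵢ, its small-sample bias λ(n−2)/(n−1), and a correction
  multiplier, for rate-trend control datasets;
- a **two-state Mk tip-error experiment** (Felsenstein pruning,
  pectinate vs balanced 64-taxon trees) showing how character-state
  errors masquerade as elevated rates in young clades;
- **synthetic scenario generators** (constant / increasing / decreasing /
  sinusoidal rates with numerator and time noise) and a recovery
  harness, including the log-log slope-vs-(−1) baseline.

## Worked example

Fit the bundled paired-comparison example (200 noisy rates whose
numerators carry time-independent noise on top of a weak linear trend):

```python
import numpy as np
from hmbfit import RateDataset, fit_all, OptimizerConfig, sample_region, parameter_bounds
from hmbfit.io import make_fixtures

ds = RateDataset.from_frame(make_fixtures(0)["paired"], name="paired")
sel = fit_all(ds, config=OptimizerConfig.fast(), seed=0)
print(sel.to_frame()[["variant", "h", "m", "b", "loglik", "aic", "delta_aic"]].round(4))

best = sel.best
region = sample_region(best, ds, n_steps=1000, seed=0)
lo, hi = parameter_bounds(region)[0]
print(f"best: {best.variant.label}; h = {best.params.h:.3f} (95% rim box {lo:.3f}-{hi:.3f})")
```

which prints

```
variant      h       m      b    loglik      aic  delta_aic
    hm0 0.2766  0.0030 0.0000    7.2449 -10.4898     0.0000
    hmb 0.2742  0.0030 0.0017    7.2518  -8.5036     1.9863
    h0b 0.2123  0.0000 0.0676   -3.4043  10.8087    21.2985
    h00 0.5513  0.0000 0.0000  -70.6801 143.3602   153.8500
    0mb 0.0000 -0.0034 0.2540  -71.5952 147.1904   157.6803
    00b 0.0000  0.0000 0.2131  -78.1683 158.3366   168.8264
    0m0 0.0000  0.0824 0.0000 -222.5701 447.1402   457.6300
best: hm0; h = 0.277 (95% rim box 0.222-0.343)
```

The selected model carries a strongly positive hyperbolic component
(h ≈ 0.28, close to the E|ε₂−ε₁| ≈ 0.4·(sd/0.5) implied by the
generator's noise) alongside the weak true trend m ≈ 0.003 — at short
intervals essentially all of the apparent rate is noise
(`decompose(best.params, 0.2)` puts the hyperbolic share at 1.0), while
the constant-rate model `00b` trails by > 160 AIC units.

The same analyses are scriptable from the shell:

```sh
hmbfit fit rates.csv --seed 1 --out results/fit
hmbfit randomize rates.csv --n 100 --seed 1 --out results/rand
hmbfit yule --n-trees 1000 --seed 1 --out results/yule
hmbfit mkbias --shape balanced --n-sims 200 --seed 1 --out results/mk
```

Input tables are comma-delimited text with a header and `time`, `rate`
(and optionally `numerator`, `denominator`, `dataset`) columns.

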