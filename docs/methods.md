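# Methods

## The problem

Across very different biological datasets — substitution rates, body-size
change in darwins, diversification rates, extinction rates — estimated
rates appear to rise toward the present.  Because a rate is a ratio of an
amount of change to an elapsed time, any time-independent error in the
numerator is divided by the interval length, and plotting such a ratio
against its own denominator manufactures a hyperbola: at short intervals
the error term dominates and the apparent rate explodes.  `hmbfit`
implements a model family, a randomization null, and simulation harnesses
for diagnosing how much of an observed rate–time relationship is
attributable to this artifact.

## The hmb model family

The observed rate at interval length *t* is modelled as

    r(t) = h/t + m·t + b

with *h* ≥ 0 the hyperbolic component (trait units — the magnitude of
time-independent numerator noise), *m* the linear slope (trait units ·
t⁻²) and *b* a constant base rate (trait units · t⁻¹).  Fixing any subset
of parameters at zero gives seven nested variants (`hmb`, `hm0`, `h0b`,
`0mb`, `h00`, `0m0`, `00b`); `00b` is the clock-like constant-rate model.

Fitting minimizes the residual sum of squares between transformed observed
and predicted rates.  The transform is the natural log, switched
automatically to log1p when any rate is exactly zero (as happens for
pure-birth clades that never bifurcate).  The RSS converts to a likelihood
through the MLE of the residual variance, σ̂² = RSS/n, giving
log L = −0.5·n·log σ̂², and to AIC = 2k − 2·log L for model selection; ties
break toward fewer parameters, and the set within 2 AIC units of the best
fit is reported alongside the ranking.  Minimizing log(RSS) and RSS have
the same argmin, so RSS is minimized directly.

Numerical choices:

- *h* is constrained non-negative: it represents an error magnitude, and
  every parameter point whose prediction leaves the transform's domain at
  an observed time (≤ 0 under log, ≤ −1 under log1p) receives an infinite
  objective sentinel instead of an error.
- A perfect fit (RSS = 0) floors σ̂² at 1e−300 before the log and flags
  the fit as degenerate; degenerate fits refuse confidence-region
  sampling.
- Optimization is multi-start and derivative-free: a fixed grid of
  heuristic starts (b = median rate, h = median rate·t, m = OLS slope of
  rate on t, and per-variant fallbacks), the same grid rescaled ×0.3 and
  ×3, then 20 random restarts around the incumbent; every start is
  polished by Nelder–Mead, Powell, and COBYQA in turn (three
  derivative-free local methods with different search geometries).
  Relative function tolerance 1e−10, at most 10,000 evaluations per run,
  box bounds ±1e6 (h: [0, 1e6]).  Single- and two-parameter fits agree
  with dense grid-search oracles to better than 1e−6 relative in the
  tests.

## Likelihood-rim uncertainty

Confidence regions come from sampling the likelihood surface rather than
from curvature.  The rim is the set of points whose log-likelihood is
within χ²(level, df)/2 of the maximum — 1.92 units for one free parameter
at 95%.  `df` defaults to the variant's free-parameter count and can be
pinned at 1.  An adaptive Gaussian random walk starts at the optimum,
records every proposal with an inside/outside label, moves whenever a
proposal stays above best − 2·threshold, and rescales its step to keep
roughly 20–40% of proposals inside.  The per-parameter minimum and maximum
over inside points give a deliberately conservative axis-aligned box; on a
single-free-parameter surface the box edge reproduces the closed-form rim
crossing to well under 2%.

The fitted rate decomposes into shares |h/t|, |m·t|, |b| normalized by
their sum (absolute values, since components of mixed sign can cancel in
the total while each still contributes variation).  Share bands through
time are computed by evaluating the decomposition at all 2^k corners of
the bounds box (8 for the full model).  When the box stays on one side of
zero in every coordinate each share is monotone per-parameter and the
corners attain the exact extremes; a box straddling zero in *m* or *b*
makes the corner bands approximate, which is accepted as part of the
deliberately conservative design.  The noise-free prediction deletes the
hyperbolic term: m·t + b, reported as-is even when negative.

## Randomization null and OO/OR/RR

The null model for "change carries no information about elapsed time" is
built by shuffling the numerators across observations and dividing by the
unshuffled denominators, preserving both marginal distributions exactly.
Datasets that only record rate and time impute the numerator as
rate × time.  Tree-derived rates use the event count over the total
branch length as numerator/denominator, while keeping the clade age as
the fitting and plotting time — shuffling event counts against clade ages
directly would misstate the rates.

Explanatory power is compared as: OO, the R² of the original data under
its own best-AIC fit; OR, the R² of the original data under each of the
(default 100) shuffled replicates' fits; RR, the R² of replicate *i*'s
data under replicate *j*'s fit for all ordered pairs i ≠ j
((100−1)·100 = 9,900 values).  R² is computed on the dataset's transform
scale and may be negative for bad cross-fits.  To keep the OO–OR and
OR–RR comparisons on equal sample-size footing, p-values are
percentile-based: the percentile uses mid-ranks with an (N+1) denominator,
p = 2·min(q, 1−q), floored at 2/(N+1) so the below-all-nulls case scores
the same as above-all (a `form="printed"` flag reproduces the
2·max(q, 1−q) variant verbatim).  The OR–RR p-value averages the
percentile p over 1,000 random draws from the RR distribution.

## Pure-birth estimator bias

The Yule study draws clade ages uniformly in log space (default 1–50 Myr,
even coverage on a log-log plot), simulates one two-lineage pure-birth
clade per age at λ = 0.1 births/Myr by exact Gillespie simulation, and
estimates λ̂ = (n−2)/Σxᵢ from each tree.  Clades that never bifurcate
estimate zero; excluding them (censoring) reproduces the ascertainment
bias that inflates apparent rates at short ages, which the tests verify
directionally.

Plugging the expected total edge length (n−1)/λ of an n-tip Yule tree
into the estimator gives the small-sample expectation E λ̂ ≈ λ(n−2)/(n−1)
and bias −λ/(n−1).  Two correction multipliers are provided: the default
n/(n−1) (which keeps n = 2 estimates at zero) and the algebraic inverse
(n−1)/(n−2) for n ≥ 3.  The expectation formula is a ratio-of-expectations
approximation for age-conditioned trees; it is *exact* under one specific
observation scheme, namely a tree grown from a single lineage and observed
over its entire n-tip lifespan, where the total length is a sum of n
i.i.d. Exponential(λ) terms so E[(n−2)/Σxᵢ] = λ(n−2)/(n−1) follows from
the inverse-gamma mean.  The conditional-bias acceptance test simulates
under that scheme; age-conditioned trees binned by tip count do *not*
satisfy the formula, which is worth knowing before applying the
correction to real compilations.

Trend diagnostics regress log1p of the rate estimates on clade age, with
the age on the natural-log scale by default (ages are drawn log-uniformly
and inspected on log axes; a flag switches to linear age).  Under the
study defaults the uncensored biased-MLE regression measures a small
positive slope (≈ 0.007 per ln-Myr, ≈ 0.015 per log10-Myr) with R² ≈ 1%,
and the corrected estimator's trend is flat (R² well under 1%).  A
variance decomposition at 200,000 trees shows clade age can explain at
most ≈ 0.8% of the log1p-rate variance under this design — the residual
scatter of small-tree estimates dominates — so the biased-trend R² is
intrinsically below a few percent at these settings.

## Mk tip-error experiment

Two 64-taxon tree shapes bracket the extremes of balance: pectinate
(each internal node splits off one tip; speciation times evenly spaced
between root and present) and perfectly balanced (equal-duration epochs;
tip count a power of 2).  Both are ultrametric; branch-length schemes are
the simplest shapes consistent with those extremes.  A symmetric
two-state character evolves with per-branch flip probability
0.5·(1 − e^(−2qt)); tip errors flip exactly k (default 6) random tips.
Rates are re-estimated by maximizing the Felsenstein pruning likelihood
(equal root frequencies) over [0, 100× the generating rate], via a coarse
log-spaced grid plus bounded scalar refinement; the pruning matches
exhaustive enumeration on small trees to 1e−10 relative and the estimate
matches a dense grid to 1e−4.  Invariant or saturated datasets produce
boundary estimates that are retained and flagged rather than filtered,
since the generating rates (0.01/Myr pectinate, 0.05/Myr balanced over
ages 5–20 Myr) were chosen to keep them rare.  Clean data give a flat
rate–age regression; error-injected data a significantly negative one,
attenuated on pectinate trees, which contain more total time at the same
age.

## Synthetic scenarios

Four generating processes over times 0.01–50 units (log-uniform placement
by default): constant 0.4, increasing 0.6 + 0.01t, decreasing 1 − 0.01t,
and a sine of period 26 (offset 1.0, amplitude 0.5 — the offset/amplitude
are this package's defaults, chosen to keep the true rate positive, and
are configurable).  The numerator is true rate × true time plus Gaussian
noise (sd ∈ {1e−6, 0.01, 0.1, 1}), magnitudes taken; times get Gaussian
noise with a 10% coefficient of variation, redrawn until positive; the
observed rate is their ratio.  Ten replicates each of 500 and 5,000
points are the reference sizes.  The recovery harness records the best
variant, the mean absolute error of m·t + b against the true curve on a
log-spaced grid, the mean hyperbolic share, and the baseline log-log
slope for comparison against the constant-numerator value of −1.
Scenarios 1–3 lie inside the model family and are recovered at vanishing
noise; the sine does not and its misfit persists as noise → 0, which is
the intended negative control.  At high noise the constant scenario
sometimes selects a spurious trend component — a documented limitation of
the approach, not of the implementation.

## What the generators do and do not emulate

The synthetic data capture time-independent numerator noise, noisy times,
zero-rate censoring, and tip-state errors.  They do not emulate
phylogenetic non-independence of comparisons, heteroscedastic or
time-correlated measurement error, ascertainment in which clades get
studied, or errors in branch lengths — so passing tests demonstrate the
machinery and the artifact mechanism, not that any particular empirical
compilation is free of other biases.

## Problem sizes and determinism

Default study sizes follow the reference experiments (1,000 trees for
estimator diagnostics; 25,000-tree control datasets are configurable).
Batch analyses in the test-suite and examples use reduced optimizer
effort (`OptimizerConfig.fast()`) and scaled replicate counts — e.g. 200
simulations per arm of the Mk experiment and 2,000 trees per tip-count
bin for the conditional-bias check — sizes chosen so the full suite
completes in a few minutes while keeping Monte-Carlo error well inside
the asserted tolerances.  Every stochastic path takes a seed; master
seeds fan out to per-replicate seeds through `numpy` `SeedSequence`
spawning, and reruns with the same seed are bit-identical.
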