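# Methods

## Model

The package analyses fixed-duration predation trials in which consumed prey
are not replaced.  Depletion makes the classic Holling disc equation
inappropriate; the expected kill count under a Type II response is instead
the Rogers random-predator relation

    Ne = N0 (1 − exp(a (Ne h − T))),

solved explicitly with the principal Lambert-W branch,

    Ne = N0 − W0(a h N0 exp(−a (T − h N0))) / (a h).

Units: the 40-hour trial is mapped to `T = 1` by default, so the attack rate
`a` is per trial and the handling time `h` is in trial-duration units per
prey.  Any other scaling of `T` rescales `a` and `h` reciprocally and is
supported through the `t` argument everywhere.

Three response families share one likelihood machinery:

* **Type I** — defined as the `h → 0` limit `Ne = N0 (1 − exp(−a T))`, not
  Holling's rectilinear form.  A depletion design cannot produce a truly
  linear kill-density relation, and the exponential limit keeps the linear
  model inside the same binomial likelihood, which is what the AIC
  comparison requires.
* **Type II** — the Rogers solution above.
* **Type III** — attack rate made density-dependent as
  `a(N) = b N / (1 + c N)` and substituted into the Rogers solution.  With
  `c = 0` this reduces to the two-parameter Hassell form `a = b N`.  The
  form of the density dependence is a package choice: it is the simplest
  saturating law that vanishes at `N = 0` (the low-density refuge) while
  retaining a finite high-density attack rate.

Numerical notes: `a·h < 1e−12` routes to the `h = 0` closed form to avoid a
0/0; Lambert arguments beyond `exp(700)` are handled in log space by Newton
iteration on `w + log w = log z`; within float rounding of the branch point
`−1/e` a three-term series replaces the library routine, which loses
accuracy there.  Solutions are clipped to `[0, N0]` (the exact root always
lies inside; clipping removes last-ulp excursions).

## Likelihood and treatment coding

Each pot's kill count is modelled as `Binomial(N0, Ne(a, h, N0, T) / N0)`.
The observation family is a package choice — it is the standard one for
bounded kill counts in non-replacement designs and matches the
proportion-based type test.  Treatment structure enters by indicator
("treatment") coding: every factor level other than the base contributes an
additive offset to `a` and/or `h`, interactions use products of the main
indicators, and the base level (native amphipod, unparasitised, no fish;
isopod prey in the between-module model) is carried by the intercepts.
Effects are estimated on the natural scale and may be negative; parameter
vectors implying `a ≤ 0` or `h < 0` in any observed cell receive an infinite
penalty instead of being transformed away, so table entries remain directly
interpretable as differences.

Optimisation is multi-start Nelder–Mead (one heuristic start — attack rate
from a disc-equation linearisation of the two lowest densities, handling
time from the reciprocal maximum kill — plus four copies with intercepts
jittered by uniform(0.5, 1.5) factors) refined by BFGS.  Standard errors
come from the inverse of a central finite-difference observed Hessian
(relative step `1e−5`); z is estimate/SE and P is two-sided normal.  No
multiple-testing adjustment is applied.  Degenerate saturated data (every
pot consuming all prey) are flagged as a boundary fit rather than reported
as converged.  The likelihood is evaluated on the unique
(treatment-cell × density) combinations with sufficient statistics, so its
cost is independent of replication.

## Response-type classification

Proportion killed (partial and complete kills both count) is regressed on a
quadratic polynomial in raw density through a logit-link binomial GLM
(IRLS, via statsmodels).  A significant negative first-order coefficient
classifies Type II; significant positive first-order followed by significant
negative second-order classifies Type III; anything else is inconclusive and
triggers an AIC comparison (`AIC = 2k − 2 logLik`) of single-curve
Type I/II/III fits.  The polynomial degree is fixed at 2 (the sign rules
involve no higher terms) but exposed for sensitivity work; density is
deliberately uncentred so the signs refer to raw-density terms; α defaults
to 0.05.

## Bootstrap envelopes

Uncertainty bands are nonparametric case bootstraps: whole pots are
resampled with replacement within each treatment-by-density stratum
(preserving the factorial layout — the choice of case over residual
resampling, and of stratification, is the package's), the model is refitted
from the point estimate, failed refits are dropped and counted (a failure
rate above 20% attaches a warning), and the per-density 2.5/97.5 percentiles
of the predicted curves form the 95% equi-tailed envelope.  Default 1500
replicates.  Within a stratum, resampling is drawn as multinomial pot
counts, which is distributionally identical to index resampling and lets
each refit reuse the compressed likelihood.

## Synthetic data

The generator reproduces the study conditions: per prey species a
2 × 2 × 2 factorial (amphipod, parasitism, fish) over densities
2, 4, 6, 8, 10, 20, 30 with 4 replicates (224 pots), 4 control pots per
density and fish level, and start days assigned 22 pots per batch every
three days.  Default curve parameters are the published within-module point
estimates (e.g. isopod prey: `a = 0.981`, `h = 0.307`, invasive-amphipod
handling offset `−0.178`).  Partial consumption is drawn per pot as
`Binomial(killed, p(N0))` when at least two prey were killed, with `p` a
logistic function of density whose prey-specific ceilings (0.02, 0.20,
0.35) echo the reported ordering of partial consumption across prey;
it is generated independently of `(a, h)`, reflecting the finding that it
tracked density rather than treatment.  Control mortality is 1% per
individual (well above the 96.5% survival benchmark); moulting hits 5% of
pots and, among parasitised invasive amphipods, acanthella and
multiple-cystacanth stages appear with probability 0.05 each — producing
exclusion counts of the magnitude the protocol reports.

Two observation models: `binomial` draws kills exactly from the fitting
likelihood and is the reference for parameter-recovery and coverage checks;
`event` is a mechanistic alternating search/handling renewal process
(exponential search with total hazard `a·n`, fixed handling bouts `h` —
fixed, matching the classic disc-equation derivation) that is deliberately
not identical to the likelihood and serves robustness checks.  Randomness
uses one root seed with counter-derived per-pot substreams, so row order
never changes draws and equal seeds give byte-identical CSVs.

What passing tests on these data do *not* show: real kill counts may be
overdispersed relative to the binomial (nothing in the published text pins
the variance), partial consumption may covary with handling in ways the
generator excludes, and prey behaviour (refuge use, interference) is not
mechanistically represented.  Results here validate the estimation
machinery, not the biology.

## Exclusions and QC

Pots are excluded when the amphipod moulted, or when dissection found
pre-infective acanthella or multiple cystacanths; a dissection result
contradicting the initial parasite-status assignment is excluded by default
(configurable — reassignment is the alternative the data cannot
distinguish).  Control survival is `1 − Σdead/ΣN0` per (prey, fish) stratum
and overall, passing above 0.965.  The day-bias diagnostic is a Spearman
rank correlation of kills against start day within each of the 24 modules,
with exact permutation p-values below n = 9.

## Kruskal–Wallis machinery

`H` uses the standard tie correction `1 − Σ(t³ − t)/(N³ − N)`; p-values come
from the χ²(k−1) approximation, replaced by full enumeration of group
assignments when `N ≤ 10`.  Completely tied data return `H = 0, p = 1`.
The per-pot proportion of kills eaten partially (pots with ≥ 2 kills) is the
observation unit — the published text does not state its unit, and the
recording rule makes anything finer unobservable.  Density is treated as a
seven-level factor; degrees of freedom are reported as `k − 1` (the
published statistic subscripts density tests with 7, which under the usual
convention would be df = 6; the package follows the convention and documents
the discrepancy here).

## Problem sizes used in the test suite

Statistical checks run at sizes chosen to keep Monte-Carlo error well below
the tolerances they assert: 200 datasets for parameter-recovery and
classification-power checks (16–40 pots per density), 200 module-scale
datasets (32 pots per density) with 300 bootstrap replicates for envelope
coverage, and full enumeration for all exact-test comparisons.
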