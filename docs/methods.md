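# Methods

## Model and scope

The package operationalises a first-significant-digit (FSD) conformity
protocol: a set of positive measurements is transformed to leading
digits, tallied over the nine digit categories, and the observed digit
distribution `OBS` is compared with the Benford reference
`EXP(d) = log10(1 + 1/d)`. Conformity is read as consistency with
steady-state dynamic equilibrium; statistics falling in the open window
between their conformity and non-conformity cut-points are read as
signals of impending state transition. The protocol is deliberately
multi-statistic ("weight of evidence"): no single p-value decides.

Assumptions worth keeping in view: measurements are strictly positive
after preprocessing, collected without digit-biasing thresholds, span
at least one order of magnitude, and are numerous enough to populate
all nine digit categories. The diagnostics object reports span
(`floor(log10(max/min))` for the integer convention, exact ratio kept
alongside), digit coverage, and whether `n` lies in the 80–500 window
for which the Euclidean-distance critical values were simulated;
outside that window the package warns rather than blocks, since the
statistic is asymptotic and the protocol is routinely applied at
larger n (the pooled fixture has n = 604).

## Digit extraction

`first_significant_digit` normalises through the decimal string
representation at 15 significant digits (`f"{x:.14e}"`) instead of
repeated multiplication/division by 10. Binary floats just below a
decade boundary (0.07, 0.29, …) are thereby read in decimal: 0.07 maps
to 7, never 6. Scale invariance under powers of ten is property-tested
against an explicit rescaling oracle. Zeros carry no digit and are
dropped with a logged count; negatives take absolute value by default
(a sign carries no digit information) or are dropped under the
configurable policy. The published case data are strictly positive, so
this policy is a package choice, made explicit and logged.

## The statistics

* **Morrow distance** `d*_n = sqrt(n) * ||OBS − EXP||_2`. The rendering
  of this formula in the source literature is typographically ambiguous;
  this form reproduces all seven published case values exactly and
  satisfies the algebraic identity `d*_n² = n · SSD · 10⁻⁴`, asserted on
  every fixture and on random tallies. Critical values 1.22/1.33/1.57
  (α = 0.10/0.05/0.01); rejection at ≥ 1.33; signal window (1.22, 1.33).
* **Kossovsky SSD** `sum((OBS−EXP)²) · 10⁴`, sample-size-free.
  ≤ 25 moderate-to-strong conformity, ≥ 100 non-conformity, signal
  window (75, 100).
* **Cohen-W** implemented **with** the square root,
  `sqrt(sum((OBS−EXP)²/EXP))` — the standard definition. The source's
  displayed equation omits the root, but every one of its nine printed
  W values (0.182, 0.316, 0.091, …) matches the rooted form, which is
  therefore taken as authoritative, with all nine values as the oracle.
* **Pearson residuals** signed, `(count − n·EXP)/sqrt(n·EXP)`;
  `sum(PR²)` equals the chi-square statistic (property-tested against
  `scipy.stats.chisquare`). The classification rule counts digits with
  |PR| ≥ 1.96 — absolute values, since a published non-conformity flag
  includes a residual of −2.23.
* **KL divergence** in log base 10 (Hartley units) by default; a `base`
  parameter exists. Zero observed cells contribute 0 (the x·log x
  limit); the reference has no zero cells, so no smoothing is needed.
* **Simpson digit index** `sum(OBS²)` over the nine digit categories,
  bounded [1/9, 1]; 0.165 for the Benford reference itself.
* **Percentage difference** `|a−b| / mean(a,b) · 100`, the symmetric
  comparison used for KL values, with 10% as the nominal level.

Internal values are full precision; rounding to reporting precision
happens only in `display()`/summary-table formatting.

## Classification

`classify` is a pure function of (statistic, thresholds). Boundary
conventions: non-conformity bounds are closed (≥), signal windows are
open intervals. The overall verdict is the worst per-method state —
any flagged method dominates — with all per-method verdicts reported
so users can apply their own synthesis.

## Bootstrap confidence intervals

The resampling unit is the n individual digit observations, drawn with
replacement B = 1000 times (implemented as multinomial resampling of
the observed proportions, which is equivalent and fast); `sd_boot` is
the sample standard deviation of the replicate statistics. The default
interval is `point ± t(0.975, df=8) · sd_boot / 3` — a t interval on
the nine digit categories, mirroring the spreadsheet construction the
protocol was published with. A conventional percentile interval is
available as `mode="percentile"`. The published intervals are much
narrower than digit-level resampling can produce (their construction is
not fully specified); they are retained in the fixture metadata as
provenance, and the package's intervals are checked for overlap with
them, not equality. Percentile-interval coverage is Monte-Carlo checked
at n = 800 under a uniform-digit generator, where the plug-in bias of
SSD is negligible relative to interval width; coverage is within 5
percentage points of nominal. All intervals are reproducible under a
fixed seed; degenerate tallies yield zero-width intervals.

## Association analyses

Kendall's tau uses the tau-b variant (scipy), which reduces to tau-a on
tie-free data such as the seven-case summary columns; it is verified
against an exhaustive concordant/discordant pair-count oracle for all
short vectors. Power laws are fit by OLS on (log10 x, log10 y), the
convention of spreadsheet power trendlines: coefficient = 10^intercept,
exponent = slope, and the reported R² is that of the log-log
regression. On the fish biomass data partitioned by first digit this
reproduces Taylor's law V = 3.36·M^2.07 exactly; the correlation
printed alongside in the source (r = 0.97) is not reproducible by
log-log OLS (which gives 0.949) and is not used as an oracle. Digit
classes with fewer than two members have undefined (NaN) variance and
are excluded from mean–variance fits.

## Packaged fixtures

Eight fixtures: digit tallies for two succession stages, two diatom
colonization scales, pre/post-1990 salamander surveys, a stream-fish
community (with its 141 raw biomass values, which re-tally to the
stored counts — verified at load), and the pooled steady-state tally
(n = 604, the element-wise sum of four constituents). CSVs are
checksummed in a manifest; `load_case` fails loudly on any edit. Each
fixture carries its published footnote statistics as regression
expectations. Two reporting artifacts in the source are documented in
the manifest rather than matched blindly: the large-island SSD prints
88.9 where full-precision recomputation gives 88.95 (tolerance 0.06 in
the regression test), and one small-island KL value differs by one unit
in the fourth decimal.

## Synthetic generators

* `gen_loguniform(n, decades, seed)` — values `10^U`, U uniform over
  `decades` orders of magnitude; exactly Benford in expectation for
  integer decades. Default study condition: 6 decades, the span both
  recommended for reliable emergence of the digit law and exhibited by
  the richest packaged cases.
* `gen_hill_mixture(n_dists, n_per, seed)` — lognormal components with
  log10-location uniform on [−2, 4] and log10-scale uniform on
  [0.3, 1.5] (roughly the span and spread of the packaged biomass
  data), `n_per` draws each. Individual components need not conform;
  the pooled sample does, on average — the aggregation phenomenon the
  pooled fixture exhibits empirically.
* `gen_digit_tally(n, probs, seed)` — multinomial null sampler, used to
  calibrate the type-I error of the d*_n ≥ 1.33 rule (≈ 0.05 at n = 200,
  5000 simulations).
* `perturb_large_digits(values, fraction, seed)` — independent thinning
  of values with leading digit 6–9, the digit signature of declining
  large-measurement individuals; SSD and KL rise essentially always at
  fraction 0.5 on a Benford-exact base sample.

All generators take an explicit seed or Generator; there is no global
RNG state. What they do **not** emulate: mechanistic population
dynamics, spatial or temporal autocorrelation, measurement error, or
rounding/reporting artifacts of field data. Passing tests on synthetic
data therefore demonstrates the statistical machinery, not that any
particular field protocol will yield Benford-conforming data.

## Problem sizes and numerical choices

The test suite runs in a few seconds on one CPU: bootstrap checks use
B ∈ [100, 1000]; the type-I calibration uses 5000 multinomial draws at
n = 200; coverage uses 300 simulations × B = 500; the Hill-aggregation
property uses 60 replicate mixtures of 50 × 100 draws; thinning uses
100 replicates of n = 2000. These sizes put Monte-Carlo error well
inside the asserted tolerances while keeping the default run fast.
Ties in Kendall tau are handled by tau-b; distribution validation uses
a 1e-9 tolerance on the unit sum; the d*/SSD identity is asserted at
1e-9 absolute.

## Known limitations

* The published confidence intervals cannot be reproduced exactly (see
  above); only overlap is checked.
* Critical values for the Euclidean distance are taken as given for
  n ∈ [80, 500] and applied asymptotically outside it with a warning.
* Second- and third-digit analyses are out of scope, as are formal
  p-values beyond the tabulated critical values, and Rényi/Tsallis
  entropy generalisations.
* Kendall Z-scores/p-values are not computed; the tau statistic itself
  is the supported quantity.
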