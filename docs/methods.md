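# Methods

## The quantification problem

Immunoblot densitometry yields band intensities that are proportional to
protein amount *times* an antibody-specific detection affinity.  Two
different proteins detected by two different antibodies therefore cannot be
compared directly: the ratio of their band intensities confounds the amount
ratio with the (unknown, often very different) affinity ratio.  The package
implements a chained calibration that removes the affinities, plus the
surrounding quantifications of a typical cell-signaling study of the AXIN1
and AXIN2 scaffold proteins: loading-control normalization and fold
changes, combined-pool composition, dual-luciferase reporter normalization,
cycloheximide-chase decay kinetics, and recruitment-fraction statistics.

## The bridging estimator

Let `a1`, `a2` be the amounts of endogenous AXIN1 and AXIN2, and `g1`, `g2`
the amounts of transiently expressed GFP-AXIN1 and GFP-AXIN2 in a
transfected lysate.  Three pairwise comparisons are run, each on one gel
with one shared antibody:

| comparison | antibody  | measures            |
|-----------|------------|---------------------|
| 1         | anti-AXIN1 | r1 = a1 / g1        |
| 2         | anti-GFP   | r2 = g1 / g2        |
| 3         | anti-AXIN2 | r3 = g2 / a2        |

Within one comparison both analytes carry the same affinity factor, which
cancels in the intensity ratio.  The chained product

    r1 · r2 · r3 = a1 / a2

is the endogenous amount ratio with *every* affinity cancelled, and the
GFP-construct amounts `g1`, `g2` also cancel — their absolute (and
experiment-to-experiment variable) expression level is irrelevant as long
as each comparison uses one lysate.  The anti-GFP antibody is assumed to
detect GFP-AXIN1 and GFP-AXIN2 with equal affinity, the model's one
substantive assumption (both constructs carry the identical tag); an
optional correction factor on comparison 2 is exposed for users who have
measured a tag-context effect, defaulting to 1.

Each comparison side is loaded as a dilution series (defaults 1:10, 1:2,
undiluted) and summarized by a least-squares line through the origin,
`intensity = slope × dilution`; the pairwise ratio is the slope ratio.
Intensities enter raw (not loading-normalized): all lanes of one
comparison come from one lysate on one gel, so lane-loading differences
are part of the measurement noise, not a bias.

**Saturation rule.**  Film/detector saturation compresses bright bands, so
a saturated undiluted lane biases the slope downward.  The lowest-dilution
(faintest) lane anchors the expected linear response; walking from the
highest dilution downward, a lane whose intensity falls below
`(1 − saturation_tolerance)` times the anchored prediction (default
tolerance 0.20) is excluded, stopping at the first lane consistent with
linearity.  The anchor is always retained.  This is a declared convention:
which lanes the original analysis kept is not recoverable from summary
figures.

**Aggregation.**  Per-experiment chained ratios are averaged on the linear
scale and reported as mean ± SEM over independent experiments, matching
how such ratios are conventionally reported.  Linear-scale averaging of a
ratio of noisy quantities carries a small Jensen (convexity) bias: with
multiplicative log-normal noise of σ = 0.15 per band, each pairwise slope
ratio is inflated by ≈ Var(slope)/μ² ≈ 1.5%, and the three-fold chain by
≈ 4.6%.  `aggregate_ratio(..., log_scale=True)` averages log-ratios
instead (geometric mean), which removes this bias; the linear scale
remains the default for comparability.

## Pool composition

With the wild-type AXIN1:AXIN2 ratio `r`, the combined AXIN1+AXIN2 pool of
untreated wild-type cells is set to 100% and split as

    pct_AXIN2 = 100 / (1 + r),    pct_AXIN1 = 100 · r / (1 + r)

(`r = 3.56` gives 78.1 / 21.9).  Every other condition's components are
the reference fractions scaled by that condition's per-analyte fold change
versus untreated wild type, and the condition's total pool is the sum of
its two components.  Knockout conditions are declared structurally
AXIN2-free (`axin2_absent`), which is distinct from a *missing* fold
change — the latter is a validation error.

**Rounding convention.**  In the default `table` mode, fold changes and
percentages are rounded to one decimal half-up *before* propagation, and
products/sums are computed in decimal arithmetic (so a tie like
21.9 × 13.5 = 295.65 rounds to 295.7; binary floating point would give
295.6499… and round down).  Every printed cell is then exactly the
product or sum of other printed cells — the property a reader checking
the table by hand expects.  `exact` mode propagates full precision and is
preferred when the table is an intermediate rather than the publication
artifact.  The two modes differ in the first decimal for some entries;
this is inherent, not an error.

## Auxiliary assays

**TOP/FOP reporter.**  β-catenin-dependent transcription is
`(TOP_luc / TOP_βgal) / (FOP_luc / FOP_βgal)`; the β-galactosidase
normalization cancels per-well transfection efficiency, the FOP (mutated
promoter) control cancels promoter-independent activity.  FOP wells are
matched within replicate; borrowing a FOP value from another replicate is
not supported.

**Cycloheximide chase.**  Protein levels (% of t = 0) are fitted as
first-order decay by ordinary least squares of `log(level)` on time with a
free intercept; `k = −slope` (h⁻¹) and half-life `ln 2 / k`.  Two or
three timepoints cannot support nonlinear fits with more parameters, and
log-OLS is deterministic and exact on noise-free exponentials.  A series
with `k ≤ 0` is flagged non-decaying rather than given a negative
half-life.  Zero levels are rejected (log undefined): a fully degraded
protein needs a detection-limit model this package does not claim.

**Recruitment fractions.**  Co-localization calls are made per cell but
summarized per experiment: each experiment contributes one percentage, and
mean ± SEM is taken across experiments.  Pooling cells would treat ~350
correlated cells as independent and understate the SEM.

**Significance.**  Two-tailed Student's t-tests, classical pooled-variance
in the unpaired case (Welch's variant behind a flag), paired by
experiment identifier where the design is paired.  Stars: `***` p < 0.001,
`**` p < 0.01, `*` p < 0.05, `ns` otherwise.  A paired test with all-zero
differences returns p = 1.0 — degenerate but reachable input, and "no
evidence of a difference" is the correct report.

## Synthetic data

The generators emulate the measurement model

    intensity = min(cap, affinity · abundance · dilution · lane_load · e^ε)

with `ε ~ N(0, σ²)` and `lane_load ~ LogNormal(0, cv²)` shared by all
bands in a lane.  Multiplicative (not additive) error is deliberate:
densitometry noise scales with signal and intensities stay positive.
Defaults σ = 0.15 and cv = 0.10 are plausible for chemiluminescent blots;
they are knobs of the generator, not claims about any particular dataset.
Draw order is fixed (experiments in order; lanes in output row order;
within a lane the loading factor, then the loading-control band, then the
target band), so a seed fully determines the output within this
implementation.

What the generators do *not* emulate: antibody cross-reactivity, gel
artifacts, blot-to-blot transfer variation, detection-limit censoring, or
image-level saturation beyond a hard intensity cap.  Passing round-trip
and recovery tests therefore demonstrates the *estimators* are correct
under the stated noise model, not that real blots meet that model.

## Validation strategy and problem sizes

Noise-free (σ = 0, cv = 0) generator output composed with the matching
pipeline stage is the identity on ground truth — ratio, fold map, decay
rate, reporter activity — and is tested exactly or to 1e-9.  Recovery
under noise is checked by a 200-study Monte-Carlo sweep (6 replicates per
study, σ = 0.15 as the sole multiplicative error, the study's design
conditions): the grand-mean ratio estimate stays within 5% of truth and
mean ± 3 SEM covers truth in ≥ 95% of studies.  These sizes keep the full
suite under a few seconds while giving the Monte-Carlo checks standard
errors well inside their tolerances.

## Known limitations

- The bridging estimator's linear-scale mean carries the ≈ (per-slope
  CV²)³ Jensen bias described above; use `log_scale=True` where unbiased
  point estimation matters more than convention.
- The saturation rule flags only monotone under-response at high load; a
  lane that is *bright* beyond linearity for other reasons (e.g. local
  background) is not distinguished.
- Pool totals in `table` mode inherit one-decimal rounding error from each
  component (worst case ±0.1 per component by construction).
- The recruitment model treats cells within an experiment as exchangeable;
  plate-position or imaging-session effects are out of scope.
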