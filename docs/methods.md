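# Methods

This note documents the models and procedures implemented in
`pareidoscope`, the defaults chosen where the design was genuinely open,
and what the synthetic-data generator does and does not emulate.

## Task and stimuli

The unit stimulus is a 300 (w) × 350 (h) canvas of i.i.d. Gaussian
luminance noise, 8-bit grayscale. Targets — 20 distinct images per
category (chimpanzee faces, human faces, letter-like glyphs), 200 × 220
pixels — are alpha-blended onto the centred target region:
`pixel = round((1 − α)·noise + α·target)` inside the region, untouched
outside. For presentation, stimuli carry a black elliptical frame
(238 × 294 bounding box, 2-px stroke, noise outside the ellipse masked to
black) and a 12 × 12 central cross (two 4-px bars). Analyses always use
the *unframed* planes: the recorded quantity is the luminance of the noise
pattern itself, and masking would only inject constant black corners into
the AOI.

Noise parameters default to mean 128, sd 30, clipped to [0, 255] —
mid-gray with clearly visible contrast, the usual regime for
Gaussian-noise classification images. Opacity defaults are 0.50 (easy)
and 0.20 (difficult); with the default observer these produce a large
accuracy gap between easy (≈ 0–2 % errors) and difficult (≈ 8–12 %)
baseline trials, reproducing the qualitative difficulty ordering of
trained observers. All geometry is centralised in `StimulusGeometry`,
which also provides proportionally scaled-down variants
(`tiny` = 1/10: 30 × 35 canvas, 20 × 22 AOI; `small` = 1/4) used by the
test suite and examples so that full analyses run in seconds.

Because target images of the original kind (photographs) are not
distributable, the target banks are procedural: faces are top-heavy
two-eyes-plus-mouth layouts with jittered geometry (the eye pair makes the
upper half darker than the lower half, the configural signature the
paradigm cares about); letters are stroke-grid glyphs. Banks are
deterministic under a seed and guaranteed pairwise distinct.

## Session structure and reward rules

A test session holds 48 trials in random order: 24 difficult baseline,
12 easy baseline, 12 test. Twenty-five sessions per category give 300
test trials. On every trial three stimuli occupy three distinct cells of
a 3 × 2 grid chosen uniformly at random; each cell is therefore used on
half of all trials in expectation. Every noise canvas id is unique across
the whole experiment.

Baseline trials reward correct choices. After an incorrect baseline trial
exactly one correction trial (the previous target alone, always resolved)
is appended and flagged; whether the original procedure repeated
corrections until success is not modelled — one flagged correction per
error is the simplest rule consistent with exclusion from analysis. Test
trials reward any choice with independent probability 0.5 (per-trial
Bernoulli draws; the alternative of balancing rewards within session would
change nothing downstream since reward never feeds back into the simulated
policy).

## Observer model

The synthetic observer operationalises a "search image" as an explicit
template `T` (by default the pixelwise mean of the trained category's
target bank). On each trial it computes the Pearson correlation `s_k`
between `T` and the AOI of each stimulus and chooses via

```
P(choose k) ∝ exp(β·s_k + bias[cell_k]),
```

mixed with a uniform lapse with probability `λ`. Response time is linear
in the strongest evidence: `rt = rt_base − rt_slope·max(s) + N(0, rt_sd)`,
floored at 1 ms. Defaults: β = 15, λ = 0.02, rt_base ≈ 1400 ms (jittered
per participant), rt_slope = 1500 ms per unit correlation, rt_sd = 150 ms.
These were set once to produce trained-observer behaviour: near-ceiling
easy baselines, clearly degraded difficult baselines, and the RT ordering
easy < difficult < test (strongest match on easy trials, none on test
trials). The choice rule and RT model are pluggable inventions — they
stand in for real decision processes, not a claim about them.

## Classification images

Per test trial, the selected plane and the mean of the two non-selected
planes are recorded (one averaged unselected observation per trial; the
per-trial average is the recorded quantity, so it enters the model once,
not as two rows). The classification image bundle holds the selected and
unselected means, their raw real-valued difference, and display-enhanced
versions via `E = (L − M)·20 + 128` with `M` the mean of the *entire*
plane (not the AOI), rounding half-up, clipped to [0, 255]. Differences
are computed on raw planes and only then enhanced; statistics never touch
enhanced planes.

## Per-pixel mixed model

The inferential model at each AOI coordinate is a Gaussian-response linear
mixed model: luminance ~ condition (selected vs unselected) with random
intercepts for participants and for trials nested within participants
(trials are unique within participant, so nesting is automatic), p-values
via Satterthwaite-type degrees of freedom — the lmerTest convention.

**Exact paired reduction.** Each trial contributes one observation per
condition, so both random intercepts cancel in the within-trial difference
`d_t = selected_t − unselected_mean_t`. Under this model the REML
fixed-effect estimate is `mean(d)`, its standard error `sd(d)/√n`, and the
Satterthwaite df is exactly `n − 1` whenever the variance components are
interior (the residual variance is then identified by the difference
contrasts alone). The full-AOI path (`fast_paired`, also backing the
`group` and `individual` variants) implements this closed form vectorised
over pixels; `mixedlm_single_pixel` fits the same model numerically with
statsmodels for spot verification, and the test suite additionally checks
a sample of pixels against R's `lmerTest`. A participant random intercept
on the differences themselves would correspond to a condition-by-
participant random *slope*, which is not part of the model above; the
paired reduction is therefore intercept-only. Note the equivalence is an
identity of fits at interior variance components; on data with literally
zero participant/trial variance a numerical optimiser sits on the boundary
and its residual-variance estimate may differ from the paired one by
sampling noise.

Degenerate pixels (zero difference variance) are flagged, their p-values
set missing and excluded from the FDR family, with the count reported —
never silently assigned p = 0.

**FDR.** All non-degenerate AOI pixels of one analysis (one category, one
variant) form a single Benjamini–Hochberg family at q = 0.05; separate
analyses are corrected separately.

**Null calibration.** `random_selection_null` re-draws each trial's
"selected" stimulus uniformly over the three presented patterns and
re-runs the identical analysis. Because the redraw is independent of the
pixel values, raw p-values are then uniform and, with independent pixels,
the BH family-wise rejection probability under this global null is exactly
q — so ~95 % of null replicates show zero significant pixels; calibration
checks use the corresponding binomial sampling band.

## Secondary analyses

- **Log-RT model:** natural-log RT of non-correction trials, fixed effects
  category × trial type, participant random intercept, Wald 95 % CIs.
  Contrast direction is explicit: `A_vs_B` = mean(B) − mean(A) on the log
  scale. Random slopes are not fitted (the random-effect structure beyond
  intercepts is an open choice; intercepts-only is reported and labelled).
- **Position bias:** chi-square goodness of fit of chosen grid cells
  against uniformity over the 6 cells, computed on test trials only —
  bias is meaningful where no target exists. The bias-vs-clarity summary
  pairs each (participant, category) chi-square with the mean *raw* AOI
  p-value (all pixels, not only significant ones) and correlates them by
  Spearman's rho (midranks; one-tailed option available).
- **RT median split:** per participant, test trials with RT ≤ median form
  the faster half. With an evidence-dependent RT model the faster half
  yields the higher template-recovery correlation — a direction-only
  property, checked as such.
- **Brightness contrasts:** AOI coordinates are the observational units;
  category means with SEs, and pairwise contrasts *paired by coordinate*
  (all maps share the same grid), giving the narrow CIs such a design
  implies.
- **Image similarity:** radially averaged 2-D FFT amplitude (mean removed,
  integer-radius annuli, `floor(min(h,w)/2)` bins, DC bin dropped before
  logs) compared by Pearson correlation of log-profiles; and plain
  Euclidean distance between planes.

## What the generator does and does not emulate

The simulator reproduces the *design*: session composition, grid
placement, unique noise, correction flow, non-contingent test rewards, and
choice behaviour driven by a pixel template. It does not emulate gaze
(every similarity is computed on perfectly registered planes, so real
free-viewing blur is absent and template recovery here is an upper bound),
learning across sessions, motivational dynamics, or photographic target
structure. Passing tests therefore validate the *analysis machinery* —
that the pipeline recovers planted templates and stays silent under
random selection — not any claim about biological observers.

## Problem sizes and numerical choices

Tests and examples run at tiny (1/10) and small (1/4) scale — 440 and
2,750 AOI pixels, 108–1,200 test trials — where every stage completes in
seconds; the full-scale 44,000-pixel map is the same vectorised
computation. Rounding of 8-bit outputs is half-up; raw analysis planes
stay float64. Sub-seeds for categories, participants and stages are
derived deterministically from the experiment seed, making every artifact
byte-reproducible. Known limitations: the paired reduction assumes the
two-condition-per-trial structure (it would not extend to unbalanced
designs with missing conditions); luminance heteroskedasticity between
conditions (the unselected mean of two canvases has half the variance of
one canvas) is absorbed into the paired difference variance, which keeps
the paired test exact but makes the equal-variance long-format model an
approximation; and the brightness-contrast model treats coordinates as
exchangeable units, ignoring spatial autocorrelation.
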