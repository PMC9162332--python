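# Methods

`switchscope` quantifies stochastic white-opaque switching of *Candida
albicans* from three kinds of single-cell data: time-lapse trap movies
(Wor1-GFP reporter), curated pedigrees of tracked cells, and flow-cytometry
dose-response plates of a synthetic Wor1 autoregulation circuit.  Because
the package is developed and tested against ground-truthed synthetic data,
this note describes both the analysis methods and the generative model the
synthetic data follow, and is explicit about what passing tests do and do
not establish about real data.

## The two-step switching model (generator)

Each microfluidic trap starts from one white founder cell.  Cells divide
with Gamma-distributed interdivision times (mean 84 min, sd 20 min, chosen
so a trap reaches its ~400-cell capacity near 12 h of a 24 h movie at
12-min frame cadence); divisions arrest when the trap is full (crowding).

Switching requires two stochastic events:

1. **Predisposition.**  At any division the newborn daughter may, with
   probability `p_predispose` = 2.67e-3, found a *predisposed clan*.  The
   predisposed state is heritable for a span of 1–4 divisions (drawn
   uniformly per clan) counted from the founder's birth.
2. **Activation.**  At each division inside a clan (division distance from
   the founder within the span), with probability `p_activate` = 0.25 the
   dividing mother–daughter pair jointly activates the Wor1 reporter.

Activated cells rise logistically from the white level (1, arbitrary
units) to the opaque level (40, i.e. the 40-fold expression difference
between states), with a 10–90% rise time of 3 h and a birth-to-maximum
time drawn from a lognormal with (untruncated) mean 9.9 h and sd 3.2 h,
truncated to [5.4, 17.2] h — the observed span of measured switching
events.  The mother's rise midpoint is jittered by at most one frame
relative to the daughter's, so pair activation is synchronous at the
movie's cadence.

**Inheritance is level-gated**: a daughter is born opaque only if her
mother's reporter is already past the rise midpoint at the division;
daughters budded while a switching mother is still low are born white and
inherit the clan's predisposition instead (within the span).  This
reproduces the observed mixed-fate pedigrees in which a mother and her
first and third daughters ultimately activate while the second does not,
and it is what makes scheme-2 event counts overdispersed relative to
Poisson (see below).

`p_predispose` and `p_activate` are a **calibration, not a prediction**:
they were fixed (by bisection over large simulations) so that the expected
fraction of traps with zero activation events equals the observed 134/168,
with the activation rate chosen so predisposed clans yield multiple
asynchronous switching groups at a realistic rate.  All reporter levels
are relative to the white baseline; the study reports no absolute
intensity units.

What the generator does **not** emulate: pseudohyphal branching
morphology, nuclear oscillations of Wor1 during mitosis (available only as
an optional modulation, off by default), polyploidization through nucleus
loss, uneven illumination, and focus drift.  Passing round-trip tests
therefore demonstrates the correctness of the measurement and statistics
code under the stated noise model, not robustness to every artifact of
real microscopy.

## Image analysis

- **Registration**: translation-only, estimated between consecutive
  DIC frames by the phase cross-correlation peak with 1/20-pixel
  refinement and accumulated to frame 0; uncovered borders are
  zero-filled.  Trap fields do not rotate, so a richer geometric model is
  unnecessary.
- **Segmentation**: the sum of a white top-hat and a black bottom-hat
  response (disk structuring elements, default radius 6 px ≈ cell
  radius/4) is thresholded (Otsu by default), closed by dilation (3 px),
  hole-filled, eroded back (3 px), and filtered by area, perimeter, and
  eccentricity ranges.  The operator sequence is fixed; every scale is a
  `SegmentationParams` field because the source pipeline specifies
  operators, not scales.  Defaults were tuned on the synthetic fixture.
- **Wor1 metric**: the mean of the 300 brightest GFP pixels inside a cell
  mask (nuclear-localized Wor1 concentrates signal); objects smaller than
  300 px are averaged whole and flagged.  No background subtraction is
  applied — non-GFP white cells define the background level.
- **Length**: the mask's major-axis length, an automated surrogate for the
  hand-drawn long-axis line; percentile comparisons use linear
  interpolation between order statistics and strict inequality for
  "longer than".

## Trace classification

Traces are LOESS-smoothed (locally weighted linear regression).  The
generic smoother takes a span as a fraction of points (default 0.3); the
switch classifier instead uses a fixed 7-frame (84 min) window, because a
fractional span on a 24 h trace would average over many hours and distort
a 3 h rise.  A cell is called opaque-state when its smoothed trace exceeds
the geometric mean of the white and opaque reference levels — a scale-free
midpoint in log space — for at least 3 consecutive frames; cells born
above threshold are "opaque" (inherited state), cells that cross it during
the movie are "switching".  Birth-to-max is the first crossing of 95% of
the cell's own maximum, with the maximum estimated robustly as the median
of the top decile of smoothed values so that residual noise peaks in the
plateau do not systematically delay the crossing.  Rise time is the
interpolated 10%-to-90% crossing interval of the white-to-opaque range.
Frames at or after a recorded nucleus-loss event are excluded.  Remaining
known bias: smoothing broadens the measured rise by roughly 0.1–0.2 h and
delays the 95% crossing by a few tenths of an hour; both are well inside
the spread of the published kinetics.

## Event grouping and counting schemes

Mother–daughter pairs that activate within 2 frames (24 min) of each other
are synchronous.  Switching cells are grouped by connected components over
*synchronous* mother–daughter edges: simultaneity is what distinguishes a
direct pattern (pair, or the extended four-cell chain) from separate
events within one lineage — a mother whose first and third daughters
activate at different times contributes two groups.  Per trap, events are
counted under three schemes: (1) every synchronous pair (a group with no
complete pair still counts one event, so scheme 1 never undercounts
scheme 2); (2) every group; (3) every ancestor-sharing cluster of groups
(mixed-fate pedigrees merge; with fully recorded single-founder traps this
is an any-event indicator, which is the faithful reading of the scheme).

The null is Poisson with rate λ = −ln(n₀/N) estimated from the zero-event
class alone (the maximum-likelihood rate given the zero/nonzero
dichotomy); expected class counts pool k ≥ 4 into a tail (configurable).
Goodness of fit is Pearson χ² with a Monte-Carlo p-value over 2,000
multinomial replicates by default, using the add-one estimator
(1 + #{sim ≥ obs})/(reps + 1) so p is never exactly zero.

## Flow cytometry and Hill fitting

The generator produces per-well event tables (FSC, SSC, GFP, mCherry,
V670) for four constructs: Wor1-mGFP (monomeric fusion), Wor1-GFP
(dimerizing fusion), free GFP (induced 10-fold higher, never activates the
reporter), and unlabeled Wor1.  Protein induction is a shared saturating
Hill curve in hormone (half-max 2 nM, slope 1.5, 100-fold dynamic range);
per-cell protein is lognormal around the well median (cv 0.40), channel
measurement noise is small (GFP cv 0.05, mCherry cv 0.15).  The reporter
follows a 4-parameter log-logistic response in per-cell protein with Hill
coefficients 3.2 (mGFP) and 4.3 (GFP) and a 5-fold half-max ratio
(K_mGFP = 15, K_GFP = 3 protein units); the dimerizing fusion's reporter
declines above 2 nM hormone (0.5 log10 per hormone decade), emulating
putative negative regulation by Wor1 dimers.  Debris (10%, low scatter)
and aggregates (5%, high scatter and high violet autofluorescence) carry
ground-truth labels.

Analysis: two rectangular gates on raw channels (FSC/SSC; GFP/V670 with a
violet upper bound), then FSC normalization (gfp_n = GFP/FSC; events with
FSC ≤ 0 dropped and tallied), then a fit of

    log10(mcherry_n) = c + (d − c) / (1 + exp(−h (ln x − log K)))

on pooled single cells across wells, with x = gfp_n floored at its 0.1th
percentile.  The default loss is **least median of squares**, minimized by
multi-start Nelder–Mead seeded from an ordinary least-squares fit (the
multi-start perturbations are fixed, so fitting is deterministic),
followed by the standard efficiency-restoring step: a least-squares refit
on the points within 2.5 robust standard deviations of the LMS curve.
This resists the clumping/bimodality artifacts of strong Wor1 induction
while keeping near-least-squares precision on clean data.  The
half-max is parameterized on the natural-log scale, so rescaling x by α
shifts log K by exactly ln α and leaves c, d, h unchanged.  For the
dimerizing fusion only wells below 2 nM hormone enter the fit.  Per-day
fits are aggregated per construct (mean ± sd of h, ratio of mean K, Welch
two-sample comparisons); fitting pooled single cells is the default, with
per-day replication providing the spread.

## Orchestration and reproducibility

`run_pipeline` executes simulate → segment → call → eventstats/flowfit,
writing plain artifacts (TIFF movies and label masks, TSV pedigrees,
calls and counts, JSON report).  Every stochastic stage derives its seed
from the global seed plus the stage name (SHA-256, reduced below 2³¹), so
a run is bit-reproducible from one integer and any stage can be recomputed
exactly from the config and seed alone; large intermediates (per-cell
traces for ~67,000 cells) are regenerated rather than reloaded.  Problem
sizes used throughout (168 traps × ~400 cells, 10 wells × 5,000 events,
8 replicate strain-days per construct, 2,000 Monte-Carlo replicates)
mirror the study design.

## Known limitations

- The mechanism of the predisposing first event is unknown; the per-division
  Bernoulli clan model is one admissible choice, selected as the minimal
  model reproducing direct pairs, four-cell patterns, and mixed-fate
  pedigrees.
- Segmentation is tuned for isolated-to-moderately-crowded cells; densely
  packed traps need the curated-table path, as in the original
  semiautomated workflow (tracking there was manual).
- The Hill fit's predictor is measured per-cell GFP, so strong GFP
  measurement noise would attenuate h (regression dilution); the generator's
  small channel noise reflects FSC-normalized measurements, and fits on
  real data with larger predictor noise would need an errors-in-variables
  treatment.
- Exact published p-values and colony-sector frequencies depend on
  unpublished per-trap counts and colony data and are out of scope.
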