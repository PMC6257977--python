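# Methods

This note documents the models and procedures implemented in `pairscreen`,
the parameter defaults and why they are what they are, the numerical
choices made where the procedure itself leaves freedom, and what the
synthetic-data generator does and does not emulate.

## Plate model and replicate merging

A checkerboard layout assigns every treated well to one `(drug pair, c1,
c2)` concentration patch; the dose grids include the zero doses, so the
single-drug margins and the untreated `(0, 0)` corner are part of every
pair's matrix.  Specifications are CSV
(`well,drug1,conc1,drug2,conc2,role,replicate`) or an equivalent JSON; the
validator enforces canonical well ids, plate bounds (384-well = 16×24 by
default, other formats via `PLATE_GEOMETRIES`), unique well assignment, and
homogeneous replicate groups.

Replicates are merged by the mean, but only when their **sample** standard
deviation (n−1 denominator), expressed in percentage points of survival
index, is *strictly below* the threshold (default 30).  Groups at or above
it are excluded from every downstream table and rendered as white "X"
patches.  The strict inequality and percentage-point scale were chosen so
"below 30%" reads on the same scale on which survival is displayed.
Singletons have SD 0 and are always kept.

## Viability and synergy

Blank and control signals are aggregated by the **median**, which is robust
to the occasional failed control well.  Survival values are stored
unclipped (noise can push them slightly outside [0, 1]); figures clip to
the display range.

Sign conventions: the Bliss index is positive when observed combination
survival falls below the independence product (synergy = extra killing);
the therapeutic index is positive when reference cells survive better than
target cells.  The refinement weights used for ranking are `1 − s12` for
the scaled Bliss index and `s_ref` for the refined therapeutic index — both
damp patches where the raw index is large but practically uninteresting
(combination barely kills, or the reference dies too).  Both weights are
plain multipliers in [0, 1], are configurable per run, and are recorded in
the result metadata so outputs are self-describing.

## Background model and segmentation

The background band is global: per well, the median pixel of the first
`n_untreated_frames` frames (all of those frames' pixels pooled — slightly
more robust than frame 1 alone); the median of that pool is `μ_b`, and
`τ = [(1−δ)·μ_b, (1+δ)·μ_b]` with δ = 0.05 by default and user-configurable.
A pixel is foreground iff it lies outside τ; the boundary values belong to
the background.  Because δ is multiplicative the model is invariant to
uniform intensity rescaling.  There is deliberately no adaptive or local
thresholding and no illumination correction — the method's robustness
against background artefacts comes from ignoring background pixels
entirely, not from modelling them.

## Hierarchical histogram features

Schedule: level 1 histograms the original frame with `b0` bins (16 for the
analysis, 128 for QC); level j histograms the frame downscaled by `r^(j−1)`
per dimension with `b0·b^(j−1)` bins, fractional counts floored, and the
hierarchy stops before the bin count would fall below 2.  Hence
`(16, b=1/2) → [16, 8, 4, 2]` and `(128, b=1/8) → [128, 16, 2]`.

Numerical choices:

- **Downscaling** is exact area-weighted averaging (per-axis overlap weight
  matrices).  For integer reciprocal factors this is a plain block mean;
  for non-integer factors boundary pixels contribute proportionally to
  their overlap.  It is deterministic, mass-preserving and has no
  interpolation kernel parameters.
- **Bin edges** are uniform over the full dtype range (e.g. [0, 255] for
  8-bit), identical for all frames and wells, rightmost bin closed.  Fixed
  edges make features comparable across the plate; float inputs require an
  explicit `value_range`.
- **Foreground at reduced resolutions** re-applies the τ predicate to the
  downscaled image rather than downscaling the mask — τ is a pure pixel
  predicate and this keeps every level self-consistent.
- **Empty-foreground levels** contribute a zero block and a warning, so
  matrices stay rectangular; QC is expected to remove pathological wells.

In foreground mode each level is normalised to unit mass, making features
independent of confluence (doubling the foreground at fixed texture leaves
them unchanged).  In all-pixels mode (QC) raw counts are kept, because
there confluence differences are exactly what should be noticed.

Extraction follows a map/reduce contract: the map step computes one frame's
feature vector, the reduce step stacks columns per well in time order.
Per-frame computation is independent and deterministic, so the assembled
matrices are bit-identical for any worker count (`joblib` backs the pool).

## Quality control

Over the untreated frames only, with the fixed QC hierarchy (128 bins,
r = 1/4, b = 1/8, all pixels): each well's matrix rows are averaged over the
untreated columns, deviations from the plate mean are L1-compressed into a
pool, and wells at or above 1.5× the pool's 95th percentile (linear
interpolation between order statistics) are flagged.  Two guards:

- if the 95th percentile is exactly 0 (all wells identical) nothing is
  flagged — otherwise the ≥ rule would flag every well;
- the plate mean includes eventual outliers (they are unknown at that
  point); a single pass is the minimal reading, and iterating the mean was
  judged not worth the added statefulness.

Flagged wells are excluded from everything downstream — deviation analysis,
confluence, optimisation — and the background model is re-estimated without
them (one extra pass), the conservative reading of "excluded from all image
processing".

## Deviation analysis and the null threshold

Controls are scored leave-one-out: `ΔH(c) = H(c) − mean(others)`, which
makes the control deviations sum exactly to zero; treated wells are
compared against the mean of *all* controls.  The L1 norms of the control
deviations form the null pool; its 95th percentile (configurable) is the
threshold τ, and `d̃ = ‖ΔH‖₁/τ − 1` is reported per well.  Wells with
`d̃ > 0` (strict) are detections, so by construction ≈5% of i.i.d. controls
are false alarms — the calibration the acceptance script measures.

Two documented resolutions of ambiguity:

- `N_D` is the *count* of detected wells (an integer, as the detection
  curves display); the sum of positive `d̃` values is additionally exported
  as a "detection strength" since a summed form is also defensible.
- A degenerate null (τ = 0, all controls identical) does not abort the run:
  treated wells with positive magnitude get a `d̃ = +inf` sentinel and the
  table is flagged, because a run-killing error on a synthetic corner case
  helps nobody.

Heatmaps clamp `d̃` to [−100%, +100%] for display; CSV/TXT outputs always
carry raw values.

## Parameter optimisation

The `(r, b)` grid — default {1/4, 1/2} × {1/8, 1/2}, configurable — is swept
over the decreasing windows `[t_k, t_n]`, k = 1..n, all ending at the last
post-treatment time point (13 windows for 13 time points).  The null pool
and threshold are recomputed *inside* every window, so thresholds are never
shared across parameter settings or windows.  Features are extracted once
per grid pair over the full range and windows are column slices, which is
mathematically identical to re-extracting per window because features are
per-frame.  The optimum per window maximises `N_D`; ties break to the first
grid pair in run order.  Everything is deterministic.

## Confluence

`c(t)` is the foreground fraction of the frame (N = 1310720 pixels at the
native 1024×1280 frame size).  Relative curves `c̃(t) = c(t)/c(t₁) − 1` are
anchored at the first **post-treatment** frame; the untreated acquisition
frames feed only QC and the background model.  Wells with `c(t₁) = 0` are
flagged invalid instead of dividing by zero.  The untreated reference curve
is the pointwise median over QC-surviving control wells.  Figures use the
[−50%, +120%] display window; CSVs are raw.  No growth-model fitting
(exponential/logistic) is done — the curves themselves are the result.

## Synthetic data generator

The generator produces exactly the statistics the pipeline measures:

- background `μ = 100` with Gaussian noise (sd 1.5, clipped to ±4) —
  strictly inside the default τ = [95, 105], so truth masks are exact;
- elliptical blobs with intensities from a two-mode mixture (modes 160 and
  220, sd 8, clipped to [118, 250]) — strictly outside τ; the mixture
  weight is the *morphology* parameter, so a treatment-induced morphology
  shift changes the foreground histogram at constant confluence;
- blob-count trajectories (`count·growth^t`) set confluence dynamics; blobs
  persist across frames, so growth adds and death removes them;
- planted pathologies: a pure-noise outlier well and (via a large growth
  factor) a runaway-growth contamination well;
- per-well RNG streams spawned from `(seed, well index)`: byte-identical
  output per seed, independent of generation order.

Defaults mirror the acquisition protocol being emulated: 15 frames per
well, the first 2 untreated, at desk-scale 64×80 frames (the native
1024×1280 geometry is exercised once in a full-frame confluence check).
What the generator does **not** emulate: phase-contrast optics (halos,
shade-off), cell shape and texture beyond intensity statistics, spatial
plate effects, or focus drift.  Passing tests therefore demonstrate the
statistical machinery — calibration, detection power against
intensity-distribution shifts, exact confluence bookkeeping — not
robustness to optical artefacts of real microscopes.

## Problem sizes used in the shipped checks

The calibration experiment uses 100 simulated plates × 100 control wells,
64×80-pixel frames, 2 untreated + 4 post-treatment frames per well, and the
(r, b) = (1/2, 1/2) schedule with 16 bins; with ~100 distinct control
magnitudes per plate the interpolated 95th percentile leaves exactly 5
controls above threshold, so the measured rate concentrates tightly at 5%.
Worker-invariance and ground-truth-recovery checks use a 96-well plate at
the same frame size.  These sizes were chosen so the entire suite runs on a
laptop-class single CPU in a couple of minutes while still exercising every
pipeline stage at realistic well counts.

## Known limitations

- Detected morphology changes are non-directional: `d̃` says *that* a well
  deviates from untreated behaviour, not *how*.
- The refinement weights for the scaled Bliss and refined therapeutic
  indices are simple defaults; groups with an in-house ranking convention
  should supply their own weight functions (the API takes callables).
- Inter-plate replicate statistics are out of scope; the unit of analysis
  is one plate (plus an optional reference plate for therapeutic indices).
- No Loewe, HSA or ZIP synergy models — Bliss and therapeutic indices only.
- The global background interval assumes a dominant, roughly uniform
  background in the untreated frames; very high seeding densities would
  violate that assumption.
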