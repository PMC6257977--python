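# pairscreen

Pairwise drug-combination screening analysis for plate-based in-vitro
experiments: end-point **viability and synergy** from plate-reader
fluorescence, and label-free, time-resolved **morphology** and **confluence**
quantification from phase-contrast video-microscopy movies.  It is aimed at
drug-discovery groups running checkerboard combination screens (two drugs at
all pairwise doses, including the single-drug margins) on 96/384-well plates
with an incubator microscope, who want more than a single end-point readout.

## What it computes

**Survival index.**  For a well with fluorescence signal `f`,

    S(c1, c2) = (f − f̃_blank) / (f̃_control − f̃_blank)

where `f̃_blank` and `f̃_control` are the medians of the blank and untreated
growth-control wells.  Intra-plate replicates are merged only when their
sample standard deviation is below 30 percentage points; over-dispersed
patches are excluded and rendered as white "X" patches.

**Synergy.**  Per concentration patch, with `s1, s2` the single-drug and
`s12` the combination survivals:

- Bliss index `B = 100·(s1·s2 − s12)` (positive = more killing than
  independence), scaled variant `B_S = B·(1 − s12)` for ranking;
- therapeutic index `T = 100·(s_ref − s_target)` against a reference
  (toxicity) cell-model plate, refined variant `T_RW = T·s_ref`.  A positive
  `T` is a therapeutic window: target cells die, reference cells survive.

**Morphology (detection of treatment-induced change).**  Every frame is
reduced to hierarchical pixel histograms: the image is histogrammed at its
original resolution and at consecutively reduced resolutions (factor `r` per
level), with the bin count shrinking by factor `b` per level until it would
drop below 2.  Only foreground pixels — those outside the global background
intensity band `τ = [0.95·μ_b, 1.05·μ_b]` — are counted, and each level is
normalised to unit mass, so the features track morphology, not confluence.
Stacking the per-frame vectors gives the per-well matrix `H_w`.  Deviation
from the untreated behaviour is `ΔH = H − H̄_control` (leave-one-out for the
controls themselves); its L1 norm, compared with the 95th percentile `τ95`
of the control pool, gives the relative difference

    d̃ = ‖ΔH‖₁ / τ95 − 1,

positive values are detections, and the false-alarm probability is 5% by
construction.  The `(r, b)` parameter pair is chosen by maximising the
number of detections `N_D` over a grid ({1/4, 1/2} × {1/8, 1/2} by default)
and over decreasing time windows.

**Confluence.**  `c(t)` is the fraction of foreground pixels per frame, and
growth curves are expressed relative to the first post-treatment frame,
`c̃(t) = c(t)/c(t₁) − 1`.

Before any of this, an image quality-control step flags outlier wells from
the untreated frames (all-pixels histograms, 128 bins; a well is excluded
when its deviation norm reaches 1.5× the pool's 95th percentile).

## Worked example

```python
import pairscreen as ps

spec = ps.SynthSpec(shape=(64, 80), n_frames=8, n_untreated=2, seed=0)
recipes = {f"c{i:02d}": ps.WellRecipe() for i in range(20)}          # untreated controls
for i in range(6):                                                   # drug-treated wells
    recipes[f"t{i:02d}"] = ps.WellRecipe(morphology=0.7, growth=0.85)
recipes["x00"] = ps.WellRecipe(outlier=True)                         # imaging artefact
plate = ps.synth_plate(spec, recipes)
roles = {w: "growth_control" if w.startswith("c") else "treated" for w in recipes}

run = ps.run_morphology(plate.datastore, roles, n_untreated_frames=2)
print(sorted(run.qc.flagged))          # ['x00']      — artefact well excluded by QC
opt = run.optimization
print(opt.n_detections[:, -1])         # [6 6 6 6]    — all 6 treated wells detected
best = opt.best_table(len(opt.intervals) - 1)
print(round(best.pool.tau, 4))         # 0.2412       — null threshold τ95
rec = best.by_well()["t00"]
print(f"{100 * rec.d_tilde:+.1f}%")    # +328.3%      — far above the null

conf = ps.run_confluence_workflow(plate.datastore, roles, n_untreated_frames=2)
print(conf.curves["t00"].relative[-1]) # ≈ -0.57      — 57% confluence loss
```

The treated wells carry a planted shift of the foreground intensity
distribution (`morphology=0.7` vs the control 0.25) plus cell death
(`growth=0.85`); the pipeline detects every one of them at a relative
difference far above the 5%-false-alarm threshold while the pure-noise well
is caught by QC, and the confluence module independently quantifies the
die-off.

The same analyses run from the shell on an image datastore
(`<WELL>_<T>.tif` files) plus a plate-specification CSV:

```
pairscreen synth --out ds --pairs 1 --doses 3 --plate-format 96 --frames 6 --shape 48x64
pairscreen morphology --datastore ds --spec ds/plate_spec.csv --untreated-frames 2 --out morph
pairscreen confluence --datastore ds --spec ds/plate_spec.csv --untreated-frames 2 --out conf
pairscreen viability  --reader reader.csv --spec ds/plate_spec.csv --out viab
```

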