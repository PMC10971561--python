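# Methods

`needlegrade` re-implements, as a tested pipeline, a workflow for grading
insect defoliation damage of larch stands from UAV canopy imagery: camera
reflectances are condensed into vegetation indices and co-occurrence
texture statistics per tree crown, screened for class sensitivity,
reduced to a low-redundancy subset, and fed to random-forest and small
convolutional classifiers whose confusion matrices grade recovery of the
four-level damage scale. Because no suitable imagery of this kind is
publicly deposited, every stage runs against a synthetic scene generator
that encodes the structural assumptions of the analysis. This note
records the model, the defaults and the judgement calls.

## Damage grading model

A tree's defoliation is summarised by its leaf-loss rate
`DR = 100 * L_d / (L_h + L_d)` (percent), where `L_h` and `L_d` count
healthy and damaged needles over sampled branches; branch rates are
averaged per tree. Four damage levels partition DR: Healthy [0, 5],
Mild (5, 30], Moderate (30, 70], Severe (70, 100]. The conventional
bands are printed as integers (0–5 / 6–30 / 31–70 / 71–100); we close
them half-open at the upper edges so fractional rates are always
gradable while every printed integer keeps its printed level.

## Synthetic scenes

The generator emulates an orthomosaic of a surveyed stand:

* **Layout.** Crowns are filled ellipses (radii drawn from 4–6 px) on a
  non-overlapping grid with jittered centres, classes shuffled across
  cells. Masks are exact pixel sets; every crown has ≥ 9 pixels.
* **Colour.** Class mean RGB reflectances follow the canopy progression
  green → yellow → red → grey: (0.20, 0.45, 0.18), (0.45, 0.48, 0.20),
  (0.55, 0.35, 0.18), (0.40, 0.40, 0.40). Each tree's mean is jittered
  by N(0, 0.04) per channel (between-tree variability — no field value
  exists for this, so it is a judgement call: small enough that classes
  remain identifiable, large enough that neighbouring classes overlap in
  single channels). Pixels add class-dependent noise ("texture grain",
  sd 0.020 / 0.035 / 0.050 / 0.065 for levels 1–4), the lever that gives
  co-occurrence statistics class signal.
* **Multispectral planes** (optional): b, g, r mirror the camera
  channels; the red-edge and near-infrared means fall with damage
  (NIR 0.75 / 0.62 / 0.50 / 0.38), the canonical stress response, so
  NIR-bearing indices respond to class.
* **Noise sources.** A soil-like background (0.32, 0.26, 0.20) with
  sd 0.015, and shadows: 15% of each crown's pixels darkened ×0.5 —
  shadowing is the dominant feature-noise source in real orthomosaics.
  Reflectances are clipped to [1e-4, 1]; the strictly positive floor
  reflects that sensors never record exactly zero radiance and keeps
  log-based indices defined.
* **Survey truth.** Needle totals are drawn uniformly in [200, 1200] and
  the damaged count uniformly over the integers whose DR lies inside the
  tree's class band, so survey grading round-trips the generating class
  exactly.

What the generator does **not** emulate: radiative transfer, mixed
pixels at crown edges beyond hard masks, crown overlap/occlusion,
georeferencing artefacts, understory vegetation, and the label noise of
real field surveys (upper/lower canopy disagreement). Tests passing on
these scenes therefore validate the *machinery* — formulas, selection,
training, evaluation, reproducibility — and the qualitative orderings
the generator encodes, not field-level accuracy.

## Features

**Vegetation indices.** A registry evaluates per-pixel index formulas
and averages them over each crown mask. Formulas with published
definitions in the source tables (ExG, ExR, GLA, CIVE, GCC, GBRI, RBRI,
RGRI, VDVI, GB, and the multispectral set 2NLI, GDVI, GMNLI, NDVIreg,
SI1reg, SI1reg\*, TCARI, MTVI2, Int2reg\*, NDSIreg, RECI, SCCI, SI2reg)
are normative; indices named without formulas (VARI, GRVI, NGRVI, PPR,
WI, ExGR, RGBVI) use standard literature definitions and are flagged
`literature-sourced` in the registry. Lower-case r, g, b in published
RGB formulas are treated as the channel reflectances (no chromatic
normalisation). Ratio denominators that are exactly zero are replaced by
1e-9 — reflectances are noisy non-negative floats and a per-pixel hard
failure would be unusable; crown averaging keeps the resulting outliers
rare. Where two published rows assign one index conflicting formulas,
the definitional table wins (the conflicting rows duplicate other
indices' formulas verbatim — a typesetting misalignment).

**Texture.** The RGB channels are projected onto the leading principal
component of the 3×3 channel covariance (sign fixed so the green loading
is non-negative, output rescaled to [0, 1]), quantised to 32 grey
levels, and summarised by sliding-window grey-level co-occurrence
matrices: window 7×7, offsets (0,1), (1,0), (1,1), (1,−1), symmetric —
common remote-sensing co-occurrence practice; the source gives no
parameters. Eight statistics (mean, var, hom, con, dis, ent, sm, corr)
use the standard Haralick forms; the typeset variants carrying a
spurious leading `i` factor inside dis/ent/sm are available as
`texture_stats(..., paper_literal=True)` for comparison but are not used
in the pipeline. Each pixel's matrix collects the symmetric pairs whose
origin falls in its window (reflective padding at edges); statistics are
computed per offset and averaged — averaging statistics rather than
matrices keeps the nonlinear entries (ent, sm) interpretable per offset.
Per-tree texture features are crown means of the statistic rasters
(raster-then-average, matching the tree-by-tree mean-extraction
description). Degenerate single-level windows define corr := 1.

## Screening and selection

Each feature is screened by a one-way ANOVA of its per-tree value
against damage level. The F statistic uses the classical k−1 / n−k
degrees of freedom; the *thresholds* reproduce the published convention
F_crit(4, 840) — 3.34 at tail 0.01 and 13.57 at tail 1e-10 — which
treats (number of classes, number of trees) as the degrees of freedom.
Both conventions are exposed (`anova_f` vs `f_critical`). The 1e-10
reading of the ambiguous "0.01^-10" tail is used because it reproduces
the printed 13.57.

The successive projections algorithm (SPA) then reduces the sensitive
set. From every candidate start feature a chain grows by repeatedly
appending the feature whose residual, after orthogonal projection onto
the span of the chain (centred calibration columns, incremental
Gram–Schmidt), has maximal norm; the successive argmax residual norms
contract monotonically. Every chain prefix of size k in [k_min, k_max]
is scored by the validation misclassification of a nearest-class-centroid
model on standardised features — cheap, deterministic, and agnostic to
the downstream classifiers — and the lowest-error subset wins, ties
breaking to smaller k then lexicographic order. SPA runs on the
ANOVA-sensitive features only, matching the narrative order of the
source method (screen, then de-redundify). Exactly collinear columns
can never be co-selected: the second one's residual is zero.

## Classifiers

Trees are split 75/25 into train and test, stratified by level so small
test sets keep all classes (a plain random split is available via
`stratify=False`). Min-max normalisation bounds are fitted on the
training trees and applied to all; screening and SPA also see only
training trees.

* **Random forest**: 500 bagged trees, unlimited depth, √m features per
  split (scikit-learn), Gini importances normalised to sum 1. The
  source gives no hyperparameters; these are stable defaults at n ≤ 840.
* **CNN**: a 1-D convolutional network over the feature vector in SPA
  selection order — 16 kernels of width 3 (zero-padded), ReLU, max-pool
  2, dense 32, softmax over the four levels; Adam at 1e-3, batch 32,
  200 epochs. Implemented directly in numpy with explicit
  backpropagation; at these sizes (≤ ~30 features, ≤ 840 trees) training
  takes seconds and is bit-reproducible for a fixed seed. Importances
  are the mean absolute loss gradient with respect to each input,
  normalised to sum 1.

The sample-size sweep draws, for each size in {140, …, 840}, an
independent stratified subsample per seed (largest-remainder
apportionment), splits, trains and evaluates. Independent draws (rather
than nested subsets) were chosen because nothing in the source indicates
nesting; each draw is seeded by (seed, size).

## Evaluation

Confusion matrices are oriented rows = predicted, columns = actual, so
user accuracy (commission) is row-wise and producer accuracy (omission)
column-wise. Overall accuracy is trace/S — the multiclass form of the
binary (TP+TN)/(TP+TN+FP+FN), to which it reduces at k = 2 — and Cohen's
Kappa is (OA − p_e)/(1 − p_e) with p_e = Σ N_p·N_t / S². Kappa is
undefined (NaN sentinel) when both axes hold a single class; zero-margin
classes report NaN accuracies rather than raising.

## Reproducibility

All randomness flows from one root seed through named substreams
(scene, split, spa, rf, cnn, sweep) derived via `SeedSequence` with a
CRC of the stream name, each below 2³¹. Repeated runs of
`run_experiment` at a fixed seed are byte-identical, including the
sweep CSV.

## Problem sizes

The default study is one 840-tree scene (210 per class, ~464×464 px).
The test suite exercises the full-size configuration for the
parameter-recovery and sweep checks (10 seeds for the feature-set
comparison) and smaller scenes (5–30 trees per class) elsewhere; these
sizes keep a complete run of the suite in the tens of minutes on one
CPU while leaving every structural property at full scale.

## Known limitations

* Synthetic colour/texture separability is far cleaner than field data;
  absolute accuracies here (~0.98 for colour-bearing sets) exceed what
  the emulated field study reports (~0.85–0.91) and should not be read
  as field performance. The qualitative orderings — texture augments
  colour, texture alone is insufficient, multispectral ≥ RGB — are the
  meaningful outputs.
* The red/green ratio is monotone only through the green→yellow→red
  stages; the grey (severe) class returns it to ~1 by construction.
* SPA's subset is chosen once per feature set and reused across sweep
  sizes; the emulated workflow re-selected per size, which is
  substantially more expensive and changes nothing structurally.
* `read_scene` rasterises crown polygons by pixel-centre containment,
  which reproduces ellipse masks only approximately at the boundary.
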