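# Methods

This note documents the estimators, the synthetic-data model, the
statistical and classification protocols, and the design choices made
where the problem left the design open.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Raster conventions and descriptor estimators

Rasters are row-major with 0-based coordinates; label 0 is background and
cell labels are contiguous positive integers.  All measurements use the
**pixel-corner polygon** model: pixel (r, c) occupies the unit square
with corners (r, c)–(r+1, c+1).  Under this convention a w × h pixel
rectangle is exactly w × h units — the convention of classical
particle-analyzer tools, which the descriptor set mirrors.  Lengths scale
linearly and areas quadratically with `pixel_size` (default 1 µm/px), by
construction and exactly.

**Area** is the foreground pixel count times the pixel area.  Holes
inside a cell region are filled before any measurement; holes inside the
colony footprint are *not* filled away for packing purposes — they count
toward the intercellular space.

**Perimeter.** The crack boundary (the polygon of pixel corners
separating foreground from background, traced keeping the region on the
right) is exact for axis-aligned shapes but overestimates oblique
boundaries by up to 41 %.  We therefore simplify it: the ring is reduced
to its corner vertices; corners whose turn direction agrees with both
neighbouring corners are *pinned* (these are the true corners of
rectangles, single pixels and 1-px-wide shapes, which must survive); the
staircase chains between pinned corners are straightened with
Douglas–Peucker simplification at a tolerance of 1.2 px.  The result is
exact on axis-aligned rectangles (10×10 px square → 40, single pixel →
4) and converges on digitized disks (+0.8 % at r = 50 px, +0.1 % at
r = 200 px).  Because Douglas–Peucker tie-breaking could in principle
depend on traversal order, the mask is first brought to a canonical
orientation (lexicographically smallest of its four 90° rotations), which
makes lossless rotations yield bit-identical perimeters.  A Crofton
estimator (scikit-image) is available via `method="crofton"` for
cross-checks; it is accurate on smooth blobs but not exact on rectangles,
which is why the traced estimator is the default.

**Ellipse axes** come from the region's second central moments (pixel
centers as point masses), with both axes rescaled so the ellipse area
equals the pixel-count area — the area-matched convention, giving
π/4·major·minor = area to machine precision.  Collinear-pixel regions are
degenerate: minor = 0 is reported with a warning and no rescaling is
attempted.

**Feret diameters** are calipers over the convex hull of the boundary
corner points: the maximum via the antipodal-pairs walk, the minimum as
the smallest edge-normal width (the minimum width of a convex polygon is
always attained perpendicular to an edge).  On a w × h rectangle this
gives √(w²+h²) and min(w, h) exactly; the maximum caliper is verified
against exhaustive pairwise search in the tests.

**Shape factor** is 4πA/P², not clamped: rasterization can push
near-circular regions slightly above 1, and such values are logged rather
than hidden.

**AIS** (area of intercellular space) is defined by subtraction: filled
footprint area minus the summed cell areas.  The definition is purely
set-theoretic, so a space-filling tessellation has AIS = 0 exactly.  When
a footprint is not provided, `fill(closing(union of cells))` with a
configurable closing radius (default 3 px) would stand in; the synthetic
generator always provides one.

## The synthetic-data model

The generators define the study conditions under which everything
downstream is validated.

**Colony images.** A colony footprint is a radially perturbed disk whose
area follows the line's growth curve `base_area · exp(rate · (t − 24 h))`
(non-decreasing by validation); the perturbation is a low-order Fourier
profile scaled by `boundary_irregularity`, plus narrow Gaussian spikes
when irregularity is high (the spiky-edge look of deteriorating
colonies), normalized to preserve the target area.  Cells are seeded by
dart throwing with a minimum spacing of 0.8 cell diameters, grown into an
anisotropic Voronoi tessellation (each cell has a random orientation and
an elongation factor entering the metric, so cells come out elongated),
made 4-connected by fragment merging, and finally eroded from their
boundaries — each cell losing a share proportional to its size — until
the free space matches the target `gap_fraction` to within pixel
rounding.  This construction gives *independent* control of packing,
elongation and edge irregularity, and makes the realized gap fraction
essentially exact rather than approximately targeted.  The defaults are
1 µm/px, rasters of at least 512×512, and cell diameters of 10–16 µm
(12 µm good, 14 µm bad), the scale of hPSC cells in monolayer colonies.
The bad preset (gap 0.16 vs 0.05, elongation 2.0 vs 1.3 with a 10 % tail
of doubly elongated outliers, irregularity 0.10 vs 0.03) is a calibration
choice: the magnitudes of real phenotype differences are not published,
so the presets are set to the ~75 % separability regime in which such
classifiers operate, and the tests treat them as ground truth only in
that sense.

**Descriptor tables** are multivariate-normal draws per (line, phenotype)
group: a common size factor (correlation 0.7 among the five size
descriptors), AIS moderately coupled to size (0.4) and anti-correlated
with shape factor (−0.3).  The default line structure mirrors the study
design: one larger, faster-growing ES-like line in which good colonies
are bigger and better packed; one iPS-like line with the size effects
reversed; and one line with no single-descriptor mean shift, separable
only through descriptor combinations.  Shape-factor draws are clipped to
(0, 1] and the caliper/axis ordering invariants are enforced on the
draws.  Clonality is an independent binary label with no morphological
effect — it matters only for expression, which is where clonality is
linked to biology.

**Ct panels** place each target gene at a base Ct (default 25 cycles),
lowered by log₂(fold) in groups with a planted fold change; the reference
gene sits at a fixed Ct (default 18) in every sample.  Every technical
measurement adds i.i.d. Gaussian noise (`noise_sd`, default 0.2 cycles);
candidate housekeeping genes can carry extra per-sample instability for
the stability screen.  Defaults are technical triplicates and three
biological repeats, the usual qPCR design.

What the generators do **not** emulate: phase-contrast appearance and
segmentation error (inputs are assumed correctly labeled), colony growth
mechanics and cell division, passage-dependent drift, and any coupling of
clonality to morphology.  Passing tests therefore demonstrate the
correctness and calibration of the measurement and analysis machinery
under the declared statistical structure — not that real colonies are
classifiable at any particular accuracy.

## Statistics

Group summaries use time bins {24}, {48}, {72–120} h (late time points
pooled), with SEM = SD/√n over the units in a bin.  Two-group
comparisons are gated on normality: Shapiro–Wilk at α = 0.05 on each
sample selects Welch's unequal-variance t-test when both pass, otherwise
Mann–Whitney.  Welch is preferred over Student's because group sizes are
unbalanced in practice; a zero-spread sample never passes the gate.  The
two-way line × phenotype ANOVA uses Type II sums of squares (appropriate
for unbalanced designs with no interaction-driven main-effect ambiguity)
and reports the interaction term; every design cell must contain at
least two observations, and empty cells are named in the error.  No
multiple-testing correction is applied across the seven descriptors by
default, matching per-descriptor α = 0.05 reporting; a Holm option
exists but is off.  The phenotype screen is restricted to 24–48 h, the
window in which phenotypes are scored.

Calibration is verified by simulation: 2000-replicate null rates of both
tests sit at 0.05 ± 0.01, and a 1-SD interaction (phenotype shift
flipping sign across three lines, 30 observations per cell) is detected
with power ≳ 0.99.

## Classification protocol

The classifier is a *declared* stand-in for an automated model search
that cannot be reproduced from its description: a single-hidden-layer
feed-forward network (lbfgs, fixed iteration cap) over the grid
{4, 8, 16} hidden units × {1e−4, 1e−2} L2 strength, with a
logistic-regression family for fast runs.  Inputs are standardized
inside each training fold (an internal model detail — no other
preprocessing is applied to the data); every grid point is evaluated on
the same repeated stratified k-fold splits (default 10 × 5-fold) and the
best mean accuracy wins, earlier grid point on ties.  SEM is computed
across repeat-level accuracies.  Everything is a pure function of
(data, config, seed).

Importance is the unweighted mean accuracy over all subsets (sizes 2..p)
containing a descriptor — 2^(p−1) − 1 models each — sorted descending
with alphabetical tie-break.  The top-k curve trains the k best
descriptors for k = 2..p; the minimal model is the smallest k with mean
accuracy ≥ (best mean) − (SEM at the best k).  Whole-sample evaluation
pools out-of-fold predictions over one stratified split by default
(resubstitution is available by flag); reported percentages are rounded
half-up.  For cellular descriptors, a configurable pre-filter drops a
descriptor whose absolute correlation with an already-retained one
exceeds 0.95 — the caliper diameters track the ellipse axes almost
exactly at the cell scale and only slow the enumeration down.

Simulation sizes in the tests and the acceptance script (60 records per
group, 5-fold CV with 1–2 repeats, logistic family, 100 replicates for
the ranking study) are chosen to make the planted-signal properties
sharp at minute-scale runtimes; the library defaults remain the full
protocol.

## Expression quantification

Classical comparative Ct with amplification efficiency fixed at 2 (no
efficiency correction is modeled).  Technical replicates are averaged
first; per biological replicate, ΔCt = Ct(target) − Ct(reference gene)
and the relative quantity is 2^−ΔCt.  A group's fold change is its mean
relative quantity divided by the reference group's mean, so the
reference group's pooled fold change is exactly 1, the quantification is
invariant under any global Ct shift, and lowering a target's Ct strictly
raises its fold change.  SEM is over biological replicates on the
normalized scale; per-gene tests reuse the normality-gated comparison
(unpaired — pairing across biological repeats is not assumed), with
stars at 0.05/0.01/0.001/0.0001.  The reference-gene screen scores
candidates by the SD of their per-sample mean Ct; geNorm-style pairwise
scores are out of scope.  Differentiation-marker panels (embryoid-body
experiments) are the same operations on a different gene list and
grouping — there is deliberately no separate code path.

## Numerical and degenerate-input choices

* Perimeter tolerance 1.2 px: below ~1.0 the staircase survives
  (oblique overestimate), far above it thin features could be shaved;
  1.2 is exact on rectangles and <1 % on r ≥ 50 px disks.
* Erosion during gap carving orders pixels by (EDT distance, row,
  column), making tie-breaks deterministic; a cell is never erased below
  one pixel, with its unmet quota redistributed.
* Voronoi fragments (a cell pinched into pieces by carving or metric
  ties) are merged into the neighbouring label they touch most, or
  released as intercellular space when isolated.
* Constant-and-equal samples in the gated comparison return p = 1
  (no evidence of difference) instead of an undefined test statistic.
* `min_feret ≤ feret` and `minor_axis ≤ feret` are enforced on synthetic
  draws and validated on loaded external rows; violating rows are
  rejected individually with their index and reason.

## Known limitations

* The traced perimeter is a quantization-corrected estimator, not a
  sub-pixel boundary: expect ~2 % error on cell-sized (r ≈ 10 px)
  regions and up to ~5 % below that.
* The minimal-model rule depends on the SEM at the maximizer; with very
  few CV repeats the SEM estimate itself is noisy, and k\* can wobble by
  one on flat curves.
* The anisotropic Voronoi construction realizes *relative* elongation
  (bad cells measurably more elongated than good), not the exact target
  axis ratio — packing constraints shrink realized elongation below the
  nominal value.
* Whole-sample confusion matrices from pooled out-of-fold predictions
  are mildly optimistic relative to fully nested evaluation when the
  grid search is active; the default grid for the logistic family is a
  single point, where the distinction vanishes.
* Segmentation itself is out of scope: garbage masks in, garbage
  portraits out.
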