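# Methods

This note documents the measurement models implemented in `nucmorph`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical decisions that affect results.

## Chromatin condensation parameter (CCP)

CCP treats heterochromatin as internal image structure: the DAPI intensity
inside a nucleus mask is min–max normalized to [0, 1], a 3×3 Sobel gradient
magnitude is computed (reflected padding at image borders), pixels whose
magnitude exceeds a threshold are counted within the mask interior, and the
count is divided by the full mask area. Values therefore lie in [0, 1].

Decisions:

- **Normalization.** Per-nucleus min–max normalization makes CCP invariant to
  affine intensity rescaling (staining brightness, exposure), so it compares
  texture, not brightness. A uniform-interior nucleus scores exactly 0.
- **Threshold.** The default policy `fracmax:0.1` thresholds at 0.1 × the
  largest Sobel magnitude attainable on a unit-range image (4√2). Anchoring
  the fraction to this fixed scale — rather than to the per-nucleus gradient
  maximum — keeps the threshold absolute after normalization: uniform nuclei
  score 0, and progressive blurring of a texture lowers the score
  monotonically, both of which fail when the threshold floats with each
  nucleus's own maximum. `otsu` (Otsu on the gradient magnitudes) is
  available as an alternative; the policy is recorded in the result.
- **Rim exclusion.** The mask is eroded by one pixel (3×3 structuring
  element) before counting, because the nucleus boundary is otherwise the
  dominant "edge" in the image. Heavy smoothing can still carry rim
  gradients deeper than one pixel; CCP comparisons should use consistently
  acquired images.
- **Denominator.** Edge pixels are divided by the *mask area* (not the
  eroded interior or the edge-candidate count); this is documented because
  conventions differ between labs.
- Percent change is `100 · (CCP_i − mean(control)) / mean(control)` per
  nucleus, against a vehicle-control population; a zero control mean is an
  error, not a NaN.

## Nuclear aspect ratio (NAR)

NAR is the axis ratio of the ellipse with the same second central moments as
the mask (eigenvalues λ₁ ≥ λ₂ of the pixel-coordinate covariance; axis
length 4√λ). The moment ellipse was chosen over bounding or boundary-fit
ellipses because it is robust to boundary pixelation and has an exact
analytic transform under affine maps, which the strain ground truth uses.

- **Pixel-size correction.** Each pixel is a unit square represented by its
  centre; the continuous region covariance exceeds the centre covariance by
  the within-pixel variance 1/12, so 1/12 is added to each eigenvalue
  (Sheppard-style). Without it, small near-circular nuclei bias NAR upward
  by >1 %. Degeneracy (minor axis < 1 px on the raw moments) is an error.
- **Accuracy envelope.** On random ellipses with semi-axes ≥ 20 px the
  measured NAR is within 1 % of the analytic axis ratio; below ~10 px
  semi-axis, boundary pixelation can push errors to ~3 %. High-magnification
  imaging (nucleus ≥ 20 px across) is assumed.
- **Tracking.** Nuclei are matched frame-to-frame by greedy nearest-centroid
  pairing after compensating the global stretch, estimated per axis from the
  ratio of centroid-cloud standard deviations (exact for a pure diagonal
  affine stretch). Maximum displacement defaults to 15 px. Tracks that lose
  their nucleus are censored from later frames, not interpolated.
- **Response summary.** Per-track OLS slope of NAR vs strain, plus the
  pooled Pearson correlation of (strain, ΔNAR) with ΔNAR relative to each
  track's strain-0 value. A zero-variance pooled ΔNAR (rigid motion) reports
  r = 0 with a `constant` flag instead of NaN.

## 3D migration scoring

- **Interface.** Per-plane tissue occupancy (Otsu-binarized over the whole
  stack) rises from ~0 to a plateau; the interface is the first z, linearly
  interpolated between planes, where occupancy crosses half the plateau.
  Both stack orientations are handled, so flipping a stack in z negates all
  depths. For an ideal step profile the estimate sits half a z-step shallow
  of the first occupied plane — an irreducible half-step ambiguity at finite
  z sampling.
- **Cells.** Local maxima of the Gaussian-smoothed cell channel
  (σ = blob radius / 2 per axis, in voxel units) above 0.3 × the smoothed
  maximum, with a minimum separation of twice the blob radius enforced in
  physical units; z is refined to sub-plane precision by a parabolic fit
  through the peak's z-profile.
- **Embedded.** "Fully embedded" is operationalized as depth ≥ margin
  (default: the blob radius, 5 µm), since per-cell 3D segmentation is out of
  scope. Percent migrated = 100 × embedded / total.
- Cumulative-frequency curves count depths ≤ each bin edge; the maximum
  depth is appended as a final edge when not covered, so curves always end
  at 100 %.

## Scratch closure

Confluent monolayers are speckle-textured while the wound void is flat, so
the void is detected in a local intensity-variance map (7 px window) rather
than raw brightness (cells and void may share mean intensity). The variance
map is thresholded by Otsu *on a log scale* — on a linear scale the threshold
collapses into the texture mode once the void is a small fraction of the
frame. Safeguards: (1) the candidate void's mean variance must be below
0.2 × the cell region's, otherwise the frame is declared confluent and
area 0 is returned with a flag; (2) the sliding window erodes the void by
its half-width at the void/cell boundary, so the detected component is
dilated by window // 2 before measurement (residual bias < 1 %). The void
must span the full frame height (wounds are scratched across the field).
Closure rate is the OLS slope of area vs time over frames before the first
zero-area frame.

## Matrix and intensity scoring

Nascent-matrix area is the Otsu-thresholded foreground of the matrix channel
with speckles below 50 px² removed, divided by the nucleus count of the
paired channel. A QC flag is raised when > 20 % of the foreground sits at the
saturation level, since densely overlapping staining cannot be interpreted
reliably. Per-cell intensity is the mean over each nucleus mask ("per cell"
is taken as per nucleus mask; whole-cell ROIs are not segmented), and
percent-positive uses a strict `>` against the supplied threshold.

## Segmentation

Otsu threshold (fixed-threshold override available), hole filling, optional
distance-transform watershed seeded by h-maxima (h = 2 px) for touching
nuclei, minimum area 50 px², consecutive relabeling. Coordinates are 0-based
(row, col) with half-open bounding boxes.

## DE summaries

The significance rule is padj < 0.05 **and** |fold change| > 2, both strict,
with the fold-change cut applied on the linear scale (|log2fc| > 1), matching
common DESeq2-output conventions. NaN padj rows are dropped with a logged
count. Correlations use genes matched by id across both tables (no
imputation); the `gene_filter` argument chooses the gene universe — callers
typically pass the union of each table's DE sets.

## Group statistics

Two groups: unpaired two-sided t-test, pooled variance by default (Welch
optional). Three or more: one-way ANOVA with Tukey's HSD (studentized-range
based, family-wise α = 0.05). Identical constant groups report statistic 0,
p = 1 rather than NaN. The null type-I error of the ANOVA path is verified
by simulation in the test suite.

## Synthetic-data generator

The generator emulates exactly the statistical structure the metrics consume,
not microscopy physics:

- **Nucleus fields**: non-overlapping ellipses (mean radius 20 px, axis ratio
  0.8–1.0), a smooth interior background, and punctate heterochromatin foci
  (12 per nucleus, Gaussian, σ = 0.12 × radius) whose contrast scales with a
  condensation knob in [0, 1]. Within-mask intensity variance is strictly
  increasing in the knob; at 0 the interior is uniform. Foci positions are
  drawn identically across knob settings at a fixed seed, so condensed and
  decondensed fields are geometrically matched. Default field: 25 nuclei,
  matching typical per-condition sample sizes in this assay.
- **Strain series**: the base frame is resampled under the plane-strain map
  x → (1+ε)x along columns about the image centre, with transverse
  contraction 1/(1+ε) by default (area-preserving) or none; strains default
  to 0–15 %. Truth NAR is computed analytically from the transformed ellipse
  quadratic form, and truth label maps are transformed with nearest-neighbour
  interpolation.
- **Migration stacks**: tissue channel fills z ≥ interface (default 20 µm);
  cells are 3D Gaussian blobs (radius 5 µm) at sampled depths, placed without
  xy overlap. Truth marks a cell embedded iff depth ≥ blob radius. Sampled
  depths keep a guard band (default one z-step) away from that threshold,
  because at finite z-resolution the flag is ill-defined for borderline
  cells; the guard is part of the generator's definition of unambiguous
  ground truth, and detection is still required to classify every cell
  correctly from the images alone.
- **Scratch series**: uniform speckle texture (0.3–1.0) with a central
  low-intensity band narrowing linearly; truth area is the realized integer
  band width × frame height.
- **DE tables**: true-effect genes get |log2fc| uniform in [1.5, 4] and padj
  below 0.05; null genes get |log2fc| < 0.9 and padj in [0.05, 1], so the
  truth set is exactly recoverable and filter errors are attributable to the
  filter, not the fixture.

Not emulated: optical PSFs, shot noise by default (additive Gaussian and
Poisson noise are available but off in fixtures), uneven illumination,
overlapping or dividing nuclei, z-dependent attenuation, and realistic
DE p-value distributions. Passing tests therefore demonstrate correctness of
the measurement code under its stated assumptions, not robustness to every
imaging pathology; the fixed-threshold and windowing defaults above are the
knobs to revisit for real data.

## Problem sizes

The test suite and `scripts/acceptance.py` use 25-nucleus fields, 4–10
nucleus strain series at 4–6 strain levels, 20 migration stacks of 12 cells
(plus one 40-cell stack), 5-frame scratch series at 500×512 px, 1000-gene DE
tables, and 1000 null simulations for ANOVA calibration — sizes chosen so a
full verification runs in about a minute on one CPU while keeping Monte-Carlo
error well inside the asserted bounds.
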