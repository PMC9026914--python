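# Methods

This note documents the models, algorithms, parameters and design
choices behind `mitohcs`, and what its validation on synthetic plates
does and does not establish.

## Image model and conventions

Input images are single-plane grayscale TIFFs (8/16-bit unsigned), one
file per channel/field/well, named `RRRCCC-F-TTTSSSCCC.tif` (3-digit
zero-padded row, column, time, stack and channel; 1–2 digit field).
Intensities are normalized to [0, 1] by the full range of the source
bit depth at load time, so every threshold in the package is expressed
on that scale and is independent of camera bit depth. Pixel
coordinates are 0-based row-major; object labels are positive integers
with 0 = background; connectivity is 8-connected throughout (labeling,
propagation, skeletons). The default physical scale is 0.299 µm/px
(40x water objective, binning 2, 1080 × 1080 fields), overridable in
the config; all µm values are px × `pixel_size_um` exactly.

## Illumination correction

Shading is modeled per image as a full quadratic surface
a + bx + cy + dx² + ey² + fxy over normalized coordinates, fitted by
least squares and subtracted with clipping at zero (negative
fluorescence is meaningless and downstream thresholds assume
non-negative input). Rank-deficient fits (degenerate grids) fall back
to the pseudo-inverse with a warning. Correction is per image, not
pooled across the plate, and is applied to every channel an assay
consumes. The order-2 choice keeps the surface too stiff to absorb
real structure at cellular scales.

## Thresholding

All histogram methods use a fixed 256-bin histogram on [0, 1]:

* **Otsu 2-class** maximizes between-class variance over all cuts;
* **Otsu 3-class** maximizes three-class between-class variance over
  all cut pairs; the *middle class* is assigned to foreground (keeps
  dim puncta — appropriate on background-free enhanced images) or to
  background (suppresses dim debris and upper background noise — used
  for nuclei and for puncta detected on raw channels);
* **minimum cross-entropy** (Li) minimizes the cross-entropy criterion
  over all cuts.

Tied optima are resolved to the **midpoint of the tied plateau**: on a
histogram with an empty gap between modes every cut inside the gap is
equally optimal, and the midpoint places the threshold mid-gap instead
of hugging one mode. This matters for sparse-foreground images, where
hugging the background mode floods the field at the first noise bin.

Adaptive scope computes per-window thresholds on a block grid (window
default 51 px), clamps them to [0.7, 1.5] × the global threshold
(blocks devoid of real foreground would otherwise threshold into the
noise floor), bilinearly interpolates to a per-pixel threshold
surface, and finally applies the user bounds. Foreground is strictly
above the threshold, so a constant image yields empty foreground (with
a degenerate-histogram warning).

## Segmentation hierarchy

**Primary objects (nuclei).** Threshold (global three-class Otsu,
middle class to background, by default) → connected components → hole
filling → equivalent-diameter filter (default 10–80 px) → optional
border exclusion → compact relabeling. Touching nuclei are *not*
declumped (no watershed); they merge, and the size filter is the only
remedy — a documented limitation.

**Secondary objects (cells) by propagation.** Seeded shortest-path
region growing restricted to the above-threshold region of a
cytoplasmic channel: a step from p to its 8-neighbor q costs
|I(p) − I(q)| + λ·len(step) with len 1 axial and √2 diagonal. Each
above-threshold pixel joins the seed of minimal accumulated cost; large
λ approaches the geometric nearest-seed partition, small λ lets
intensity valleys draw the dividing lines. λ defaults to 0.05. Costs
are computed by vectorized label-correcting relaxation (Bellman–Ford
over the grid), which converges to the exact Dijkstra solution because
step costs are non-negative. A seed entirely below threshold keeps
itself as its own object, with a warning.

**Tertiary objects (cytoplasm).** Per-label set difference
cell − nucleus, preserving label ids so the exact area identity
area(cell) = area(cytoplasm) + area(cell ∩ nucleus) holds per object.

**Filtering.** Objects are filtered by (feature, min, max) criteria on
area, eccentricity, intensity etc., and optionally by border contact.
No cutoffs are inherited from any instrument; package defaults are
nucleus area 100–10,000 px², eccentricity ≤ 0.95, border cells dropped.

## The three assays

**H2O2 (speckle colocalization).** The MitoPY1 channel is enhanced by a
white top-hat (image minus its opening) with a disk of radius
⌈feature_size/2⌉, feature_size defaulting to 35 px — the upper puncta
diameter, so no valid punctum is suppressed. The disk is applied as its
cross-decomposition sequence (O(radius) per pixel rather than
O(radius²)). Puncta are primary objects of equivalent diameter 3–35 px
under an adaptive three-class Otsu (middle class kept: the enhanced
background is exactly zero, so the middle class holds dim puncta).
Each punctum is assigned to the cell containing its centroid; centroids
on background are dropped. The per-cell level is
coloc_area / mito_area, the mitochondrial mask coming from a
three-class Otsu (bright class) on the corrected MITO-ID channel; a
puncta-area denominator is available in config. Cells with empty
mitochondrial mask are excluded and counted, never reported as zero.

**MMP (JC-10 ratio).** Monomer (cell) regions are the secondary
objects grown from nuclei on the green channel. Aggregates are primary
objects of diameter 3–15 px on the raw corrected orange channel, using
adaptive three-class Otsu with the middle class to background (on a raw
channel the dominant background mode occupies the lower classes) and a
0.05 lower threshold bound (~10x read noise) so aggregate-free fields
detect nothing. Mutual masking is "keep overlapping region, retain
labels": A* = aggregates ∩ the cell's monomer region, M* = monomer
region ∩ the aggregate footprint (the literal reading; the complement
is a config alternative). The ratio uses mean (not integrated)
intensities, robust to the area asymmetry between A* and M*, and is
computed per cell then averaged per well. Cells with empty A* or M*
are excluded and counted.

**Morphology (granularity + skeleton length).** The MITO-ID channel is
enhanced by a Hessian-eigenvalue tubeness filter at scale σ = 1.5 px
(response |λ₂| where λ₂ < 0, rescaled to [0, 1]); tubes respond more
strongly than equal-height blobs. The binary mask is
enhanced ≥ max(Li threshold, 0.1): the manual floor guards against the
whole-image rescaling pulling the histogram threshold into the noise.
Objects are filtered to 3–100 px equivalent diameter.

The granular spectrum is computed per cell on the **binary
mitochondrial object image** restricted to the cytoplasm (raw or
enhanced sources are config options): subtract the opening with a disk
of radius `element_size` (default 10 px, background removal), then
iterate L = 16 rounds of erosion with a disk of radius 1 followed by
morphological reconstruction under the original; g_i is the percent of
total intensity removed at round i. No subsampling by default
(subsample = 1.0): the tubes are only ~3 px wide at this magnification
and do not survive 4× downsampling; a fraction < 1 is available for
speed on coarser structures. The headline `fragmentation_percent` sums
the first k = 3 bins — the scale just above the tube half-width, where
punctate fission fragments are removed but intact tubes survive.

Skeletons come from topological thinning; endpoints are skeleton
pixels with exactly one 8-neighbor; lengths are geodesics along the
skeleton with weights 1/√2, computed by Dijkstra on the per-object
pixel graph; an object's length is the maximal endpoint-pair geodesic
(the longest path). Objects thinning to < 2 endpoints (e.g. fission
puncta) record length 0, flagged, and *are included* in the per-cell
mean — fragmentation therefore pulls the mean length down both by
shortening tubes and by adding zero-length puncta. Note that thinning
replaces a sharp right-angle corner with a diagonal step, so an
L-shape of two 10-px arms measures 16 + √2 ≈ 17.41 px, not 18.

## Statistics and QC

Per-cell values are pooled within condition for inference, matching
how distributions are displayed; per-well and per-field means are also
emitted, and the run log notes that wells are technical replicates of a
single plate (n = 1 per condition at the plate level). Summaries are
mean ± 1.96·SE (95% normal CI; undefined and flagged for n < 2).
Outliers are flagged by the Tukey boxplot rule (1.5×IQR beyond the
quartiles, linear-interpolation quartiles) and reported, never removed.
More than two groups: one-way ANOVA with Tukey HSD adjusted pairwise
p-values; two groups: Student's equal-variance t-test (Welch behind a
flag). Stars: * < 0.05, ** < 0.01, *** < 0.001.

## Synthetic plate generator

The generator is the package's study-condition definition, not a
tuning knob. Defaults emulate the target acquisition: 1080² 16-bit
fields at 0.299 µm/px, 15–40 cells/field, 60 fields/well, 2 wells per
condition. Each cell has an elliptical nucleus, a circular body with
diffuse cytoplasmic haze, and 5–9 gently curving mitochondrial tubes in
the perinuclear-to-periphery annulus. Condition knobs: `puncta_density`
(mean MitoPY1 puncta per cell, Poisson counts, placed on tubes),
`polarization` (JC-10 aggregate amplitude ∝ p, monomer haze ∝ 1 − p),
and `fragmentation` (per-tube probability of collapsing into 2–3
punctate fragments — real fission yields puncta, and fragments are
rendered smaller than the tube width so size-resolving granulometry can
see them). A quadratic illumination bias and Poisson–Gaussian noise
(full-scale photon count 5000, read noise σ 0.004) are added per
channel; identical design + seed reproduces every TIFF bit-for-bit.

What the generator does **not** emulate: optics (no PSF beyond Gaussian
blur), photobleaching, cell-to-cell staining heterogeneity beyond
Poisson counts, z-structure, or touching/overlapping cells. Passing
dose–response tests therefore demonstrates that the pipeline recovers
known generative orderings under realistic noise and bias — not that
absolute levels match any particular instrument or cell line, which
depend on chemistry and optics outside desk-scale reproduction.

## Validation problem sizes

Tests and the acceptance script run a scaled-down design (256² fields,
4–7 cells/field, 2 wells × 3 conditions; 10 fields/well × 10 seeds in
the test suite, 6 fields/well × 5 seeds in the acceptance script) with
cell geometry scaled to match — chosen so the full three-assay
validation completes in minutes on one CPU while keeping ≥ several
hundred cells per condition. Dose–response checks compare condition
means pooled across seeds (Spearman ρ over the 3 ordered conditions)
and require the package's own ANOVA to reject at p < 0.05.

## Known limitations

* No declumping of touching nuclei; dense fields bias cell counts low.
* The propagation cost uses local intensity differences only, not
  gradients along the path as some implementations do; dividing lines
  on plateaus fall at the octagonal (not exactly Euclidean) bisector.
* Granularity on binary masks discards intensity weighting inside
  mitochondria; the raw-image option restores it at the cost of
  sensitivity to staining brightness.
* The per-cell H2O2 level depends on the mitochondrial-mask threshold
  family; switching it rescales levels plate-wide (dose orderings are
  robust to this, absolute values are not).
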