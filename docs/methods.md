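# Methods

## Scope and data model

The pipeline quantifies multi-channel fluorescence fields of macrophage
monolayers stained with Hoechst 33342 (all DNA), SYTOX Orange
(membrane-impermeant DNA dye: dead-cell nuclei and endo-lysosomal DNA
puncta), MPO (cell bodies and traps) and CitH3 (citrullinated histone 3,
the MET marker). Every stage consumes a `ChannelStack` — a
`(channel, z, y, x)` nonnegative intensity array with named channels and a
pixel size — and produces either a labeled-region table (`label`,
`area_px`, centroid, `mfi`, bbox) or a typed result object. Coordinates are
pixel-centered, 0-based, x rightward, y downward. Channels are addressed by
configured name, never acquisition order, because 3- and 4-channel
experiments are mixed.

## Segmentation chain

All measurements build on one chain: threshold → morphological close
(disk, radius 1 by default) → hole fill → optional watershed split →
connected components (8-connectivity, the particle-counting convention) →
per-label measurement, with a minimum-area filter and optional border
exclusion. The watershed operates on the negated Euclidean distance
transform, seeded by regional maxima after h-maxima suppression
(h = 2 px by default, capped at half the maximal distance so small objects
always keep one seed). This splits touching round nuclei or cells without
over-fragmenting single ones; watershed only reassigns foreground pixels,
so total labeled area never exceeds the thresholded foreground.

Automatic thresholds are Otsu per image. Two situations need care:

* **After nuclear blackout** the zeroed pixels would dominate the Otsu
  histogram; the threshold is therefore estimated over non-excluded pixels
  only.
* **Sparse bright objects** (puncta, MET blobs occupying ≪ 1% of pixels)
  can make any histogram-splitting threshold collapse into the background
  mode — Otsu and ISODATA each fail on different degenerate histograms.
  Detection of such objects floors the automatic threshold at
  background median + 6 × 1.4826 × MAD. The floor is inactive on noiseless
  images (MAD = 0) and never rejects real objects, since anything below
  the noise floor is undetectable in principle.

## MET scoring

CitH3 is present both in nuclei and in released traps; only the latter
count. The nuclear label mask (from Hoechst) is filled with black in the
CitH3 image, the remainder thresholded, raw segments counted, and the
binary mask dilated three times with a radius-1 disk so that the several
fragments a single trap typically segments into merge into one component.
Counting is on post-dilation components; increasing the iteration count can
only merge further, never split, so the merged count is non-increasing in
the dilation depth. Percent is taken against the nuclear count of the same
field; fold change requires an explicit positive reference percent
(typically the spontaneous release of control cells). Border-touching
segments are excluded by default. With Otsu thresholding the percent is
invariant under uniform rescaling of the CitH3 channel.

## Condensation gating

Apoptotic nuclei are small and densely stained. The gate flags nuclei with
`area < a·median(area)` and `MFI > m·median(MFI)`; the relative form
(defaults a = 0.7, m = 1.4, requiring ≥ 10 nuclei for stable medians) is
the default because it is acquisition-independent. The module constants are
design choices of this package, not published gate coordinates — the
hand-drawn gates such studies use are not recoverable. Absolute thresholds
are available. The gate is monotone: tightening either threshold never
increases the flagged count.

## Puncta detection and classification

Cell bodies are segmented on the MPO channel (watershed on, so touching
cells separate); DNA puncta are detected on a DNA channel after excluding
the nuclear mask, which is first dilated by 2 px to absorb the PSF-blurred
nuclear rim — without this, rim fragments register as spurious puncta on
noisy images. Detected components below 3 px are discarded (shot-noise
suppression; no size filter is inherent to the method). Each punctum is
assigned to the cell whose ROI contains its centroid; centroids outside
every cell are tallied separately as extracellular. For z-stacks, slices
are thresholded with one volume-wide threshold and linked into 3-D
components (26-connectivity); both linked and per-slice counts are
reported, since whether a punctum visible in several slices is one object
or several is an acquisition-level ambiguity.

Staining positivity per channel defaults to a **per-cell contrast rule**: a
punctum is positive when ≥ 50% of its pixels exceed twice the median
intensity of its own cell's non-nuclear, non-punctum pixels in that
channel. Puncta are bright relative to the diffuse stain of their own cell,
so this is robust to staining strength, to the extreme pixel-class
imbalance that defeats global histogram thresholds, and to cytoplasmic MPO
(diffuse MPO stays below 2× its own median; punctate MPO accumulations do
not). Global ISODATA, fixed, and background-MAD rules are available
options. The combination classes are the nested sequence H, H+S, H+S+M,
H+S+M+C; any non-nested flag pattern is reported as "other". Class
fractions are normalized to the total punctum count.

## Colocalization

The Manders coefficient is computed in one direction only — the fraction of
cytoplasmic DNA signal residing in protein-positive pixels — because
control cells contain essentially no cytoplasmic DNA, making the reverse
coefficient meaningless there. Nuclear pixels are removed from both
channels first; thresholds are per-channel (Otsu after nuclear removal by
default, explicit values recommended when the protein channel has a diffuse
cytoplasmic component; `t_dna = 0` reproduces the unthresholded-denominator
variant). A field whose DNA signal is wholly nuclear raises an explicit
`NoCytoplasmicDNAError` rather than leaking 0/0. The colocalization map is
exactly the numerator support. M1 is invariant under positive rescaling of
the protein channel with its threshold rescaled identically.

## Quadrant polarity

For each cell, a circle of configurable radius (default: the whole
cytoplasm) is centered on the nucleus and split into four 90° sectors, with
sector 1 centered on the nucleus→MET-anchor axis. Sector intervals are
|θ| ≤ 45° (1), (45°, 135°] (2), [−135°, −45°) (4), remainder (3) — closed
boundaries are measure-zero but deterministic. z-slices are pooled. Sector
counts are compared with **paired** t-tests (sector 1 versus each other
sector): the four counts of a cell are jointly constrained (more puncta in
one sector means fewer elsewhere), and an unpaired two-sample test is
measurably anticonservative under this dependence (≈ 8% empirical type-I
error at nominal 5% in the 9-cell design), while the paired test is
calibrated. A von Mises helper supplies the analytic sector-1 mass for
validation.

## Death kinetics

Frames are counted independently — no tracking — with a nucleus-scale
minimum area so cytoplasmic puncta never count as deaths. Fractions are
normalized to the nucleus count of the frame-0 Hoechst image only (the DNA
dye is exposed once, at the start). The plateau level is the mean of the
trailing 4 points; the onset is the earliest time after which the curve
stays within a tolerance band (default ± 0.02) of that level, and a curve
that never settles raises an explicit error.

## Statistics

Two groups: classical equal-variance Student t (two-tailed); Welch behind a
flag. Three or more: one-way ANOVA with Tukey HSD adjusted pairwise
p-values. Degenerate identical-group inputs return t = 0 / F = 0 with
p = 1 deterministically instead of NaN. Stars map to thresholds 0.05, 0.01,
0.001, 0.0001. Normality screening uses normal QQ pairs at plotting
positions (i − 0.5)/n with their correlation coefficient; the plotting
position is a package choice among the standard conventions.

## Synthetic fields

The generator is first-class, tested code, and defines the validation
conditions. Cells are disk nuclei (radius 6 ± 1 px at the default
low-magnification scale) with annular cytoplasm (2× the nuclear radius),
placed by random sequential adsorption with a spacing that keeps
neighbouring cells' MET blobs from merging even after 3 dilations; 20% of
cells are pyroptotic (whole nucleus SYTOX-positive), 2% apoptotic
(nuclear area × 0.4, intensity × 2.0), 16% MET-positive (ellipse blob,
4 × 2.5 px semi-axes, tangent to the cell edge at a uniform-random anchor).
The forward model is ideal intensities → Gaussian PSF (σ = 1 px) → Poisson
shot noise → Gaussian read noise (σ = 2, clipped at 0), in that order.
Identical (config, seed) pairs are bit-identical.

Two canonical regimes mirror the two imaging modes of such experiments:
the class defaults emulate the stitched low-magnification overview
(hundreds to thousands of cells; puncta are below the resolution limit and
not rendered), and `SimConfig.high_res()` emulates 63× per-cell imaging
(nuclear radius 12 px, cytoplasm ratio 2.4, ~5 puncta per MET-positive
cell). Punctum counts per cell are negative-binomial — the field provides
no established distribution, so mean and dispersion are exposed without a
fidelity claim. Punctum angles are von Mises around the nucleus→anchor
direction (κ = 4 by default; κ = 0 is uniform — the polarization seen in
real cells is reproduced phenomenologically, not mechanistically). All
puncta carry Hoechst (they are nuclear DNA); SYTOX, MPO and CitH3 switch on
at stages 2, 3 and 4, so staging is strictly nested before noise. Puncta
are placed in the cytoplasmic annulus with ≥ 3 px clearance from the
nucleus and ≥ 2r + 3 px from each other; a punctum that cannot be placed
within 50 tries is dropped, so the truth always matches what is rendered.
Time-lapse death times are logistic (midpoint 5 h, scale 1 h by default),
truncated to the recording window by inverse-CDF sampling, for a fraction
of doomed cells that sets the plateau; the default recording is 16 h at
15-minute intervals (65 frames), Hoechst rendered at frame 0 only.

What the generator does **not** emulate — and what passing tests therefore
do not demonstrate about real data: irregular cell and nuclear morphology,
overlapping or motile cells, uneven illumination and autofluorescence,
photobleaching, chromatic misregistration, out-of-focus light beyond a
single Gaussian PSF, and biological correlation structure between fates and
staining beyond the configured fractions. Recovery results here bound the
algorithmic error of the pipeline, not the biological error of a real
experiment.

## Problem sizes

Validation runs use 200-cell fields for counting (10 seeds, noiseless and
noisy), 500 cells for MET and death-curve recovery, 1000 nuclei for gating,
~80-cell high-resolution fields (≥ 400 puncta) for classification, 1000
Monte-Carlo replicates for polarity calibration and 10 000 for t-test
calibration — sizes chosen so the full validation completes in minutes on a
single CPU while keeping binomial error well inside the asserted
tolerances. Larger fields (up to the ~2000-cell stitched-mosaic scale) are
supported by configuration.

## Known limitations

* Punctum–cell assignment is by centroid containment; a punctum straddling
  a cell boundary is attributed wholly to one cell.
* MET blobs are not attributed to individual source cells; the percent is a
  field-level quantity.
* The watershed h-parameter trades under- against over-splitting; heavily
  clumped nuclei beyond pairwise contact are not guaranteed to split
  exactly.
* The condensation gate's relative factors (0.7, 1.4) are package defaults,
  adequate for the simulated contrast (area × 0.4, MFI × 2) but requiring
  per-assay review on real data.
* Death counting without tracking assumes dead cells neither move nor
  fragment; drift is only absorbed by the area filter.
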