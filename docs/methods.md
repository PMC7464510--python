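# Methods

`casakit` implements three analysis pipelines for computer-assisted sperm
analysis (CASA) over microscopy stills and videos, a shared particle-detection
stage, and a ground-truthed synthetic-data generator used to validate all of
them. This note records the models, the parameters that matter, the numerical
choices, and what the synthetic validation does and does not establish.

## Particle detection (`casakit.imaging`)

All pipelines reduce a field image to a set of cell centroids and areas:

1. **Grayscale conversion** of RGB input by BT.601 luminance
   (0.299 R + 0.587 G + 0.114 B), rounded to 8-bit.
2. **Global histogram equalization** (256 bins, classic CDF remapping
   `round((cdf − cdf_min)/(N − cdf_min)·255)`). Constant images pass through.
   Equalization is per-pipeline configurable: on by default for accumulation
   and concentration, off for fluorescence classification because it would
   distort hue.
3. **Otsu binarization** by exhaustive scan of all 256 candidate levels,
   maximizing between-class variance; among ties the lowest level wins, and
   foreground is `value > level` (bright cells) or `value ≤ level`
   (dark-on-bright, e.g. negative phase contrast — polarity is an explicit
   flag). A constant image yields an empty mask plus `ConstantImageWarning`.
4. **Connected components** (8-connected by default; 4 configurable) with
   continuous centroids (mean of member pixel coordinates, 0-based,
   pixel-center convention) and **size filtering in µm²**
   (`area = pixels × scale²`), so parameter files transfer across
   magnifications. Typical bull-sperm bounds at the default settings are
   10–80 µm².

When more than 5% of foreground area is discarded by the max-size bound,
`HighDensityWarning` is raised: at high densities colliding cells segment as
one over-size aggregate and silently vanish from counts. This failure mode is
intentionally preserved (it is inherent to single-head segmentation) but made
visible.

## Accumulation heat maps (`casakit.accumulation`)

For each pixel, the count of cell centroids within Euclidean distance ≤ R of
the pixel center is computed (equivalent to stamping each centroid's disk of
influence). Near the borders part of the R-disk lies outside the image, so the
raw count is divided by the **in-bounds area fraction** of the disk —
rasterized on the same integer grid used for counting, so interior fractions
are exactly 1 and the corrected value is an unbiased density estimate
everywhere. Corrected maps are linearly rescaled to 0–255
(`(x − x_min)·255/(x_max − x_min)`, rounded half-up; a constant map maps to
all zeros since the rescale is undefined) and rendered through a fixed
256-entry Jet look-up table built once from the classic piecewise-linear
channel ramps, so rendering is bit-exact across platforms.

Video acceleration follows the original design: full maps at frames
0, f, 2f, … (plus the final frame), per-pixel **linear interpolation** in
between; with a pixel window W (odd), counts are evaluated only at each W×W
block's center pixel and the block painted with that value. Scaling is
per-frame by default; `global_scale` normalizes across the whole video for
comparable colors.

ROI monitoring counts centroids at distance ≤ r, ≤ 2r, ≤ 3r from a circle
center (boundary particles count as inside; radius also reported in µm).
Relative values use **that frame's** total detected particles as denominator
(the field total changes over a recording); zero-particle frames report the
percentage as missing rather than 0.

## Functionality classification (`casakit.functionality`)

Triple staining (membrane-impermeant red nuclear dye, membrane-permeant blue
nuclear dye, green esterase substrate) produces five patterns mapping to
plasma-membrane × acrosome status. Pixels are classified by HSV hue on a
0–255 scale — red iff H > 200 or H < 20, green iff 50 < H < 125, blue iff
130 < H < 185, strict inequalities, all bounds configurable; the scale is the
0–255 hue convention of the original host platform (the printed bounds exceed
0–179 and 0–100 conventions). Pixels that are dark (V < 30) or desaturated
(S < 30) have unreliable hue and are left unclassified, as are those outside
every band. Per cell, red/green/blue ratios divide the band counts by the
cell's **total** pixel count, so ratios sum to ≤ 1.

The decision tree (thresholds configurable):

1. `green ≥ τ_ifi` (default 0.75) → **IFI** (whole cell green).
2. Otherwise acrosome intact iff `green ≥ τ_acr` (default 0.10; a green
   apical cap covers well above 10% of the segmented head).
3. Membrane status by majority nuclear stain: damaged iff red > blue, intact
   iff blue > red → IADM/DADM/IAIM/DAIM.
4. An exact red = blue tie (including the all-zero case) leaves membrane
   status undetermined → UNCLASSIFIED. The tie case is measure-zero for real
   imagery; mapping it to UNCLASSIFIED keeps the tree total and deterministic.

The internal thresholds are design choices constrained only by the verbal
pattern descriptions (pure-pattern cells must map to their named classes —
the tested contract); they are not claimed to match any other implementation
bit-for-bit. Summaries report per-subtype counts/percentages plus
acrosome-intact % (IAIM + IADM) and membrane-intact % (IAIM + DAIM + IFI by
default; IFI cells retain the esterase substrate and are excluded via a flag).
Segmentation for this pipeline runs on the HSV value channel (max of R, G, B)
with equalization off.

## Concentration (`casakit.concentration`)

A fixed-depth counting chamber images a slab of known volume: imaged field
area (image dimensions × µm/px, or an explicit override for grid-based
conventions) × chamber depth. Concentration in millions of cells per mL is
`n · dilution · 10⁶ / V[µm³]` (1 mL = 10¹² µm³). The dilution factor is
applied multiplicatively after counting. Particles with in-bounds centroids
are counted — a deterministic stand-in for manual two-edge hemocytometer
rules; it over- and under-counts border cells symmetrically. Multi-field runs
report mean ± sample SD (n−1).

## Synthetic data (`casakit.synth`)

The generators state a world in which every pipeline's answer is known:

* **Still fields**: bright elliptical heads (default 9 × 4.5 µm ≈ 32 µm²,
  bull-like, at 1 µm/px; intensity 220 on background 10, optional Gaussian
  noise) placed by rejection sampling at centers ≥ one head length + 4 px
  apart and fully in-bounds. Cells are filled ellipses with Gaussian edge
  softening (σ = 1 px) for stable Otsu segmentation. The 4 px slack is the
  measured blur-bridging limit: below it, two thresholded heads can merge
  into one component (merge rate 22/40 at 11 px separation, 0/40 at ≥ 13 px).
* **Motion videos**: per frame, each cell takes a Rayleigh-distributed step
  (scale 2.5 px/frame); with probability κ the direction is the exact bearing
  to the attractant (clamped to never overshoot), otherwise uniform. κ = 0 is
  the unbiased control. Cells reflect at the boundary margin and are
  **sterically excluded** (pairwise relaxation to the same minimum
  separation): without exclusion, every cell collapses onto the attractant
  point by ~100 frames, merges into one over-size blob and disappears from
  detection entirely — a physically impossible state (sperm heads cannot
  overlap) that would make the assay read-out undefined. With exclusion the
  case arm forms a dense but resolvable cluster, reproducing the intended
  "accumulation in the vicinity of the stimulus".
* **Stained fields**: heads rendered in mid-band hues (red 235, green 87,
  blue 157 on the 0–255 scale — strictly inside the classifier's bands);
  IAIM/IADM get a green apical cap (head pixels beyond 0.25·a along the major
  axis, ≈ 30% of head area — between τ_acr and τ_ifi), IFI a thin green tail
  attached to the head. Subtype counts follow the requested proportions
  exactly (largest-remainder apportionment). Optional per-pixel hue jitter
  (wrapped Gaussian, SD in hue units) models chromatic noise.

All generators are deterministic given their seed.
`FieldSpec.recommended_detection()` supplies size bounds of (0.5×, 4×) the
nominal head area: equalization plus edge softening makes a head segment at
72–84 px² rather than the nominal 32, while merged pairs exceed 4×. Matching
the size filter to the imaged cells is exactly what a practitioner does per
species and magnification.

**What a green test establishes** — the analysis chain (detection geometry,
edge correction, hue classification, tree logic, chamber arithmetic) is
correct on data whose truth is known. **What it does not** — robustness to
real-microscopy effects the generators omit: point-spread functions,
phase-contrast halos, debris and background gradients, flagellar motion blur,
overlapping cells, staining heterogeneity. Real recordings remain the only
test of those.

## Validation statistics

`agreement_stats` returns Pearson or Spearman correlation (scipy) plus the
Bland–Altman bias `mean(x − y)`; constant series make the correlation
undefined (NaN). The case/control chemotaxis check runs 10 independent seed
pairs of 200-cell, 150-frame videos (κ = 0.5 vs 0) end-to-end and requires
the case arm's final relative ROI count to beat the control's in ≥ 9/10
pairs. "No trend in controls" is tested **across replicates** (Wilcoxon
signed-rank on final − first per seed): the per-frame ROI occupancy series is
strongly autocorrelated (cells take ~100 frames to cross the ROI), so a
per-series rank test against frame index is miscalibrated — on unbiased
controls it flags "significant" trends of both signs in about half the runs.
A per-series Spearman test is still applied to an every-30th-frame thinning
(approximately the decorrelation time).

## Numerical choices and degenerate inputs

* Rounding for display scaling is half-up (`floor(x + 0.5)`).
* Otsu ties break to the lowest level; foreground is strictly above it.
* Disk membership is `≤ R` on pixel-center distances everywhere (counting,
  boundary fractions, ROI circles), so the same rasterization underlies
  counts and corrections.
* Constant images: equalization is identity; binarization warns and returns
  an empty mask.
* Empty particle sets: zero count matrices, empty CSV tables, ROI
  percentages missing (NaN).
* The boundary-fraction map is computed by FFT convolution of an all-ones
  image with the disk kernel and rounded back to exact integer counts.
* Hue of achromatic pixels (S = 0) is undefined → unclassified.

## Known limitations

* No trajectory linking: counts are per-frame positions; directionality or
  path-based chemotaxis statistics are out of scope.
* High-density aggregation depresses counts (warned, not corrected).
* AVI decoding requires an ffmpeg-backed imageio; the portable path is a
  directory of numbered PNG/TIFF frames, and heat-map videos are written the
  same way.
* The decision-tree thresholds are declared defaults; against real stained
  imagery they may need tuning via `TreeParams`.
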