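# casakit

Open, scriptable computer-assisted sperm analysis (CASA): chemotactic
accumulation heat maps, fluorescence-based sperm functionality
classification, and counting-chamber concentration estimation — for
reproductive-biology labs that need automated, auditable sperm-quality
measurements without a commercial CASA system.

## What it computes

**Accumulation heat maps** (`casakit.accumulation`). From a video of a sperm
field, every pixel receives the number of detected cell centroids within a
search radius R. Border counts are corrected by the in-bounds fraction of the
R-disk, then linearly rescaled,

    scaled(x) = (x − x_min) · 255 / (x_max − x_min),

and rendered through a 256-entry Jet look-up table (cold = sparse,
warm = dense). A circular region of interest (ROI) around an attractant
source — plus concentric circles at 2r and 3r — is counted per frame,
absolute and relative to that frame's detected total, to quantify chemotactic
accumulation over time. Sampling factor *f* (compute every *f*-th frame,
interpolate between) and pixel window *W* (count at W×W block centers)
accelerate long videos.

**Functionality classification** (`casakit.functionality`). Cells from
triple-stained fluorescence fields (red = membrane-damaged nuclei,
blue = intact-membrane nuclei, green = esterase activity / acrosome) are
classified by HSV hue bands (0–255 scale: red H > 200 or H < 20, green
50 < H < 125, blue 130 < H < 185) into per-cell color ratios and then, via a
decision tree, into five subpopulations: IAIM, IADM, DAIM, DADM (intact or
damaged acrosome × membrane) and IFI (whole cell green). Image summaries
report subtype percentages and acrosome-/membrane-integrity rates.

**Concentration** (`casakit.concentration`). Counts in a known chamber
volume (imaged field area × depth) convert to millions of cells per mL:
`C = n · dilution · 10⁶ / V[µm³]`, with multi-field mean ± SD.

All three share one detection stage (`casakit.imaging`): grayscale →
histogram equalization → Otsu thresholding → connected components with size
filtering in µm². `casakit.synth` generates ground-truthed synthetic fields,
drift-vs-control motion videos and stained fields to validate every pipeline,
plus Pearson/Spearman + Bland–Altman agreement statistics. See
`docs/methods.md` for models, parameters and limitations.

## Worked example

```python
from casakit import (
    ChamberGeometry, DetectionParams, FieldSpec, StainSpec,
    classify_field, compute_concentration, count_field,
    make_field, make_stained_field,
)

# a synthetic 448×448 field (1 µm/px) with 60 planted bull-like sperm heads
spec = FieldSpec(width=448, height=448, n_cells=60, seed=1)
frame, truth = make_field(spec)
n = count_field(frame, spec.recommended_detection())
conc = compute_concentration(n, ChamberGeometry.from_frame(frame, depth_um=10.0))
print(n, f"{conc.concentration_mcells_per_ml:.2f} M/mL")

# a stained field with a known subtype mix, classified end-to-end
sframe, struth = make_stained_field(
    StainSpec(n_cells=80, proportions=(0.35, 0.2, 0.05, 0.2, 0.2), seed=2)
)
det = DetectionParams(min_area_um2=10, max_area_um2=200, equalize=False)
cells, summary = classify_field(sframe, det)
print(summary.total, f"{summary.pct_acrosome_intact:.1f}%",
      f"{summary.pct_membrane_intact:.1f}%")
```

prints

    60 29.89 M/mL
    80 55.0% 60.0%

60 of 60 planted cells are counted; in a 448 × 448 × 10 µm volume
(≈ 2.0 × 10⁻⁶ mL) that is 29.89 million cells per mL. All 80 stained cells
are detected; with the planted mix, acrosome-intact (IAIM + IADM) is
0.35 + 0.2 = 55.0% and membrane-intact (IAIM + DAIM + IFI) is
0.35 + 0.05 + 0.2 = 60.0% — the classifier recovers the planted truth
exactly.

The same pipelines run from the shell:

    casakit synth stained --spec spec.json --seed 5 --out demo/
    casakit classify --input demo/stained.png --scale 1.0 \
        --min-area 10 --max-area 200 --out results/
    casakit accumulate --input frames_dir/ --scale 0.55 --radius-um 50 \
        --sampling 5 --roi 400,300,80 --out results/

Every run writes its resolved configuration and a log next to its outputs.
Videos are read from AVI (when an ffmpeg backend is present) or, portably,
from a directory of numbered PNG/TIFF frames.

## Acceptance script

`scripts/acceptance.py` re-runs all three pipelines end-to-end on synthetic
data — planted-field concentration, stained-field classification with
agreement statistics against the planted truth, and an attractant-drift video
versus an unbiased control through detection, heat maps and ROI time
series — and writes its results JSON:

    python scripts/acceptance.py --seed 1 --out results/acceptance.json
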