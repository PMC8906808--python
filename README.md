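# somitoscreen

Quantitative image analysis for **somite-forming paraxial mesoderm
organoids** ("somitoids"): human iPSC-derived 3D aggregates that, under the
right culture conditions, form somite-like structures — epithelial rosettes
of PAX3⁺ columnar cells arranged radially around an N-cadherin/F-actin-rich
central cavity.  The package is written for groups running image-based
organoid screens who need per-organoid, per-condition numbers rather than
representative pictures: which treatment regime forms the most somite-like
structures, how reproducibly, and how the structures compare in size to
embryonic somites.

## What it computes

Given multi-channel confocal z-stacks (nuclear stain, fate marker such as
PAX3, structural marker such as NCAD/F-ACTIN):

1. **Segmentation** (`somitoscreen.segment`) — per z-slice: Gaussian blur
   (σ = 5 px) → Li minimum cross-entropy threshold → rounds of
   erosion/dilation with a 3×3 cross, largest connected component, hole
   fill.  The organoid diameter is the equivalent-disk diameter
   2·√(A_max/π) of the largest-area slice ROI, in µm.
2. **Marker quantification** (`somitoscreen.intensity`) — both channels
   blurred at σ = 10 px, divided pixel-wise; pixels with near-zero nuclear
   signal are excluded as undefined.  The organoid's normalized marker
   intensity is the mean of per-slice means inside the mask.
3. **Rosette counting** (`somitoscreen.rosettes`) — Laplacian-of-Gaussian
   blob detection on the structural channel proposes candidate foci; each
   is scored on three criteria, all required for a count: a
   marker-positive ring (mean normalized marker ratio in the shell annulus
   > 1), a central cavity (lumen nuclear signal < 0.5 × shell signal under
   a bright structural focus), and radial arrangement (circular variance
   of nuclear gradient orientations relative to the focus direction
   < 0.55).  Two in-slice diameters d₁, d₂ give the structure's area as
   the rectangle d₁ × d₂.
4. **Screen statistics** (`somitoscreen.screen`) — per-condition means,
   SDs and coefficients of variation (CV% = 100·s/x̄, sample SD), condition
   ranking by mean rosette count; box-plot statistics (median, quartiles
   by linear interpolation, whiskers) for structure sizes; qPCR analysis
   by the ΔΔCt method (ΔCt against a housekeeping gene, ΔΔCt against a
   reference sample, fold change 2^−ΔΔCt, per-gene Z-scores of log₂ fold
   changes).
5. **scRNA-seq QC** (`somitoscreen.qc`) — droplet filters (UMIs < 500,
   genes < 200, mitochondrial fraction > 0.2, complexity
   log₁₀(genes)/log₁₀(UMIs) < 0.8, exclusion conditions strict) and
   cluster marker genes by two-sided Wilcoxon rank-sum with Bonferroni
   correction (marker ⇔ log₂FC ≥ 0.25 and adjusted p < 0.05).

A first-class synthetic-data generator (`somitoscreen.simulate`) renders
organoid stacks with planted rosettes, screen plates, UMI count matrices
with planted low-quality cells and marker genes, and Ct tables with known
fold changes — every downstream stage is tested against this ground truth.

## Worked example

```python
from somitoscreen import (SyntheticOrganoidSpec, RosetteTruth, model_for_radius,
                          tissue_cell_count, generate_organoid_stack,
                          segment_organoid, organoid_diameter, count_rosettes,
                          normalized_marker_image, mean_normalized_intensity)
from somitoscreen.simulate import _place_rosette_centers
import numpy as np

radius = 55.0                               # µm
model = model_for_radius(radius)            # FOV framed to the organoid
rng = np.random.default_rng(0)
centers = _place_rosette_centers(5, model.physical_extent / 2, radius, 12.0, rng)
spec = SyntheticOrganoidSpec(
    radius=radius, n_cells=tissue_cell_count(radius),
    rosettes=tuple(RosetteTruth(center=tuple(c)) for c in centers),
    marker_pos_fraction=0.8, rng_seed=0,
)
stack, truth = generate_organoid_stack(spec, model)   # noisy 3-channel stack

mask, roi = segment_organoid(stack)
ratio, eps = normalized_marker_image(stack.channel("marker"),
                                     stack.channel("nuclear"))
intensity = mean_normalized_intensity(ratio, roi, epsilon=eps)
count, calls = count_rosettes(stack, roi)
print(f"diameter      {organoid_diameter(roi):6.1f} µm   (truth {truth.diameter:.1f})")
print(f"marker mean   {intensity.organoid_mean:6.2f}")
print(f"rosettes      {count:6d}      (planted {truth.n_rosettes})")
```

prints

```
diameter       102.6 µm   (truth 110.0)
marker mean     1.36
rosettes           5      (planted 5)
```

All five planted rosettes are detected and pass all three scoring
criteria, and the normalized marker mean reflects the 80% marker-positive
composition (organoid means run from ~0.1 for fully negative to ~1.7 for
fully positive tissue).  The diameter reads ~7% low here: bright internal
rosette rings raise the Li threshold and shave the mask edge — a known
property of intensity-dependent thresholding discussed in
`docs/methods.md` (rosette-free organoids recover their diameter to
within ±5%; see `scripts/acceptance.py`).

The same stages are available from a CLI (`somitoscreen simulate | segment
| quantify | score | screen | qpcr | qc | run`); `somitoscreen run`
executes the whole synthetic screen from a YAML config and writes a
manifest with the resolved configuration and its hash, so a run is
reproducible byte-for-byte from (config, seed).

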