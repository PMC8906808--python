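# Methods

This note records the models, conventions and numerical choices behind
`somitoscreen`, the parameters that matter and their defaults, what the
synthetic generator does and does not emulate, and known limitations.

## The measurement problem

Somite-forming paraxial mesoderm organoids are scored on three kinds of
readout: geometry (organoid diameter), fate (average nuclear marker such
as PAX3, normalized to the nuclear stain), and morphogenesis (the number
and size of somite-like structures — epithelial rosettes of marker-positive
columnar cells around an N-cadherin/F-actin-rich central cavity).  The
package turns each readout into a deterministic computation on a
calibrated multi-channel z-stack, then aggregates organoids into
screen-level statistics.

## Segmentation

Per z-slice, on the nuclear channel: Gaussian blur (σ = 5 px) → Li minimum
cross-entropy threshold → `rounds` erosions then dilations (morphological
opening) with a 3×3 cross structuring element → largest 4-connected
component → hole fill.  All processing is strictly 2D per slice; no 3D
connectivity is attempted.  Defaults: `rounds = 3` ("several rounds" is
otherwise unspecified), hole filling on (so ROI areas are well defined for
cavity-bearing organoids); both are recorded in the mask provenance.

**Li threshold.** Computed on a 256-bin histogram over the slice's
[min, max] range; bin centers are shifted positive before taking logs.
The Li–Tam fixed-point iteration `t ← (µ_fg − µ_bg)/(ln µ_fg − ln µ_bg)`
runs from the mean gray to a tolerance of half a bin, with an exhaustive
scan fallback on non-convergence.  Two refinements matter in practice:

* the returned threshold is *canonicalised* to the lowest occupied gray of
  the foreground class.  The cross-entropy objective is constant while the
  threshold moves through empty bins (the partition does not change), so
  without canonicalisation two equally-optimal thresholds can differ by
  the width of the histogram gap;
* the converged fixed point is *polished by discrete descent* on the
  histogram objective.  The fixed point solves the continuous relaxation
  and can sit 1–3 bins away from the discrete argmin on skewed unimodal
  histograms; descent walks to the local minimum of the objective that is
  actually being optimised.  Foreground is `image >= threshold`.

**Signal-free slices.** A slice is rejected when its above-threshold class
mean is less than 1.5× the below-threshold mean.  Li always returns *some*
split, and on a blurred noise-only slice that split separates nothing but
noise texture (class-mean ratio ≈ 1.01); real tissue-vs-background splits
run well above 2.  This guard is what makes a blank stack fail loudly
instead of producing a garbage mask.

**Field of view.**  Li thresholding implicitly assumes the histogram has a
meaningful class balance.  When an organoid occupies a small percent of a
large empty field, the background-dominated histogram drags the threshold
down and the mask overshoots by 2–3 µm per side — which is 7% of the
diameter for a 60 µm organoid.  `model_for_radius` therefore frames the
synthetic field at 1.3× the organoid diameter, as a microscopist frames a
single-organoid well; with that framing, recovered diameters stay within
±3% over radii 30–80 µm at default noise.

**Diameter.** The equivalent-disk diameter `2·√(A_max/π)` of the
largest-area slice.  The underlying convention (Feret vs equivalent-disk,
which slice) is not fixed by any imaging standard; equivalent-disk on the
largest slice is robust to boundary roughness.  Known limitation: bright
internal structures (dense rosette rings) raise the slice's Li threshold
and shave the mask boundary, reading a few percent low on
structure-dense organoids.  This is an inherent property of
intensity-dependent thresholding, shared by the macro-style pipeline the
module reproduces.

## Normalized marker intensity

Marker and nuclear channels are each blurred per slice at σ = 10 px, then
divided pixel-wise.  Pixels whose blurred nuclear signal falls below
ε = 1% of the nuclear channel's 99th-percentile intensity are flagged
undefined and excluded from every mean (rationale: the ratio is unbounded
and meaningless outside nuclei-bearing tissue; exclusion, unlike clipping,
does not bias the mean).  The per-organoid value is the unweighted mean of
per-slice means over slices with at least one defined ROI pixel; an
area-weighted variant would up-weight equatorial slices and is trivially
derivable from the per-slice means in the result object.

The ratio is invariant to joint rescaling of both channels and linear in
marker-only rescaling (with ε held fixed), which is what makes organoid
means comparable across acquisition gain settings.

## Rosette detection and scoring

Candidate foci come from scale-normalised Laplacian-of-Gaussian filtering
of the background-subtracted structural channel (background = channel
median; most voxels lie outside the organoid).  Scales are lumen radii
r ∈ [5, 25] µm (6 geometric steps), each filtered with σ = r/√3
anisotropically in voxel units.  Local maxima above an absolute response
threshold (2000 intensity units in 16-bit data) become candidates; greedy
non-maximum suppression keeps the strongest of any pair closer than the
larger of their lumen scales.  The threshold is absolute rather than
max-relative because a zero-rosette organoid has no bright reference: its
brightest structure is the diffuse boundary step, and normalising by it
would amplify boundary responses into false candidates.

Each candidate is scored on the focus's best slice ±1 (statistics
averaged across the three slices), with the lumen disc at radius r and
the shell annulus from r to 2.4·r:

* **marker-positive ring** — mean defined normalized marker ratio in the
  annulus > 1.0.  On the generator, marker-positive rings measure
  1.6–1.9 and marker-negative rings 0.2–0.5, so the threshold sits in a
  wide margin;
* **central cavity** — mean smoothed nuclear signal in the lumen
  < 0.5 × the annulus mean, plus the structural response already required
  at detection.  Intact cavities measure 0.27–0.38; cavity-ablated
  (filled) structures 0.8–1.2;
* **radial arrangement** — circular variance of nuclear gradient
  orientations in the annulus, measured against the direction to the
  focus with angles doubled (inward and outward gradients both count as
  radial), weighted by gradient magnitude, < 0.55.  Intact rosettes
  measure ≤ ~0.40 (the 2 µm z-grid samples the 3D shell coarsely, which
  lifts the variance above the ideal-ring value of ≈ 0), shells with
  scattered (non-radial) nuclei ≥ ~0.66, and unstructured tissue ≈ 0.9.
  The 0.55 default is placed in the gap; all three thresholds were
  calibrated once on the generator and are exposed in the config.

A structure is counted only when all three flags hold.  Its two diameters
d₁, d₂ are measured in-slice along ±x and ±y as the distance between
opposing nuclear-ring intensity peaks, and its area is the rectangle
d₁ × d₂.  The diameters therefore span the nuclear ring (mid-shell), not
the outer shell edge.

On the generator at default noise, the detector achieves precision and
recall ≥ 0.97 over stacks carrying 3–12 rosettes, and exact counts on
noise-free stacks.  Counts on real images are comparable to manual
scoring in rank and ballpark only: the three criteria formalise a manual
protocol that was never given quantitative thresholds.

## Screen statistics

* CV = 100 × sample SD (n − 1 denominator) / mean; undefined for n < 2 or
  zero mean.  Whether a population SD was ever intended is unknowable
  from a single printed percentage; the sample convention is stated here
  once and used everywhere.
* Condition ranking: by mean rosette count, ties broken by lower
  rosette-count CV (reproducibility as the tie-breaker is the point of
  the screen).
* Size statistics: median and quartiles by linear interpolation between
  order statistics (the convention matters — IQR endpoints move by tens
  of µm² under the nearest-rank convention at n ≈ 20); whiskers are
  min/max.
* ΔΔCt: technical replicates averaged per gene×sample; ΔCt against the
  housekeeping gene (default PP1A); ΔΔCt against the reference sample
  (default undifferentiated iPSC); fold change 2^−ΔΔCt.  Z-scores are
  computed per gene across samples on log₂ fold changes — symmetric
  treatment of up- and down-regulation; Z-scores on raw fold changes
  would let a single strong induction dominate the scale.

## scRNA-seq QC and markers

The four droplet filters are exclusion conditions ("less than", "above"),
so boundary cells — exactly 500 UMIs, exactly 0.2 mitochondrial fraction,
complexity exactly 0.8 — are retained.  Complexity
log₁₀(genes)/log₁₀(UMIs) is undefined at ≤ 1 UMI; such cells fail the
complexity criterion.  Mitochondrial genes are named by the `MT-` prefix
or an explicit list.

Marker testing uses a two-sided Wilcoxon rank-sum per gene per cluster
(cluster vs all other cells): exact enumeration of all C(n+m, n) rank
assignments when both groups have ≤ 8 cells (valid under ties), otherwise
the tie-corrected normal approximation without continuity correction.
Expression is depth-normalised (counts per 10k, log1p) before testing —
the test is rank-based, so this choice affects only the fold-change
estimate, computed as log₂ of the ratio of de-logged group means with a
pseudocount of 1.  Bonferroni correction is per cluster over the genes
tested in that comparison (genes expressed in at least one cell), stated
explicitly because the family size is otherwise ambiguous.  A gene is a
marker when log₂FC ≥ 0.25 and adjusted p < 0.05.

## The synthetic generator

The generator renders what the pipeline assumes and nothing more:

* **Organoid**: a ball of radius r; nuclei as isotropic 3D Gaussians
  (σ = nucleus_radius/2, default 2 µm) at uniform positions, count
  derived from volume at 1.5×10⁻³ nuclei/µm³ (≈ 9 µm spacing) unless
  given; a dim cytoplasmic haze (100 units) fills the tissue ball.
  Marker-positive nuclei appear in the marker channel at 2× the nuclear
  amplitude, so blurred marker/nuclear ratios exceed 1 on positive
  tissue.
* **Rosette**: a nucleus- and haze-free lumen ball (default radius 6 µm)
  inside an exclusive shell (12 µm) whose mid-sphere is tiled by ring
  nuclei on a jittered Fibonacci lattice (40 cells — columnar epithelia
  pack evenly; Poisson placement leaves gaps that no real epithelium
  has); a bright structural focus (Gaussian, σ = lumen_radius/2) at the
  lumen center.  Shells keep a 30% standoff below the organoid surface
  and interior nuclei stay out of them entirely.  Ablation switches
  (`marker_positive`, `has_lumen`, `ring_on_sphere`) each defeat exactly
  one scoring criterion, which is how criterion-necessity is tested.
* **Imaging**: 2 µm z-step, 0.65 µm/px XY (a configuration default — the
  acquisition pixel size is not pinned by any metadata this package
  consumes), isotropic PSF blur σ = 0.8 µm, background 100, Poisson
  photon noise, Gaussian read noise σ = 5, 16-bit clipping.
* **Screen plate**: per-condition organoid radius, marker fraction and
  rosette-count distribution; per-organoid seeds are `seed + index`.  The
  optimal-protocol condition draws counts from a rounded normal
  (mean 9, sd 1, clipped at 0): a reproducible, regulated condition is
  sub-Poisson by definition — Poisson(9) would force a 33% CV and
  misrepresent what "reproducible" means.  Unoptimised conditions stay
  Poisson.
* **Count matrix**: lognormal gene weights; per-cell multinomial draws;
  planted classes built to trip exactly one QC filter each (low-UMI
  50–400 total; high-mito fraction drawn in [0.3, 0.6]; low-complexity
  cells concentrate normal depth on a 250-gene support, keeping the gene
  count above 200 so only complexity trips); cluster markers at 8× weight
  in their cluster.
* **Ct tables**: Ct = base + per-sample loading offset − log₂(fold
  change) + noise, in triplicate; the housekeeping gene carries the
  loading offset only, so ΔΔCt recovers the planted fold changes exactly
  at zero noise.

What it does **not** emulate: depth-dependent attenuation, spectral
bleed-through, nucleus shape and instance boundaries, segmentation-clock
dynamics, ambient RNA, doublets, batch effects.  Passing tests therefore
demonstrate that the pipeline recovers planted truth under the stated
image-formation model — not that it is robust to every artifact of real
microscopy or droplet chemistry.

## Problem sizes

Tests and the acceptance script run the imaging stages at organoid radii
30–80 µm with fields framed per organoid (up to ~84×320×320 voxels),
20-stack batches for detector fidelity, 12-organoid batches in the
acceptance script, a 2-condition × 5-replicate plate, 550-cell × 2000-gene
count matrices, and 5-gene × 3-sample Ct tables — sizes chosen so the full
suite completes on a single CPU in minutes while every statistic keeps a
meaningful n.

## Known limitations

* Per-slice 2D processing means no 3D surface regularisation; diameters
  inherit slice-level threshold noise.
* The Li threshold is intensity-dependent: unusually bright internal
  structure biases the mask inward (see Segmentation).
* The rosette criteria are a formalisation of a manual scoring protocol;
  absolute counts on real data depend on thresholds that real somitoids
  were never scored with.
* Structure areas use the nuclear-ring diameter convention; comparing to
  areas measured at the outer epithelial boundary requires a scale factor
  of roughly (shell/mid-shell)².
* The marker test's fold-change definition (pseudocount on de-logged
  CP10k means) is one of several in common use; marker *lists* are
  threshold-stable but fold-change *values* are convention-dependent.
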