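"""Organoid mask generation and diameter measurement from the nuclear channel.

The per-slice recipe mirrors a batch-mode ImageJ macro: Gaussian blur
(sigma = 5 px) → Li minimum cross-entropy threshold → several rounds of
erosion/dilation (morphological opening) → largest connected component and
hole filling → per-slice ROI.  All processing is 2D per z-slice; geometric
outputs are converted to µm with the stack calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .stack import ImageStack

#: 3×3 cross (4-connected) structuring element used for erosion/dilation
CROSS_SE = ndi.generate_binary_structure(2, 1)

#: minimum foreground/background class-mean ratio for a slice to count as
#: containing signal; blurred noise-only slices split at ratios near 1
DEFAULT_MIN_CLASS_SEPARATION = 1.5


class SegmentationError(RuntimeError):
    """Raised when no slice of a stack yields a usable organoid mask."""


class DegenerateImageError(ValueError):
    """Raised when an image has a single-valued (constant) histogram."""


def gaussian_denoise(image: np.ndarray, sigma: float) -> np.ndarray:
    """Slice-wise 2D Gaussian blur with reflective boundaries.

    3D inputs are filtered independently per z-slice (the macro operates
    slice by slice); 2D inputs are filtered directly.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return ndi.gaussian_filter(image, sigma=sigma, mode="reflect")
    if image.ndim == 3:
        return np.stack(
            [ndi.gaussian_filter(sl, sigma=sigma, mode="reflect") for sl in image]
        )
    raise ValueError("image must be 2D or 3D")


def _cross_entropy(bin_centers: np.ndarray, hist: np.ndarray, t: float) -> float:
    """Minimum-cross-entropy objective for a candidate threshold.

    With S_k the intensity mass and µ_k the mean gray of the two classes
    split at ``t``, the data-independent part of the cross entropy between
    the image and its two-level reconstruction is
    ``−(S_below·ln µ_below + S_above·ln µ_above)``.  Bin centers must be
    positive (callers shift the histogram).
    """
    below = bin_centers < t
    s0 = float(np.sum(bin_centers[below] * hist[below]))
    s1 = float(np.sum(bin_centers[~below] * hist[~below]))
    n0 = float(hist[below].sum())
    n1 = float(hist[~below].sum())
    total = 0.0
    if n0 > 0 and s0 > 0:
        total -= s0 * math.log(s0 / n0)
    if n1 > 0 and s1 > 0:
        total -= s1 * math.log(s1 / n1)
    return total


def _li_histogram(image: np.ndarray, nbins: int) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Histogram over [min, max], bin centers shifted to positive grays."""
    values = np.asarray(image, dtype=float).ravel()
    lo, hi = float(values.min()), float(values.max())
    if not hi > lo:
        raise DegenerateImageError("constant image: threshold undefined")
    hist, edges = np.histogram(values, bins=nbins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    # shift grays so every bin center is >= one bin width (log needs > 0)
    shift = lo - width
    return centers - shift, hist.astype(float), shift, width


def _li_scan(centers: np.ndarray, hist: np.ndarray) -> float:
    """Exhaustive minimiser of the cross-entropy objective over bin centers."""
    occupied = centers[hist > 0]
    candidates = occupied[1:]  # a split must leave both classes non-empty
    objective = [_cross_entropy(centers, hist, t) for t in candidates]
    return float(candidates[int(np.argmin(objective))])


def li_threshold(image: np.ndarray, nbins: int = 256) -> float:
    """Li minimum cross-entropy threshold of an intensity image.

    Computed on a 256-bin histogram over the image's [min, max] range
    (float inputs are thereby min–max scaled into bins).  The Li–Tam
    fixed-point iteration ``t ← (µ_above − µ_below)/(ln µ_above − ln
    µ_below)`` runs to a tolerance of half a bin width, falling back to an
    exhaustive scan of all candidate bin thresholds on non-convergence.
    The fixed point solves the continuous relaxation and can sit a few
    bins off the discrete argmin on skewed histograms, so the converged
    value is polished by discrete descent on the histogram objective.
    Foreground is ``image >= threshold``.

    The cross-entropy objective is constant wherever the threshold moves
    through empty histogram bins (the induced partition does not change),
    so the returned value is canonicalised to the lowest occupied gray of
    the foreground class — equal-partition thresholds compare equal.

    Raises
    ------
    DegenerateImageError
        If the image is constant.
    """
    centers, hist, shift, width = _li_histogram(image, nbins)
    total_mass = float(np.sum(centers * hist))
    total_n = float(hist.sum())

    t = total_mass / total_n  # start at the mean gray
    converged = False
    for _ in range(100):
        below = centers < t
        n0 = float(hist[below].sum())
        n1 = total_n - n0
        if n0 == 0 or n1 == 0:
            break
        mu0 = float(np.sum(centers[below] * hist[below])) / n0
        mu1 = (total_mass - mu0 * n0) / n1
        if mu1 <= mu0:
            break
        t_new = (mu1 - mu0) / (math.log(mu1) - math.log(mu0))
        if abs(t_new - t) < 0.5 * width:
            t = t_new
            converged = True
            break
        t = t_new
    if not converged or not centers[0] < t <= centers[-1] + width:
        t = _li_scan(centers, hist)

    # canonicalise to an occupied candidate (equal-partition thresholds
    # compare equal), then descend to the local discrete minimum
    occupied = centers[hist > 0]
    candidates = occupied[1:]  # both classes must stay non-empty
    j = int(np.searchsorted(candidates, t))
    j = min(j, len(candidates) - 1)
    obj = {j: _cross_entropy(centers, hist, candidates[j])}

    def objective(k: int) -> float:
        if k not in obj:
            obj[k] = _cross_entropy(centers, hist, candidates[k])
        return obj[k]

    moved = True
    while moved:
        moved = False
        for k in (j - 1, j + 1):
            if 0 <= k < len(candidates) and objective(k) < objective(j):
                j, moved = k, True
                break
    return float(candidates[j] + shift)


@dataclass
class OrganoidMask:
    """Per-slice binary masks plus the provenance of their computation."""

    masks: np.ndarray                      # (z, y, x) bool
    sigma: float
    rounds: int
    thresholds: list[float | None]         # None where slice was rejected
    min_class_separation: float
    hole_filled: bool = True


@dataclass
class OrganoidROI:
    """Largest-component region per slice with calibrated areas."""

    regions: np.ndarray                    # (z, y, x) bool, one CC per slice
    areas_um2: np.ndarray                  # (z,) µm²; 0 where empty
    pixel_size_xy: float
    z_step: float

    @property
    def nonempty_slices(self) -> np.ndarray:
        return np.flatnonzero(self.areas_um2 > 0)

    @property
    def largest_slice(self) -> int:
        if not len(self.nonempty_slices):
            raise SegmentationError("ROI is empty on every slice")
        return int(np.argmax(self.areas_um2))


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndi.label(mask, structure=CROSS_SE)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def refine_mask(mask: np.ndarray, rounds: int) -> np.ndarray:
    """Opening (``rounds`` erosions then dilations, 3×3 cross), largest
    connected component, hole fill — per slice for 3D inputs."""
    if rounds < 0:
        raise ValueError("rounds must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim == 3:
        return np.stack([refine_mask(sl, rounds) for sl in mask])
    if mask.ndim != 2:
        raise ValueError("mask must be 2D or 3D")
    out = mask
    if rounds > 0 and out.any():
        out = ndi.binary_erosion(out, structure=CROSS_SE, iterations=rounds)
        if out.any():
            out = ndi.binary_dilation(out, structure=CROSS_SE, iterations=rounds)
    out = _largest_component(out)
    if out.any():
        out = ndi.binary_fill_holes(out)
    return out


def segment_organoid(
    stack: ImageStack,
    nuclear_channel: str = "nuclear",
    sigma: float = 5.0,
    rounds: int = 3,
    min_class_separation: float = DEFAULT_MIN_CLASS_SEPARATION,
) -> tuple[OrganoidMask, OrganoidROI]:
    """Per-slice denoise → Li threshold → refine → ROI on the nuclear channel.

    A slice is rejected (empty ROI) when its histogram is degenerate or the
    mean intensity of its above-threshold class is less than
    ``min_class_separation`` times the below-threshold class mean — the
    signature of a signal-free slice whose Li split only divides noise.

    Raises
    ------
    SegmentationError
        If every slice is empty after refinement.
    """
    nuclear = stack.channel(nuclear_channel)
    nz = nuclear.shape[0]
    masks = np.zeros(nuclear.shape, dtype=bool)
    regions = np.zeros(nuclear.shape, dtype=bool)
    areas = np.zeros(nz)
    thresholds: list[float | None] = [None] * nz

    for z in range(nz):
        blurred = gaussian_denoise(nuclear[z], sigma)
        try:
            t = li_threshold(blurred)
        except DegenerateImageError:
            continue
        fg = blurred >= t
        if not fg.any() or fg.all():
            continue
        mu_fg = float(blurred[fg].mean())
        mu_bg = float(blurred[~fg].mean())
        if mu_bg > 0 and mu_fg / mu_bg < min_class_separation:
            continue
        thresholds[z] = t
        refined = refine_mask(fg, rounds)
        masks[z] = refined
        regions[z] = refined
        areas[z] = refined.sum() * stack.pixel_size_xy**2

    if not masks.any():
        raise SegmentationError("no slice produced a non-empty organoid mask")

    mask = OrganoidMask(
        masks=masks,
        sigma=sigma,
        rounds=rounds,
        thresholds=thresholds,
        min_class_separation=min_class_separation,
    )
    roi = OrganoidROI(
        regions=regions,
        areas_um2=areas,
        pixel_size_xy=stack.pixel_size_xy,
        z_step=stack.z_step,
    )
    return mask, roi


def organoid_diameter(roi: OrganoidROI) -> float:
    """Equivalent-disk diameter ``2·sqrt(A_max/π)`` of the largest-area
    slice, in µm."""
    z = roi.largest_slice  # raises SegmentationError when empty
    return float(2.0 * math.sqrt(roi.areas_um2[z] / math.pi))
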