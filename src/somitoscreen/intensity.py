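"""Nuclear-normalized marker intensity per organoid.

The marker (e.g. PAX3) and nuclear (Hoechst) channels are each blurred with
a sigma = 10 px Gaussian per slice, then divided pixel-wise.  Pixels whose
blurred nuclear signal falls below an epsilon floor are flagged undefined
(NaN) and excluded from all means — ratios outside nuclei are unbounded and
meaningless.  Per-organoid intensity is the unweighted mean of per-slice
means over slices with at least one defined ROI pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segment import OrganoidROI, gaussian_denoise

DEFAULT_RATIO_SIGMA = 10.0


@dataclass
class NormalizedIntensityResult:
    per_slice_mean: np.ndarray   # (z,) NaN where slice unusable
    organoid_mean: float
    n_slices_used: int
    n_undefined_pixels: int
    sigma: float
    epsilon: float


def default_epsilon(nuclear_blurred: np.ndarray) -> float:
    """Nuclear-signal floor: 1% of the channel's 99th-percentile intensity."""
    return float(0.01 * np.percentile(nuclear_blurred, 99))


def normalized_marker_image(
    marker: np.ndarray,
    nuclear: np.ndarray,
    sigma: float = DEFAULT_RATIO_SIGMA,
    epsilon: float | None = None,
) -> tuple[np.ndarray, float]:
    """Blur both channels per slice, divide marker by nuclear.

    Returns the ratio grid (NaN at undefined pixels, i.e. where the blurred
    nuclear signal is below ``epsilon``) and the epsilon actually used.
    """
    marker = np.asarray(marker, dtype=float)
    nuclear = np.asarray(nuclear, dtype=float)
    if marker.shape != nuclear.shape:
        raise ValueError(
            f"channel shapes differ: {marker.shape} vs {nuclear.shape}"
        )
    marker_b = gaussian_denoise(marker, sigma)
    nuclear_b = gaussian_denoise(nuclear, sigma)
    if epsilon is None:
        epsilon = default_epsilon(nuclear_b)
    defined = nuclear_b >= epsilon
    ratio = np.full(marker.shape, np.nan)
    np.divide(marker_b, nuclear_b, out=ratio, where=defined)
    return ratio, float(epsilon)


def mean_normalized_intensity(
    ratio: np.ndarray,
    roi: OrganoidROI,
    sigma: float = DEFAULT_RATIO_SIGMA,
    epsilon: float = float("nan"),
) -> NormalizedIntensityResult:
    """Mean defined ratio inside the ROI, per slice and per organoid."""
    ratio = np.asarray(ratio, dtype=float)
    if ratio.shape != roi.regions.shape:
        raise ValueError("ratio grid and ROI geometry differ in shape")
    nz = ratio.shape[0]
    per_slice = np.full(nz, np.nan)
    n_undefined = 0
    for z in range(nz):
        sel = roi.regions[z]
        if not sel.any():
            continue
        vals = ratio[z][sel]
        defined = ~np.isnan(vals)
        n_undefined += int((~defined).sum())
        if defined.any():
            per_slice[z] = float(vals[defined].mean())
    used = ~np.isnan(per_slice)
    if not used.any():
        raise ValueError("no defined ratio pixel inside the ROI on any slice")
    return NormalizedIntensityResult(
        per_slice_mean=per_slice,
        organoid_mean=float(per_slice[used].mean()),
        n_slices_used=int(used.sum()),
        n_undefined_pixels=n_undefined,
        sigma=sigma,
        epsilon=epsilon,
    )
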