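"""Segmentation oracles: blur, Li threshold, morphology, diameter."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somitoscreen import (
    DegenerateImageError,
    ImageStack,
    SegmentationError,
    SyntheticOrganoidSpec,
    gaussian_denoise,
    li_threshold,
    organoid_diameter,
    refine_mask,
    segment_organoid,
    tissue_cell_count,
    generate_organoid_stack,
    model_for_radius,
)
from somitoscreen.stack import DEFAULT_CHANNELS


def brute_force_blur(image: np.ndarray, sigma: float) -> np.ndarray:
    """Direct 2D convolution with a truncated discrete Gaussian kernel,
    reflect-padded — independent of scipy's separable filter."""
    radius = int(4 * sigma + 0.5)
    ax = np.arange(-radius, radius + 1)
    k1 = np.exp(-(ax**2) / (2 * sigma**2))
    kernel = np.outer(k1, k1)
    kernel /= kernel.sum()
    padded = np.pad(image, radius, mode="symmetric")
    out = np.empty_like(image, dtype=float)
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            out[i, j] = np.sum(
                padded[i : i + 2 * radius + 1, j : j + 2 * radius + 1] * kernel
            )
    return out


def cross_entropy_objective(image: np.ndarray, nbins: int = 256):
    """Independent exhaustive-scan Li oracle on the image histogram."""
    vals = image.ravel().astype(float)
    hist, edges = np.histogram(vals, bins=nbins, range=(vals.min(), vals.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    g = centers - vals.min() + width  # positive grays
    best_t, best_obj = None, np.inf
    occupied = np.flatnonzero(hist)
    for idx in occupied[1:]:
        t = g[idx]
        lo = g < t
        n0, n1 = hist[lo].sum(), hist[~lo].sum()
        s0 = float((g[lo] * hist[lo]).sum())
        s1 = float((g[~lo] * hist[~lo]).sum())
        obj = 0.0
        if n0:
            obj -= s0 * math.log(s0 / n0)
        if n1:
            obj -= s1 * math.log(s1 / n1)
        if obj < best_obj:
            best_obj, best_t = obj, t
    return best_t + vals.min() - width, width


class TestGaussianDenoise:
    def test_constant_image_unchanged(self):
        img = np.full((32, 32), 7.0)
        assert np.allclose(gaussian_denoise(img, 5.0), img)

    def test_impulse_peak_matches_closed_form(self):
        img = np.zeros((101, 101))
        img[50, 50] = 1.0
        peak = gaussian_denoise(img, 5.0)[50, 50]
        assert peak == pytest.approx(1.0 / (2 * math.pi * 25.0), rel=0.01)

    def test_matches_brute_force_convolution(self):
        rng = np.random.default_rng(5)
        img = rng.random((64, 64))
        ours = gaussian_denoise(img, 2.0)
        oracle = brute_force_blur(img, 2.0)
        assert np.allclose(ours, oracle, atol=1e-6)

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            gaussian_denoise(np.zeros((4, 4)), 0.0)


class TestLiThreshold:
    def test_two_population_image_separates_exactly(self):
        rng = np.random.default_rng(0)
        img = np.where(rng.random((64, 64)) < 0.5, 10.0, 200.0)
        t = li_threshold(img)
        assert 10.0 < t <= 200.0
        assert set(np.unique(img >= t)) == {False, True}
        assert ((img >= t) == (img == 200.0)).all()

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateImageError):
            li_threshold(np.full((16, 16), 3.0))

    def test_matches_exhaustive_scan_on_bimodal_mixture(self):
        rng = np.random.default_rng(7)
        n = 256 * 256
        vals = np.concatenate(
            [
                rng.normal(30.0, 5.0, int(0.6 * n)),
                rng.normal(150.0, 10.0, n - int(0.6 * n)),
            ]
        )
        img = np.clip(np.round(vals), 0, 255).reshape(256, 256)
        t_scan, width = cross_entropy_objective(img)
        assert abs(li_threshold(img) - t_scan) <= width + 1e-9

    def test_agrees_with_skimage_reference(self):
        """Same binary partition as skimage's Li implementation (threshold
        values are not comparable where the histogram has empty gaps)."""
        from skimage.filters import threshold_li

        rng = np.random.default_rng(3)
        n = 128 * 128
        vals = np.concatenate(
            [rng.normal(40, 6, n // 2), rng.normal(170, 12, n - n // 2)]
        )
        img = np.clip(np.round(vals), 0, 255).reshape(128, 128)
        ours = img >= li_threshold(img)
        reference = img > threshold_li(img)
        assert (ours == reference).mean() > 0.999

    @given(c=st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_equivariance(self, c):
        rng = np.random.default_rng(11)
        img = np.concatenate(
            [rng.normal(30, 4, 2000), rng.normal(120, 9, 2000)]
        ).reshape(40, 100)
        t = li_threshold(img)
        t_scaled = li_threshold(c * img)
        bin_width = c * (img.max() - img.min()) / 256
        assert abs(t_scaled - c * t) <= 2 * bin_width
        assert np.array_equal(c * img >= t_scaled, img >= t)


class TestRefineMask:
    def test_single_pixel_vanishes_after_one_round(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[8, 8] = True
        assert not refine_mask(mask, 1).any()

    def test_opening_preserves_disk_interior(self):
        yy, xx = np.mgrid[:64, :64]
        disk = (yy - 32) ** 2 + (xx - 32) ** 2 <= 20**2
        interior = (yy - 32) ** 2 + (xx - 32) ** 2 <= 16**2
        refined = refine_mask(disk, 3)
        assert refined[interior].all()

    def test_matches_skimage_opening_oracle(self):
        from scipy import ndimage as ndi
        from skimage import measure, morphology

        rng = np.random.default_rng(2)
        yy, xx = np.mgrid[:64, :64]
        mask = (yy - 32) ** 2 + (xx - 32) ** 2 <= 18**2
        mask = mask | (rng.random((64, 64)) < 0.01)  # salt noise

        ours = refine_mask(mask, 3)

        se = morphology.diamond(1)  # 3×3 cross
        opened = mask
        for _ in range(3):
            opened = morphology.binary_erosion(opened, se)
        for _ in range(3):
            opened = morphology.binary_dilation(opened, se)
        labels = measure.label(opened, connectivity=1)
        if labels.max():
            sizes = np.bincount(labels.ravel())[1:]
            opened = labels == (np.argmax(sizes) + 1)
        oracle = ndi.binary_fill_holes(opened)
        assert np.array_equal(ours, oracle)

    def test_area_monotone_nonincreasing_in_rounds(self):
        rng = np.random.default_rng(9)
        mask = rng.random((48, 48)) < 0.6
        areas = [refine_mask(mask, r).sum() for r in range(4)]
        assert all(a >= b for a, b in zip(areas, areas[1:]))

    def test_idempotent_at_zero_rounds(self):
        rng = np.random.default_rng(4)
        mask = rng.random((32, 32)) < 0.5
        once = refine_mask(mask, 0)
        assert np.array_equal(refine_mask(once, 0), once)


class TestSegmentOrganoid:
    def test_equatorial_area_close_to_disk_area(self):
        model = model_for_radius(50.0)
        spec = SyntheticOrganoidSpec(
            radius=50.0, n_cells=tissue_cell_count(50.0), rng_seed=3
        )
        stack, _ = generate_organoid_stack(spec, model, noise=False)
        _, roi = segment_organoid(stack)
        area = roi.areas_um2[roi.largest_slice]
        assert area == pytest.approx(math.pi * 50.0**2, rel=0.05)

    def test_blank_stack_raises_segmentation_failure(self, small_model):
        rng = np.random.default_rng(0)
        shape = (3, *small_model.stack_shape)
        data = np.clip(
            rng.normal(
                small_model.background_level,
                small_model.read_noise_sd,
                size=shape,
            ),
            0,
            None,
        )
        blank = ImageStack(
            data, DEFAULT_CHANNELS, small_model.pixel_size_xy, small_model.z_step
        )
        with pytest.raises(SegmentationError):
            segment_organoid(blank)

    def test_keeps_only_larger_of_two_blobs(self):
        yy, xx = np.mgrid[:128, :128]
        big = (yy - 64) ** 2 + (xx - 40) ** 2 <= 22**2
        small = (yy - 64) ** 2 + (xx - 100) ** 2 <= 10**2
        nuclear = np.where(big | small, 1000.0, 50.0)[None, :, :]
        stack = ImageStack(
            np.stack([nuclear, nuclear * 0, nuclear * 0]),
            DEFAULT_CHANNELS,
            pixel_size_xy=1.0,
            z_step=2.0,
        )
        _, roi = segment_organoid(stack, rounds=1)
        region = roi.regions[0]
        assert region[64, 40] and not region[64, 100]


class TestOrganoidDiameter:
    def test_disk_of_known_area_gives_100um(self):
        # a single-slice disk of area pi * 50^2 um^2 at 1 um/px
        yy, xx = np.mgrid[:128, :128]
        disk = (yy - 64) ** 2 + (xx - 64) ** 2 <= 50.0**2
        nuclear = np.where(disk, 2000.0, 50.0)[None, :, :]
        stack = ImageStack(
            np.stack([nuclear, nuclear * 0, nuclear * 0]),
            DEFAULT_CHANNELS,
            pixel_size_xy=1.0,
            z_step=2.0,
        )
        _, roi = segment_organoid(stack, sigma=1.0, rounds=1)
        assert organoid_diameter(roi) == pytest.approx(100.0, abs=2.0)

    def test_ellipse_gives_geometric_mean_diameter(self):
        yy, xx = np.mgrid[:160, :160]
        ellipse = ((yy - 80) / 40.0) ** 2 + ((xx - 80) / 50.0) ** 2 <= 1.0
        nuclear = np.where(ellipse, 2000.0, 50.0)[None, :, :]
        stack = ImageStack(
            np.stack([nuclear, nuclear * 0, nuclear * 0]),
            DEFAULT_CHANNELS,
            pixel_size_xy=1.0,
            z_step=2.0,
        )
        _, roi = segment_organoid(stack, sigma=1.0, rounds=1)
        assert organoid_diameter(roi) == pytest.approx(
            2 * math.sqrt(40.0 * 50.0), abs=2.0
        )

    def test_diameter_recovery_on_noisy_organoids(self):
        for seed, radius in [(1, 32.0), (2, 55.0), (3, 75.0)]:
            model = model_for_radius(radius)
            spec = SyntheticOrganoidSpec(
                radius=radius, n_cells=tissue_cell_count(radius), rng_seed=seed
            )
            stack, truth = generate_organoid_stack(spec, model, noise=True)
            _, roi = segment_organoid(stack)
            assert organoid_diameter(roi) == pytest.approx(
                truth.diameter, rel=0.05
            )
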