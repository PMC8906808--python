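"""Shared fixtures: small, fast synthetic organoids with known truth."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

# property tests run derandomised so the suite is reproducible everywhere
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from somitoscreen import (  # noqa: E402
    ImagingModel,
    RosetteTruth,
    SyntheticOrganoidSpec,
    generate_organoid_stack,
    model_for_radius,
    tissue_cell_count,
)
from somitoscreen.simulate import _place_rosette_centers


@pytest.fixture(scope="session")
def small_model() -> ImagingModel:
    """Field of view sized for a radius-40 µm organoid."""
    return model_for_radius(40.0)


def make_rosette_organoid(
    n_rosettes: int,
    seed: int,
    radius: float = 55.0,
    noise: bool = True,
    marker_pos_fraction: float = 0.8,
    **rosette_kwargs,
):
    """One organoid with ``n_rosettes`` planted structures and its truth."""
    model = model_for_radius(radius)
    rng = np.random.default_rng(seed)
    centers = _place_rosette_centers(
        n_rosettes, model.physical_extent / 2.0, radius, 12.0, rng
    )
    rosettes = tuple(
        RosetteTruth(center=tuple(c), **rosette_kwargs) for c in centers
    )
    spec = SyntheticOrganoidSpec(
        radius=radius,
        n_cells=tissue_cell_count(radius),
        marker_pos_fraction=marker_pos_fraction,
        rosettes=rosettes,
        rng_seed=seed,
    )
    stack, truth = generate_organoid_stack(spec, model, noise=noise)
    return stack, truth, model


@pytest.fixture(scope="session")
def plain_organoid(small_model):
    """Rosette-free organoid (radius 40 µm, default noise)."""
    spec = SyntheticOrganoidSpec(
        radius=40.0, n_cells=tissue_cell_count(40.0), rng_seed=11
    )
    stack, truth = generate_organoid_stack(spec, small_model, noise=True)
    return stack, truth


@pytest.fixture(scope="session")
def seven_rosette_stack():
    """Noise-free stack with 7 planted marker-positive rosettes."""
    return make_rosette_organoid(7, seed=21, noise=False)
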