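"""Ground-truthed synthetic inputs for the organoid screening pipeline.

Four generators emulate the data the pipeline consumes:

* :func:`generate_organoid_stack` — a 3-channel confocal z-stack of one
  organoid (nuclear stain, fate marker, structural marker) with planted
  epithelial rosettes and a full geometric ground truth;
* :func:`generate_screen_plate` — a plate of organoids across treatment
  conditions with per-condition effect parameters;
* :func:`generate_count_matrix` — a gene×cell UMI matrix with planted
  low-quality cells and cluster-specific marker genes;
* :func:`generate_ct_table` — triplicate qPCR Ct values built so that the
  ΔΔCt method recovers known fold-changes in expectation.

All generators are deterministic given their seed: identical inputs yield
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .stack import DEFAULT_CHANNELS, ImageStack

# Rendered blob peak amplitudes (16-bit intensity units).  The fate-marker
# amplitude of a marker-positive nucleus exceeds the nuclear-stain amplitude
# so that the blurred marker/nuclear ratio is > 1 on positive cells and
# well below 1 on negative ones.
NUCLEAR_AMPLITUDE = 3000.0
MARKER_AMPLITUDE_FACTOR = 2.0
STRUCTURAL_FOCUS_AMPLITUDE = 3000.0
STRUCTURAL_DIFFUSE_LEVEL = 300.0
#: dim haze filling the whole organoid ball in the nuclear channel —
#: cytoplasmic Hoechst background and out-of-focus light in dense tissue
NUCLEAR_DIFFUSE_LEVEL = 100.0

#: nuclei per µm³ of packed organoid tissue (≈ 9 µm centre-to-centre
#: spacing), used when a cell count is derived from organoid volume
DEFAULT_PACKING_DENSITY = 1.5e-3


def tissue_cell_count(radius: float, density: float = DEFAULT_PACKING_DENSITY) -> int:
    """Nucleus count of a packed organoid ball of the given radius (µm)."""
    return max(1, round(density * 4.0 / 3.0 * math.pi * radius**3))


@dataclass(frozen=True)
class ImagingModel:
    """Acquisition model for rendered stacks.

    Defaults mirror a 20× confocal z-series: 2 µm z-step, 66 optical
    sections, 16-bit detector.  The XY pixel size is a configuration
    default (0.65 µm/px), not a measured value.
    """

    pixel_size_xy: float = 0.65
    z_step: float = 2.0
    stack_shape: tuple[int, int, int] = (66, 256, 256)
    psf_sigma: float = 0.8          # µm, isotropic optical blur
    background_level: float = 100.0  # camera offset + autofluorescence
    read_noise_sd: float = 5.0       # Gaussian read noise, intensity units
    photon_scale: float = 1.0        # Poisson rate per intensity unit
    bit_depth: int = 16

    def __post_init__(self) -> None:
        for name in ("pixel_size_xy", "z_step", "psf_sigma", "photon_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.background_level < 0 or self.read_noise_sd < 0:
            raise ValueError("background and read noise must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if len(self.stack_shape) != 3 or any(s < 1 for s in self.stack_shape):
            raise ValueError("stack_shape must be three positive ints")

    @property
    def max_intensity(self) -> float:
        return float(2**self.bit_depth - 1)

    @property
    def voxel_size(self) -> np.ndarray:
        """(z, y, x) voxel edge lengths in µm."""
        return np.array([self.z_step, self.pixel_size_xy, self.pixel_size_xy])

    @property
    def physical_extent(self) -> np.ndarray:
        """(z, y, x) physical size of the imaged volume in µm."""
        return np.asarray(self.stack_shape) * self.voxel_size


def model_for_radius(
    radius: float,
    base: ImagingModel | None = None,
    margin: float = 1.3,
) -> ImagingModel:
    """An :class:`ImagingModel` whose field of view frames one organoid.

    The lateral extent is ``margin`` times the organoid diameter and the
    z-range covers the full ball plus a few slices, mirroring how a
    single-organoid well is framed during acquisition.  Framing matters:
    Li's threshold assumes a reasonably balanced foreground/background
    histogram, which a vast empty field would break.
    """
    base = base or ImagingModel()
    n_xy = int(math.ceil(margin * 2.0 * radius / base.pixel_size_xy))
    n_z = int(math.ceil(2.0 * radius / base.z_step)) + 4
    return ImagingModel(
        pixel_size_xy=base.pixel_size_xy,
        z_step=base.z_step,
        stack_shape=(n_z, n_xy, n_xy),
        psf_sigma=base.psf_sigma,
        background_level=base.background_level,
        read_noise_sd=base.read_noise_sd,
        photon_scale=base.photon_scale,
        bit_depth=base.bit_depth,
    )


@dataclass(frozen=True)
class RosetteTruth:
    """One planted somite-like rosette.

    A nucleus-free lumen ball of ``lumen_radius`` sits at ``center``;
    ``n_ring_cells`` nuclei are placed on the mid-shell sphere between
    lumen and ``shell_radius``; the structural channel carries a bright
    focus at the lumen center (apical F-ACTIN/NCAD accumulation).  The
    epithelial shell is exclusive territory: interior (non-ring) nuclei
    are kept out of the whole shell ball, as cells cannot straddle the
    epithelium.  The default ring count packs the mid-shell sphere at
    columnar-epithelium density so every z-slice through the center shows
    a closed ring.
    """

    center: tuple[float, float, float]  # (z, y, x) µm
    lumen_radius: float = 6.0
    shell_radius: float = 12.0
    n_ring_cells: int = 40
    marker_positive: bool = True
    #: ablation switch — False fills the cavity with ordinary tissue
    #: (nuclei + haze), defeating the central-cavity criterion only
    has_lumen: bool = True
    #: ablation switch — False scatters the ring nuclei through the shell
    #: volume instead of tiling the mid-shell sphere, defeating the
    #: radial-arrangement criterion only
    ring_on_sphere: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.lumen_radius < self.shell_radius:
            raise ValueError("need 0 < lumen_radius < shell_radius")
        if self.n_ring_cells < 4:
            raise ValueError("n_ring_cells must be >= 4")

    @property
    def mid_shell_radius(self) -> float:
        return 0.5 * (self.lumen_radius + self.shell_radius)

    @property
    def n_fill_cells(self) -> int:
        """Nuclei filling an ablated cavity (``has_lumen=False``) at the
        same volumetric density as the epithelial shell."""
        if self.has_lumen:
            return 0
        lumen_vol = self.lumen_radius**3
        shell_vol = self.shell_radius**3 - self.lumen_radius**3
        return max(1, round(self.n_ring_cells * lumen_vol / shell_vol))


@dataclass(frozen=True)
class SyntheticOrganoidSpec:
    """Geometry and composition of one synthetic organoid."""

    radius: float = 60.0            # µm
    n_cells: int = 500              # initial cell number of the aggregate
    nucleus_radius: float = 4.0     # µm
    marker_pos_fraction: float = 0.8
    rosettes: tuple[RosetteTruth, ...] = ()
    center: tuple[float, float, float] | None = None  # µm; None = stack center
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.nucleus_radius <= 0:
            raise ValueError("radii must be positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0.0 <= self.marker_pos_fraction <= 1.0:
            raise ValueError("marker_pos_fraction must be in [0, 1]")
        object.__setattr__(self, "rosettes", tuple(self.rosettes))


@dataclass
class GroundTruth:
    """What was actually planted — the oracle for every downstream stage."""

    diameter: float                   # µm, = 2 × spec radius
    center: np.ndarray                # (z, y, x) µm
    nucleus_positions: np.ndarray     # (n_cells, 3) µm
    marker_labels: np.ndarray         # (n_cells,) bool
    rosettes: list[RosetteTruth]
    condition: str = ""

    @property
    def n_rosettes(self) -> int:
        return len(self.rosettes)

    @property
    def n_marker_positive_rosettes(self) -> int:
        return sum(r.marker_positive for r in self.rosettes)


def _validate_geometry(spec: SyntheticOrganoidSpec, model: ImagingModel) -> np.ndarray:
    extent = model.physical_extent
    center = (
        np.asarray(spec.center, dtype=float)
        if spec.center is not None
        else extent / 2.0
    )
    if np.any(center - spec.radius < 0) or np.any(center + spec.radius > extent):
        raise ValueError(
            f"stack extent {tuple(np.round(extent, 1))} µm too small for an "
            f"organoid of radius {spec.radius} µm at {tuple(np.round(center, 1))}"
        )
    for ros in spec.rosettes:
        d = np.linalg.norm(np.asarray(ros.center, dtype=float) - center)
        if d > spec.radius - ros.lumen_radius:
            raise ValueError(
                f"rosette at {ros.center} lies outside the organoid sphere "
                f"(|offset| = {d:.1f} µm, radius = {spec.radius} µm)"
            )
    return center


def _sample_in_ball(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """Uniform points in a 3D ball (radius scaling of unit directions)."""
    directions = rng.normal(size=(n, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return directions * r[:, None]


def _fibonacci_sphere(n: int, rng: np.random.Generator) -> np.ndarray:
    """Near-even unit directions: jittered, randomly rotated Fibonacci
    lattice.  Epithelial cells tile a surface at even spacing, so the ring
    nuclei cover the mid-shell sphere without the large gaps that
    Poisson-random placement would leave."""
    i = np.arange(n) + 0.5
    phi = math.pi * (1.0 + math.sqrt(5.0)) * i
    cos_theta = 1.0 - 2.0 * i / n
    sin_theta = np.sqrt(np.clip(1.0 - cos_theta**2, 0.0, 1.0))
    pts = np.column_stack(
        [cos_theta, sin_theta * np.sin(phi), sin_theta * np.cos(phi)]
    )
    # small positional jitter (~20% of lattice spacing) keeps realism
    pts += rng.normal(scale=0.2 * 2.0 / math.sqrt(n), size=pts.shape)
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    # random rotation so the lattice poles are not axis-aligned
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return pts @ rot.T


def _place_nuclei(
    spec: SyntheticOrganoidSpec,
    center: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Nucleus positions (µm) and marker labels honouring planted rosettes."""
    n_ring_total = sum(r.n_ring_cells + r.n_fill_cells for r in spec.rosettes)
    n_interior = spec.n_cells - n_ring_total
    if n_interior < 0:
        raise ValueError(
            f"rosette ring cells ({n_ring_total}) exceed n_cells ({spec.n_cells})"
        )

    positions: list[np.ndarray] = []
    labels: list[np.ndarray] = []

    for ros in spec.rosettes:
        c = np.asarray(ros.center, dtype=float)
        if ros.ring_on_sphere:
            directions = _fibonacci_sphere(ros.n_ring_cells, rng)
            ring = c + directions * ros.mid_shell_radius
        else:
            # ablated radial arrangement: scatter through the shell volume.
            # Nuclei keep a nucleus-sized standoff from the cavity (whole
            # cells cannot protrude into the lumen), so only the angular
            # arrangement is perturbed, not the cavity itself.
            inner = ros.lumen_radius + spec.nucleus_radius / 2.0
            directions = rng.normal(size=(ros.n_ring_cells, 3))
            directions /= np.linalg.norm(directions, axis=1, keepdims=True)
            u = rng.random(ros.n_ring_cells)
            radii = (
                inner**3 + u * (ros.shell_radius**3 - inner**3)
            ) ** (1.0 / 3.0)
            ring = c + directions * radii[:, None]
        positions.append(ring)
        labels.append(np.full(ros.n_ring_cells, ros.marker_positive))
        if ros.n_fill_cells:
            # ablated cavity: nuclei occupy the lumen at shell density
            fill = c + _sample_in_ball(rng, ros.n_fill_cells, ros.lumen_radius)
            positions.append(fill)
            labels.append(np.full(ros.n_fill_cells, ros.marker_positive))

    if n_interior > 0:
        shell_centers = np.array(
            [r.center for r in spec.rosettes], dtype=float
        ).reshape(-1, 3)
        shell_radii = np.array([r.shell_radius for r in spec.rosettes])
        accepted = np.empty((0, 3))
        # rejection sampling: interior nuclei avoid every rosette shell ball
        while len(accepted) < n_interior:
            batch = center + _sample_in_ball(rng, 2 * n_interior, spec.radius)
            if len(shell_centers):
                d = np.linalg.norm(
                    batch[:, None, :] - shell_centers[None, :, :], axis=2
                )
                batch = batch[np.all(d > shell_radii[None, :], axis=1)]
            accepted = np.vstack([accepted, batch])
        interior = accepted[:n_interior]
        positions.append(interior)
        labels.append(rng.random(n_interior) < spec.marker_pos_fraction)

    return np.vstack(positions), np.concatenate(labels)


def _render_blobs(
    positions_um: np.ndarray,
    amplitudes: np.ndarray,
    sigma_um: float,
    model: ImagingModel,
) -> np.ndarray:
    """Sum of isotropic 3D Gaussians rendered on the voxel grid.

    Implemented as amplitude impulses at the nearest voxel followed by one
    anisotropic (in voxel units) Gaussian filter, normalised so each blob's
    rendered peak equals its amplitude.
    """
    field_ = np.zeros(model.stack_shape, dtype=np.float32)
    if len(positions_um) == 0:
        return field_
    sigma_total = math.sqrt(sigma_um**2 + model.psf_sigma**2)
    sigma_vox = sigma_total / model.voxel_size  # (z, y, x)
    peak_norm = (2.0 * math.pi) ** 1.5 * float(np.prod(sigma_vox))
    idx = np.round(positions_um / model.voxel_size).astype(int)
    idx = np.clip(idx, 0, np.asarray(model.stack_shape) - 1)
    np.add.at(field_, tuple(idx.T), (amplitudes * peak_norm).astype(np.float32))
    return ndi.gaussian_filter(field_, sigma=sigma_vox, mode="constant")


def _ball_mask(
    center_um: np.ndarray, radius_um: float, model: ImagingModel
) -> np.ndarray:
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(model.stack_shape, model.voxel_size)],
        indexing="ij",
    )
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center_um))
    return d2 <= radius_um**2


def apply_noise(
    clean: np.ndarray,
    model: ImagingModel,
    rng: np.random.Generator,
    enabled: bool = True,
) -> np.ndarray:
    """Background + Poisson photon noise + Gaussian read noise, clipped."""
    expected = (clean + model.background_level).astype(np.float64)
    if not enabled:
        return np.clip(expected, 0.0, model.max_intensity).astype(np.float32)
    photons = rng.poisson(expected * model.photon_scale) / model.photon_scale
    noisy = photons + rng.normal(0.0, model.read_noise_sd, size=clean.shape)
    return np.clip(noisy, 0.0, model.max_intensity).astype(np.float32)


def generate_organoid_stack(
    spec: SyntheticOrganoidSpec,
    model: ImagingModel | None = None,
    noise: bool = True,
) -> tuple[ImageStack, GroundTruth]:
    """Render one organoid as a 3-channel stack plus its ground truth.

    Channels: ``nuclear`` — Gaussian blobs at every nucleus; ``marker`` —
    blobs only at marker-positive nuclei (brighter, so the blurred
    marker/nuclear ratio exceeds 1 on positive cells); ``structural`` —
    diffuse signal across the organoid plus one bright Gaussian focus per
    planted rosette.  Rosette lumens are nucleus-free and their ring nuclei
    sit on the mid-shell sphere.
    """
    model = model or ImagingModel()
    center = _validate_geometry(spec, model)
    rng = np.random.default_rng(spec.rng_seed)

    positions, labels = _place_nuclei(spec, center, rng)

    blob_sigma = spec.nucleus_radius / 2.0
    nuclear = _render_blobs(
        positions, np.full(len(positions), NUCLEAR_AMPLITUDE), blob_sigma, model
    )
    # cytoplasmic haze fills the tissue ball but not rosette lumens (cavities)
    haze = np.zeros(model.stack_shape, dtype=np.float32)
    haze[_ball_mask(center, spec.radius, model)] = NUCLEAR_DIFFUSE_LEVEL
    for ros in spec.rosettes:
        if ros.has_lumen:
            haze[
                _ball_mask(np.asarray(ros.center, float), ros.lumen_radius, model)
            ] = 0.0
    nuclear += ndi.gaussian_filter(
        haze, sigma=model.psf_sigma / model.voxel_size, mode="constant"
    )
    marker_amp = np.where(
        labels, NUCLEAR_AMPLITUDE * MARKER_AMPLITUDE_FACTOR, 0.0
    )
    marker = _render_blobs(positions[labels], marker_amp[labels], blob_sigma, model)

    structural = np.zeros(model.stack_shape, dtype=np.float32)
    structural[_ball_mask(center, spec.radius, model)] = STRUCTURAL_DIFFUSE_LEVEL
    structural = ndi.gaussian_filter(
        structural, sigma=model.psf_sigma / model.voxel_size, mode="constant"
    )
    # one render pass per distinct lumen size, not per rosette
    by_sigma: dict[float, list] = {}
    for ros in spec.rosettes:
        by_sigma.setdefault(ros.lumen_radius / 2.0, []).append(ros.center)
    for focus_sigma, centers_ in by_sigma.items():
        pos = np.asarray(centers_, dtype=float).reshape(-1, 3)
        structural += _render_blobs(
            pos,
            np.full(len(pos), STRUCTURAL_FOCUS_AMPLITUDE),
            focus_sigma,
            model,
        )

    channels = np.stack(
        [
            apply_noise(nuclear, model, rng, noise),
            apply_noise(marker, model, rng, noise),
            apply_noise(structural, model, rng, noise),
        ]
    )
    stack = ImageStack(
        data=channels,
        channel_names=DEFAULT_CHANNELS,
        pixel_size_xy=model.pixel_size_xy,
        z_step=model.z_step,
        metadata={"rng_seed": spec.rng_seed, "noise": noise},
    )
    truth = GroundTruth(
        diameter=2.0 * spec.radius,
        center=center,
        nucleus_positions=positions,
        marker_labels=np.asarray(labels, dtype=bool),
        rosettes=list(spec.rosettes),
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Screen plates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenCondition:
    """Effect parameters of one treatment condition on the plate.

    ``rosette_count`` fixes the number of planted rosettes per organoid;
    ``rosette_mean`` instead draws the count from a Poisson distribution,
    or — when ``rosette_sd`` is also given — from a rounded normal
    clipped at zero.  The latter models a regulated, reproducible
    condition whose replicate-to-replicate dispersion is smaller than
    Poisson (an optimised protocol forms a characteristic number of
    structures per organoid).  Exactly one of ``rosette_mean`` /
    ``rosette_count`` must be set.  ``n_cells = None`` derives the
    rendered nucleus count from the organoid volume at tissue packing
    density.
    """

    label: str
    n_cells: int | None = None
    radius: float = 60.0             # µm
    marker_pos_fraction: float = 0.8
    rosette_mean: float | None = None
    rosette_sd: float | None = None
    rosette_count: int | None = None
    rosette_marker_positive_prob: float = 1.0
    lumen_radius: float = 6.0        # µm
    shell_radius: float = 12.0       # µm
    n_ring_cells: int = 40

    def __post_init__(self) -> None:
        if (self.rosette_mean is None) == (self.rosette_count is None):
            raise ValueError("set exactly one of rosette_mean / rosette_count")


def _place_rosette_centers(
    n: int,
    organoid_center: np.ndarray,
    organoid_radius: float,
    shell_radius: float,
    rng: np.random.Generator,
    max_tries: int = 5000,
) -> np.ndarray:
    """Rosette centers inside the organoid, pairwise-separated by 2 shells.

    Shells keep a ~30% standoff below the organoid surface: somite-like
    structures form embedded in tissue, and a nucleus-free shell band
    touching the surface would bite into the organoid outline.
    """
    placement_radius = organoid_radius - 1.3 * shell_radius
    if placement_radius <= 0:
        raise ValueError("organoid too small to contain a rosette shell")
    centers: list[np.ndarray] = []
    for _ in range(max_tries):
        if len(centers) == n:
            break
        cand = organoid_center + _sample_in_ball(rng, 1, placement_radius)[0]
        if all(np.linalg.norm(cand - c) >= 2.0 * shell_radius for c in centers):
            centers.append(cand)
    if len(centers) < n:
        raise ValueError(
            f"could not place {n} rosettes of shell radius {shell_radius} µm "
            f"in an organoid of radius {organoid_radius} µm"
        )
    return np.array(centers).reshape(n, 3)


def generate_screen_plate(
    conditions: Sequence[ScreenCondition],
    replicates_per_condition: int,
    model: ImagingModel | None = None,
    seed: int = 0,
    noise: bool = True,
) -> tuple[list[tuple[ImageStack, GroundTruth]], pd.DataFrame]:
    """One stack per organoid replicate plus a metadata table.

    Per-organoid seeds follow the stated splitting rule
    ``seed + organoid_index`` (index running over conditions × replicates).
    """
    if not conditions:
        raise ValueError("need at least one condition")
    model = model or ImagingModel()
    organoids: list[tuple[ImageStack, GroundTruth]] = []
    rows = []
    index = 0
    for cond in conditions:
        for rep in range(replicates_per_condition):
            org_seed = seed + index
            rng = np.random.default_rng(org_seed)
            if cond.rosette_count is not None:
                k = cond.rosette_count
            elif cond.rosette_sd is not None:
                k = max(0, int(round(rng.normal(cond.rosette_mean, cond.rosette_sd))))
            else:
                k = int(rng.poisson(cond.rosette_mean))
            center = model.physical_extent / 2.0
            ros_centers = _place_rosette_centers(
                k, center, cond.radius, cond.shell_radius, rng
            )
            rosettes = tuple(
                RosetteTruth(
                    center=tuple(c),
                    lumen_radius=cond.lumen_radius,
                    shell_radius=cond.shell_radius,
                    n_ring_cells=cond.n_ring_cells,
                    marker_positive=bool(
                        rng.random() < cond.rosette_marker_positive_prob
                    ),
                )
                for c in ros_centers
            )
            n_cells = (
                cond.n_cells
                if cond.n_cells is not None
                else tissue_cell_count(cond.radius)
            )
            spec = SyntheticOrganoidSpec(
                radius=cond.radius,
                n_cells=n_cells,
                marker_pos_fraction=cond.marker_pos_fraction,
                rosettes=rosettes,
                rng_seed=org_seed,
            )
            stack, truth = generate_organoid_stack(spec, model, noise=noise)
            truth.condition = cond.label
            organoids.append((stack, truth))
            rows.append(
                {
                    "organoid_id": f"{cond.label}_r{rep}",
                    "condition": cond.label,
                    "replicate": rep,
                    "seed": org_seed,
                    "n_cells": n_cells,
                    "radius_um": cond.radius,
                    "marker_pos_fraction": cond.marker_pos_fraction,
                    "true_rosette_count": truth.n_rosettes,
                    "true_marker_positive_rosettes": truth.n_marker_positive_rosettes,
                }
            )
            index += 1
    return organoids, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Count matrices with planted low-quality cells and cluster markers
# ---------------------------------------------------------------------------

MITO_PREFIX = "MT-"


@dataclass(frozen=True)
class CountMatrixPlan:
    """Planted composition of a synthetic gene×cell UMI matrix.

    Low-quality classes are constructed to trip exactly the droplet-QC
    filters used downstream: ``low_umi`` cells fall under 500 total UMIs,
    ``high_mito`` cells draw a mitochondrial fraction above 0.3, and
    ``low_complexity`` cells concentrate their counts on a small gene
    support so that log10(genes)/log10(UMIs) drops below 0.8.
    """

    n_low_umi: int = 50
    n_high_mito: int = 50
    n_low_complexity: int = 50
    n_clusters: int = 2
    markers_per_cluster: int = 5
    marker_fold_change: float = 8.0
    good_umi_range: tuple[int, int] = (2000, 8000)
    low_umi_range: tuple[int, int] = (50, 400)
    low_complexity_umi_range: tuple[int, int] = (2000, 8000)
    low_complexity_n_genes: int = 250
    high_mito_fraction_range: tuple[float, float] = (0.3, 0.6)
    good_mito_fraction_range: tuple[float, float] = (0.01, 0.10)
    n_mito_genes: int = 10

    def validate(self, n_genes: int) -> None:
        if self.low_umi_range[0] >= 500:
            raise ValueError("low-UMI class floor must stay below the 500-UMI cutoff")
        if self.high_mito_fraction_range[0] <= 0.2:
            raise ValueError("high-mito class must draw fractions above the 0.2 cutoff")
        worst = math.log10(self.low_complexity_n_genes) / math.log10(
            self.low_complexity_umi_range[0]
        )
        if worst >= 0.8:
            raise ValueError(
                "low-complexity class parameters cannot guarantee complexity < 0.8"
            )
        if self.low_complexity_n_genes < 200:
            raise ValueError(
                "low-complexity support must keep >= 200 genes so only the "
                "complexity criterion trips"
            )
        needed = self.n_mito_genes + self.n_clusters * self.markers_per_cluster + 200
        if n_genes < needed:
            raise ValueError(f"need at least {needed} genes for this plan")
        if self.marker_fold_change <= 1:
            raise ValueError("marker_fold_change must exceed 1")


class CountMatrixResult(NamedTuple):
    counts: pd.DataFrame          # genes × cells, integer UMI counts
    truth: pd.DataFrame           # per cell: planted_class, cluster
    cluster_markers: dict[int, list[str]]


def generate_count_matrix(
    n_cells: int = 550,
    n_genes: int = 2000,
    plan: CountMatrixPlan | None = None,
    seed: int = 0,
) -> CountMatrixResult:
    """Integer UMI matrix with planted cell classes and marker genes.

    ``n_cells`` minus the planted low-quality classes leaves the good
    cells, split evenly across ``plan.n_clusters`` clusters; each cluster's
    marker genes have their expression weight multiplied by
    ``plan.marker_fold_change`` in that cluster.  Mitochondrial genes carry
    the ``MT-`` name prefix.
    """
    plan = plan or CountMatrixPlan()
    plan.validate(n_genes)
    n_bad = plan.n_low_umi + plan.n_high_mito + plan.n_low_complexity
    n_good = n_cells - n_bad
    if n_good < 2 * plan.n_clusters:
        raise ValueError(
            f"n_cells={n_cells} leaves only {n_good} good cells for "
            f"{plan.n_clusters} clusters"
        )
    rng = np.random.default_rng(seed)

    n_mito = plan.n_mito_genes
    gene_names = [f"{MITO_PREFIX}G{i + 1}" for i in range(n_mito)] + [
        f"GENE{i + 1:04d}" for i in range(n_genes - n_mito)
    ]
    mito_idx = np.arange(n_mito)
    regular_idx = np.arange(n_mito, n_genes)

    base_weight = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    # dedicated marker genes, disjoint across clusters, drawn from the
    # regular (non-mito) block after the low-complexity support
    marker_pool = regular_idx[plan.low_complexity_n_genes:]
    cluster_markers: dict[int, list[str]] = {}
    marker_idx: dict[int, np.ndarray] = {}
    for c in range(plan.n_clusters):
        sel = marker_pool[
            c * plan.markers_per_cluster : (c + 1) * plan.markers_per_cluster
        ]
        marker_idx[c] = sel
        cluster_markers[c] = [gene_names[i] for i in sel]

    classes = (
        ["good"] * n_good
        + ["low_umi"] * plan.n_low_umi
        + ["high_mito"] * plan.n_high_mito
        + ["low_complexity"] * plan.n_low_complexity
    )
    clusters = [c % plan.n_clusters for c in range(n_good)] + [-1] * n_bad

    counts = np.zeros((n_genes, n_cells), dtype=np.int64)
    for j, (cls, clu) in enumerate(zip(classes, clusters)):
        if cls == "low_umi":
            umi = int(rng.integers(plan.low_umi_range[0], plan.low_umi_range[1] + 1))
            mito_frac = float(rng.uniform(*plan.good_mito_fraction_range))
            support = regular_idx
            weights = base_weight[support]
        elif cls == "high_mito":
            umi = int(rng.integers(plan.good_umi_range[0], plan.good_umi_range[1] + 1))
            mito_frac = float(rng.uniform(*plan.high_mito_fraction_range))
            support = regular_idx
            weights = base_weight[support]
        elif cls == "low_complexity":
            umi = int(
                rng.integers(
                    plan.low_complexity_umi_range[0],
                    plan.low_complexity_umi_range[1] + 1,
                )
            )
            mito_frac = float(rng.uniform(*plan.good_mito_fraction_range))
            support = regular_idx[: plan.low_complexity_n_genes]
            weights = base_weight[support]
        else:  # good
            umi = int(rng.integers(plan.good_umi_range[0], plan.good_umi_range[1] + 1))
            mito_frac = float(rng.uniform(*plan.good_mito_fraction_range))
            support = regular_idx
            weights = base_weight[support].copy()
            boost = marker_idx[clu] - n_mito  # positions within regular block
            weights[boost] *= plan.marker_fold_change

        n_mito_umi = int(round(mito_frac * umi))
        n_reg_umi = umi - n_mito_umi
        if n_reg_umi > 0:
            p = weights / weights.sum()
            counts[support, j] += rng.multinomial(n_reg_umi, p)
        if n_mito_umi > 0:
            pm = base_weight[mito_idx] / base_weight[mito_idx].sum()
            counts[mito_idx, j] += rng.multinomial(n_mito_umi, pm)

    cell_names = [f"cell_{j + 1:04d}" for j in range(n_cells)]
    counts_df = pd.DataFrame(counts, index=gene_names, columns=cell_names)
    truth = pd.DataFrame(
        {"planted_class": classes, "cluster": clusters}, index=cell_names
    )
    return CountMatrixResult(counts_df, truth, cluster_markers)


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------


def generate_ct_table(
    genes: Sequence[str],
    samples: Sequence[str],
    true_fold_changes: pd.DataFrame,
    housekeeping: str = "PP1A",
    reference_sample: str = "iPSC",
    ct_noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Technical-replicate Ct values encoding known fold-changes.

    Ct values are built as ``base + loading_offset − log2(fold_change)`` so
    that the ΔΔCt method (housekeeping and reference-sample correction)
    recovers ``true_fold_changes`` exactly at zero noise and in expectation
    otherwise.  ``true_fold_changes`` is genes × samples, relative to
    ``reference_sample`` (whose column must be 1 where present).

    Returns a long-format table with columns gene, sample, replicate, ct.
    """
    genes = list(genes)
    samples = list(samples)
    if housekeeping not in genes:
        raise ValueError(f"housekeeping gene {housekeeping!r} missing from genes")
    if reference_sample not in samples:
        raise ValueError(f"reference sample {reference_sample!r} missing from samples")

    fc = true_fold_changes.copy()
    for g in genes:
        if g not in fc.index:
            fc.loc[g] = 1.0
    fc.loc[housekeeping] = 1.0
    for s in samples:
        if s not in fc.columns:
            fc[s] = 1.0
    if not np.allclose(fc[reference_sample].astype(float), 1.0):
        raise ValueError("fold-changes in the reference sample must all be 1")
    if (fc.loc[genes, samples].astype(float) <= 0).any().any():
        raise ValueError("fold-changes must be positive")

    rng = np.random.default_rng(seed)
    loading = {s: float(rng.uniform(-1.0, 1.0)) for s in samples}
    base_ct = {housekeeping: 20.0}
    for g in genes:
        if g != housekeeping:
            base_ct[g] = 20.0 + float(rng.uniform(3.0, 8.0))

    rows = []
    for g in genes:
        for s in samples:
            mean_ct = base_ct[g] + loading[s] - math.log2(float(fc.loc[g, s]))
            for rep in range(1, n_replicates + 1):
                ct = mean_ct + (
                    float(rng.normal(0.0, ct_noise_sd)) if ct_noise_sd > 0 else 0.0
                )
                rows.append({"gene": g, "sample": s, "replicate": rep, "ct": ct})
    return pd.DataFrame(rows)
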