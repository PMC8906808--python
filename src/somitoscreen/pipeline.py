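"""End-to-end pipeline: simulate → segment → quantify → score → screen.

Every run writes a manifest recording the resolved config, its hash, the
seed and the per-stage outputs; rerunning with an identical config and
seed reproduces identical outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .intensity import mean_normalized_intensity, normalized_marker_image
from .io import write_ground_truth, write_json, write_mask, write_stack
from .rosettes import count_rosettes
from .screen import aggregate_screen
from .segment import organoid_diameter, segment_organoid
from .simulate import ScreenCondition, generate_screen_plate, model_for_radius
from .stack import ImageStack

log = logging.getLogger(__name__)


def analyze_organoid(
    stack: ImageStack, config: PipelineConfig | None = None
) -> tuple[dict, list]:
    """Segment one organoid stack and extract its screen features.

    Returns the feature record (diameter, mean normalized marker
    intensity, rosette count, slice count) and the list of rosette calls.
    """
    config = config or PipelineConfig()
    seg = config.segmentation
    mask, roi = segment_organoid(
        stack,
        nuclear_channel=config.channels.nuclear,
        sigma=seg.sigma,
        rounds=seg.rounds,
        min_class_separation=seg.min_class_separation,
    )
    diameter = organoid_diameter(roi)
    ratio, epsilon = normalized_marker_image(
        stack.channel(config.channels.marker),
        stack.channel(config.channels.nuclear),
        sigma=config.intensity.sigma,
        epsilon=config.intensity.epsilon,
    )
    intensity = mean_normalized_intensity(ratio, roi, config.intensity.sigma, epsilon)
    count, calls = count_rosettes(
        stack,
        roi,
        config.rosettes,
        nuclear_channel=config.channels.nuclear,
        marker_channel=config.channels.marker,
        structural_channel=config.channels.structural,
    )
    features = {
        "diameter_um": diameter,
        "mean_normalized_marker": intensity.organoid_mean,
        "rosette_count": count,
        "n_slices": intensity.n_slices_used,
    }
    return features, calls


def _conditions(config: PipelineConfig) -> list[ScreenCondition]:
    return [
        ScreenCondition(
            label=c.label,
            radius=c.radius,
            marker_pos_fraction=c.marker_pos_fraction,
            rosette_mean=c.rosette_mean,
            rosette_sd=c.rosette_sd,
            rosette_count=c.rosette_count,
        )
        for c in config.simulate.conditions
    ]


def run_pipeline(
    config: PipelineConfig,
    output_dir=None,
    write_stacks: bool = False,
) -> Path:
    """Run the configured synthetic screen end to end.

    Writes per-organoid features (``features.csv``), rosette calls
    (``rosette_calls.csv``), the per-condition summary (``screen_summary
    .csv``), plate metadata and ground truth, plus ``manifest.json``.
    Stack TIFFs are written only on request (they are large).
    Returns the output directory.
    """
    config.validate()
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        radius = max(c.radius for c in config.simulate.conditions)
        model = model_for_radius(radius)
        plate, metadata = generate_screen_plate(
            _conditions(config),
            config.simulate.replicates_per_condition,
            model,
            seed=config.seed,
            noise=config.simulate.noise,
        )
        metadata.to_csv(out / "plate_metadata.csv", index=False)
        for (stack, truth), oid in zip(plate, metadata["organoid_id"]):
            write_ground_truth(truth, out / "truth" / f"{oid}.json")
            if write_stacks:
                write_stack(stack, out / "stacks" / f"{oid}.tiff")

        stage = "analyze"
        feature_rows, call_rows = [], []
        for (stack, truth), row in zip(plate, metadata.to_dict("records")):
            features, calls = analyze_organoid(stack, config)
            feature_rows.append(
                {
                    "organoid_id": row["organoid_id"],
                    "condition": row["condition"],
                    "replicate": row["replicate"],
                    **features,
                }
            )
            for call in calls:
                z, y, x = call.position_um
                call_rows.append(
                    {
                        "organoid_id": row["organoid_id"],
                        "z_um": z,
                        "y_um": y,
                        "x_um": x,
                        "marker_positive_ring": call.marker_positive_ring,
                        "central_focus": call.central_focus,
                        "radial_arrangement": call.radial_arrangement,
                        "counted": call.counted,
                        "d1_um": call.d1_um,
                        "d2_um": call.d2_um,
                        "area_um2": call.area_um2,
                    }
                )
        features_df = pd.DataFrame(feature_rows)
        features_df.to_csv(out / "features.csv", index=False)
        pd.DataFrame(call_rows).to_csv(out / "rosette_calls.csv", index=False)

        stage = "screen"
        summary = aggregate_screen(features_df)
        summary.to_csv(out / "screen_summary.csv", index=False)
    except Exception:
        (out / f"{stage}.partial").write_text(
            f"pipeline aborted during stage: {stage}\n"
        )
        log.exception("pipeline failed during stage %s", stage)
        raise

    write_json(
        {
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.content_hash(),
            "config": config.to_dict(),
            "outputs": sorted(
                str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
            ),
        },
        out / "manifest.json",
    )
    return out
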