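"""Readers and writers for the pipeline's on-disk formats.

Stacks travel as multi-channel TIFF with axis order (channel, z, y, x) and
a JSON sidecar (same path plus ``.json``) holding channel names and the
µm calibration.  Count matrices are MatrixMarket ``matrix.mtx`` with
``genes.txt`` / ``barcodes.txt`` name files; tables are CSV; ground truth
and manifests are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import io as spio
from scipy import sparse

from .simulate import GroundTruth, RosetteTruth
from .stack import ImageStack


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path) -> Path:
    """Write a stack as (C, Z, Y, X) TIFF plus a calibration sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.data.astype(np.float32))
    meta = {
        "channel_names": list(stack.channel_names),
        "pixel_size_xy": stack.pixel_size_xy,
        "z_step": stack.z_step,
        "axes": "CZYX",
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_stack(path) -> ImageStack:
    path = Path(path)
    data = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    return ImageStack(
        data=np.asarray(data, dtype=float),
        channel_names=tuple(meta["channel_names"]),
        pixel_size_xy=float(meta["pixel_size_xy"]),
        z_step=float(meta["z_step"]),
    )


def write_mask(masks: np.ndarray, path) -> Path:
    """Binary per-slice masks as an 8-bit single-channel TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, (np.asarray(masks, bool) * np.uint8(255)))
    return path


def write_ground_truth(truth: GroundTruth, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "diameter": truth.diameter,
        "center": list(map(float, truth.center)),
        "condition": truth.condition,
        "nucleus_positions": np.asarray(truth.nucleus_positions).tolist(),
        "marker_labels": np.asarray(truth.marker_labels, bool).tolist(),
        "rosettes": [dataclasses.asdict(r) for r in truth.rosettes],
    }
    path.write_text(json.dumps(payload))
    return path


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    rosettes = [
        RosetteTruth(**{**r, "center": tuple(r["center"])})
        for r in payload["rosettes"]
    ]
    return GroundTruth(
        diameter=payload["diameter"],
        center=np.asarray(payload["center"]),
        nucleus_positions=np.asarray(payload["nucleus_positions"]),
        marker_labels=np.asarray(payload["marker_labels"], dtype=bool),
        rosettes=rosettes,
        condition=payload.get("condition", ""),
    )


def write_counts_mtx(counts: pd.DataFrame, directory) -> Path:
    """Genes × cells matrix as matrix.mtx + genes.txt + barcodes.txt."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(directory / "matrix.mtx", sparse.csr_matrix(counts.to_numpy()))
    (directory / "genes.txt").write_text("\n".join(counts.index) + "\n")
    (directory / "barcodes.txt").write_text("\n".join(counts.columns) + "\n")
    return directory


def read_counts_mtx(directory) -> pd.DataFrame:
    directory = Path(directory)
    matrix = spio.mmread(directory / "matrix.mtx").toarray().astype(np.int64)
    genes = (directory / "genes.txt").read_text().splitlines()
    cells = (directory / "barcodes.txt").read_text().splitlines()
    return pd.DataFrame(matrix, index=genes, columns=cells)


def write_json(payload: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path
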