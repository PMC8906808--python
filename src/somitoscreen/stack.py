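"""Multi-channel 3D image stacks with physical calibration.

A stack holds one voxel grid per fluorescence channel, all sharing the same
(z, y, x) shape, an XY pixel size in µm/px and a z-step in µm.  Geometry in
every downstream module is expressed in µm using this calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: canonical channel order used by the synthetic generator and the pipeline
DEFAULT_CHANNELS = ("nuclear", "marker", "structural")


@dataclass
class ImageStack:
    """A calibrated multi-channel z-stack.

    Parameters
    ----------
    data:
        Array of shape ``(n_channels, n_z, n_y, n_x)`` with non-negative
        intensities.
    channel_names:
        One name per channel, e.g. ``("nuclear", "marker", "structural")``.
    pixel_size_xy:
        Lateral calibration in µm per pixel.
    z_step:
        Axial distance between consecutive slices in µm.
    """

    data: np.ndarray
    channel_names: tuple[str, ...]
    pixel_size_xy: float
    z_step: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 4:
            raise ValueError("stack data must be (channel, z, y, x)")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.pixel_size_xy <= 0 or self.z_step <= 0:
            raise ValueError("calibration must be positive")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        """(z, y, x) voxel counts."""
        return self.data.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as a (z, y, x) array."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown channel {name!r}; have {self.channel_names}"
            ) from None
        return self.data[idx]

    def has_channel(self, name: str) -> bool:
        return name in self.channel_names


def max_projection(stack: ImageStack, channel: str) -> np.ndarray:
    """Maximum z-projection of one channel (per-pixel maximum over z)."""
    return stack.channel(channel).max(axis=0)
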