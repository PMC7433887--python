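"""Shared data containers for the organoid screening pipeline.

Coordinate convention: arrays are indexed (z, y, x), 0-based. Physical sizes
derive from ``AcquisitionParams.pixel_size`` (lateral, µm/px) and ``z_step``
(axial, µm/plane).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np


class ValidationError(ValueError):
    """Raised when parameters or inputs violate a documented contract."""


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition geometry and noise model of a confocal z-stack.

    Defaults mirror a 384-well high-content confocal run at low
    magnification: 25 optical sections spaced 10 µm apart.
    """

    n_z_planes: int = 25
    z_step: float = 10.0            # µm between planes
    pixel_size: float = 3.25        # µm per pixel (4x objective, binned)
    frame_shape: tuple = (256, 256)  # (height, width) pixels
    background_level: float = 100.0  # camera offset, intensity counts
    noise_sd: float = 5.0            # additive Gaussian read noise
    photon_scaling: float = 1.0      # counts per photon for shot noise

    def __post_init__(self):
        if self.n_z_planes < 1:
            raise ValidationError("n_z_planes must be >= 1")
        if self.z_step <= 0:
            raise ValidationError("z_step must be > 0")
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be > 0")
        if len(self.frame_shape) != 2 or min(self.frame_shape) < 64:
            raise ValidationError("frame_shape dims must both be >= 64")
        if self.photon_scaling <= 0:
            raise ValidationError("photon_scaling must be > 0")

    @property
    def depth_um(self) -> float:
        return self.n_z_planes * self.z_step


@dataclass
class ImageStack:
    """Two-channel 3D intensity volume for one well."""

    nuclei_channel: np.ndarray   # (n_z, H, W)
    actin_channel: np.ndarray    # (n_z, H, W)
    acquisition: AcquisitionParams
    well_id: str = ""

    def __post_init__(self):
        if self.nuclei_channel.shape != self.actin_channel.shape:
            raise ValidationError("channel shapes differ")
        if self.nuclei_channel.ndim != 3:
            raise ValidationError("channels must be 3D (z, y, x)")
        if self.nuclei_channel.shape[0] != self.acquisition.n_z_planes:
            raise ValidationError("plane count does not match acquisition")


@dataclass
class ChannelProjection:
    """2D maximum-intensity projections plus arg-max focus maps."""

    nuclei_2d: np.ndarray
    actin_2d: np.ndarray
    focus_map: np.ndarray        # arg-max plane index of the actin channel
    nuclei_focus_map: np.ndarray
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    well_id: str = ""


@dataclass
class LabelMasks:
    """Integer-labelled organoid, lumen and nucleus masks for one well.

    Label 0 is background; positive labels are consecutive. Parent maps link
    every lumen/nucleus label to the organoid label containing it.
    """

    organoid_labels: np.ndarray
    lumen_labels: np.ndarray
    nucleus_labels: np.ndarray
    parent_of_lumen: Dict[int, int]
    parent_of_nucleus: Dict[int, int]
    well_id: str = ""
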