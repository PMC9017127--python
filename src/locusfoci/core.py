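"""Core domain types shared across the pipeline.

Conventions used throughout the package:

* voxel indices are 0-based and ordered ``(z, y, x)``;
* windows are half-open intervals ``[start, stop)``;
* physical coordinates are nanometres, ordered ``(x, y, z)`` when fed to the
  distance formula;
* image data are non-negative integer counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "VoxelStack",
    "SpotSeed",
    "RoiBox",
    "SpotCentroid",
    "SnrResult",
    "EfficiencyPoint",
    "DistanceRecord",
    "Exclusion",
]


@dataclass
class VoxelStack:
    """A calibrated single-channel 3D intensity grid.

    Parameters
    ----------
    intensities
        Non-negative integer counts indexed ``(z, y, x)``.
    voxel_size
        Physical voxel edge lengths ``(dz, dy, dx)`` in nanometres.
    channel_name
        Free-text channel label (e.g. ``"green"``, ``"red"``, ``"dapi"``).
    """

    intensities: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"intensities must be 3D (z, y, x); got ndim={self.intensities.ndim}"
            )
        if any(d < 1 for d in self.intensities.shape):
            raise ValueError(f"all dims must be >= 1; got shape {self.intensities.shape}")
        if len(self.voxel_size) != 3 or any(s <= 0 for s in self.voxel_size):
            raise ValueError(f"voxel_size must be three positive values; got {self.voxel_size}")
        if np.issubdtype(self.intensities.dtype, np.integer):
            if self.intensities.size and self.intensities.min() < 0:
                raise ValueError("intensities must be non-negative")
        else:
            # float grids appear transiently (expected counts before noise);
            # they must still be non-negative
            if self.intensities.size and float(self.intensities.min()) < 0:
                raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class SpotSeed:
    """An integer-voxel seed marking a candidate focus."""

    channel: str
    z: int
    y: int
    x: int


@dataclass(frozen=True)
class RoiBox:
    """A half-open sub-volume ``[origin, origin + size)`` of a parent stack."""

    origin: tuple[int, int, int]
    size: tuple[int, int, int]
    parent_shape: tuple[int, int, int]
    seed: Optional[SpotSeed] = None

    def __post_init__(self) -> None:
        for o, s, p in zip(self.origin, self.size, self.parent_shape):
            if o < 0 or s < 1 or o + s > p:
                raise ValueError(
                    f"box [{self.origin}, +{self.size}) outside parent {self.parent_shape}"
                )

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(o, o + s) for o, s in zip(self.origin, self.size))  # type: ignore[return-value]


@dataclass
class SpotCentroid:
    """A sub-voxel focus position in the parent stack frame (voxel units)."""

    channel: str
    cz: float
    cy: float
    cx: float
    voxel_count: int = 0
    threshold_used: float = float("nan")
    detector: str = "object_counter"
    group_id: Optional[int] = None

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.cz, self.cy, self.cx)


@dataclass
class SnrResult:
    """Per-spot signal-to-noise statistic with its intermediates.

    ``snr = (max_intensity - background_mean) / background_sd`` where the
    background statistics come from the strictly positive pixels of the
    28x28 box after the 14x14 central deletion, on the max-skew slice.
    """

    seed: SpotSeed
    skew_slice: int
    max_intensity: float
    max_position: tuple[int, int]
    background_mean: float
    background_sd: float
    snr: float
    n_background_pixels: int


@dataclass
class EfficiencyPoint:
    """One labeling-efficiency data point: one MAX-projected substack."""

    substack_index: int
    z_range: tuple[int, int]
    n_nuclei: int
    n_spot_positive: int

    def __post_init__(self) -> None:
        if self.n_spot_positive > self.n_nuclei:
            raise ValueError("spot-positive count cannot exceed nucleus count")

    @property
    def ratio(self) -> float:
        return self.n_spot_positive / self.n_nuclei if self.n_nuclei else float("nan")


@dataclass
class DistanceRecord:
    """A paired green/red focus with its 3D separation in nm."""

    group_id: Optional[int]
    green: SpotCentroid
    red: SpotCentroid
    distance_nm: float
    kept: bool = True
    threshold_nm: float = float("inf")


# exclusion reasons mirror the manual curation rules: nuclei with two
# same-color spots (replicated DNA), missing partners, and the nm filter
EXCLUSION_REASONS = ("two_green", "two_red", "missing_partner", "over_threshold")


@dataclass(frozen=True)
class Exclusion:
    """One excluded candidate pair/group and the rule that removed it."""

    group_id: Optional[int]
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.reason!r}")
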