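"""ROI extraction and 3D focus localization.

Two detectors are provided, mirroring the two routes used for the presented
data: a threshold/volume object counter (threshold at a fraction of the ROI
max, 26-connected components, minimum object size, intensity-weighted
centroid) and a difference-of-Gaussians blob detector with 3-point quadratic
sub-pixel refinement.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
from scipy import ndimage

from .core import RoiBox, SpotCentroid, SpotSeed, VoxelStack

__all__ = [
    "extract_roi",
    "slice_skewness",
    "max_skew_slice",
    "detect_objects",
    "detect_object_counter",
    "detect_dog",
    "find_seeds",
]

logger = logging.getLogger(__name__)

# 26-connectivity in 3D
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def extract_roi(
    stack: VoxelStack, seed: SpotSeed, xy_size: int = 40, n_slices: int = 13
) -> tuple[VoxelStack, RoiBox]:
    """Cut the fixed-geometry analysis window around a seed.

    The XY window is an even ``xy_size`` square covering
    ``[s - xy_size/2, s + xy_size/2)`` on each axis, so the seed sits at
    local index ``xy_size/2``.  The Z window is ``n_slices`` centered on the
    seed slice and truncated at the stack Z boundaries (the actual depth is
    recorded in the returned box).  Seeds closer than ``xy_size/2`` to an XY
    border are rejected.  Returns a copy, never a view.
    """
    if xy_size % 2 != 0:
        raise ValueError(f"xy_size must be even, got {xy_size}")
    nz, ny, nx = stack.shape
    half = xy_size // 2
    if not (0 <= seed.z < nz and 0 <= seed.y < ny and 0 <= seed.x < nx):
        raise ValueError(f"seed {seed} outside stack {stack.shape}")
    if seed.y < half or seed.y + half > ny or seed.x < half or seed.x + half > nx:
        raise ValueError(
            f"border seed: ({seed.y}, {seed.x}) closer than {half} px to an XY border"
        )
    zhalf_lo = (n_slices - 1) // 2
    zhalf_hi = n_slices - zhalf_lo  # half-open
    z0 = max(0, seed.z - zhalf_lo)
    z1 = min(nz, seed.z + zhalf_hi)
    box = RoiBox(
        origin=(z0, seed.y - half, seed.x - half),
        size=(z1 - z0, xy_size, xy_size),
        parent_shape=stack.shape,
        seed=seed,
    )
    sub = stack.intensities[box.slices].copy()
    return VoxelStack(sub, stack.voxel_size, stack.channel_name), box


def slice_skewness(plane: np.ndarray) -> float:
    """Population (Fisher-Pearson) skewness ``m3 / m2**1.5`` of a 2D plane.

    This is the biased moment form, matching ImageJ's "Skewness" measure.
    Returns 0 for a zero-variance plane.
    """
    vals = np.asarray(plane, dtype=np.float64).ravel()
    if vals.size == 0:
        raise ValueError("empty plane")
    mu = vals.mean()
    d = vals - mu
    m2 = np.mean(d**2)
    if m2 == 0:
        return 0.0
    m3 = np.mean(d**3)
    return float(m3 / m2**1.5)


def max_skew_slice(substack) -> int:
    """Local 0-based index of the Z slice with maximal skewness (ties: lowest)."""
    data = substack.intensities if isinstance(substack, VoxelStack) else np.asarray(substack)
    if data.shape[0] < 1:
        raise ValueError("need at least one slice")
    skews = np.array([slice_skewness(data[k]) for k in range(data.shape[0])])
    return int(np.argmax(skews))


def _weighted_centroid(data: np.ndarray, mask: np.ndarray) -> np.ndarray:
    idx = np.argwhere(mask)
    w = data[mask].astype(np.float64)
    return (idx * w[:, None]).sum(axis=0) / w.sum()


def detect_objects(
    substack,
    threshold_frac: float = 0.7,
    min_volume: int = 20,
    origin: tuple[int, int, int] = (0, 0, 0),
    channel: str = "",
) -> list[SpotCentroid]:
    """All above-threshold objects passing the volume filter.

    Thresholds the whole volume at ``threshold_frac`` times its global max,
    labels 26-connected components, drops those smaller than ``min_volume``
    voxels, and reports the intensity-weighted centroid of each survivor in
    the parent frame (``origin`` offsets local coordinates).  Sorted by
    component peak intensity, descending.
    """
    if not (0 < threshold_frac <= 1):
        raise ValueError(f"threshold_frac must be in (0, 1], got {threshold_frac}")
    if min_volume < 1:
        raise ValueError(f"min_volume must be >= 1, got {min_volume}")
    data = substack.intensities if isinstance(substack, VoxelStack) else np.asarray(substack)
    data = data.astype(np.float64)
    gmax = data.max() if data.size else 0.0
    if gmax <= 0:
        logger.warning("detect_objects: all-zero substack, no objects")
        return []
    threshold = threshold_frac * gmax
    mask = data >= threshold
    labels, n = ndimage.label(mask, structure=_STRUCT_26)
    results = []
    off = np.asarray(origin, dtype=np.float64)
    for lab in range(1, n + 1):
        comp = labels == lab
        count = int(comp.sum())
        if count < min_volume:
            continue
        cz, cy, cx = _weighted_centroid(data, comp) + off
        peak = float(data[comp].max())
        results.append(
            (
                peak,
                SpotCentroid(
                    channel=channel,
                    cz=float(cz),
                    cy=float(cy),
                    cx=float(cx),
                    voxel_count=count,
                    threshold_used=float(threshold),
                    detector="object_counter",
                ),
            )
        )
    results.sort(key=lambda t: -t[0])
    return [c for _, c in results]


def detect_object_counter(
    substack,
    threshold_frac: float = 0.7,
    min_volume: int = 20,
    origin: tuple[int, int, int] = (0, 0, 0),
    channel: str = "",
) -> Optional[SpotCentroid]:
    """The object-counter detection for one ROI: the component holding the
    global-max voxel, if it survives the volume filter; otherwise ``None``.
    """
    data = substack.intensities if isinstance(substack, VoxelStack) else np.asarray(substack)
    data = data.astype(np.float64)
    gmax = data.max() if data.size else 0.0
    if gmax <= 0:
        logger.warning("detect_object_counter: all-zero substack")
        return None
    threshold = threshold_frac * gmax
    if not (0 < threshold_frac <= 1):
        raise ValueError(f"threshold_frac must be in (0, 1], got {threshold_frac}")
    if min_volume < 1:
        raise ValueError(f"min_volume must be >= 1, got {min_volume}")
    mask = data >= threshold
    labels, _ = ndimage.label(mask, structure=_STRUCT_26)
    peak_idx = np.unravel_index(int(np.argmax(data)), data.shape)
    lab = labels[peak_idx]
    comp = labels == lab
    count = int(comp.sum())
    if count < min_volume:
        return None
    cz, cy, cx = _weighted_centroid(data, comp) + np.asarray(origin, dtype=np.float64)
    return SpotCentroid(
        channel=channel,
        cz=float(cz),
        cy=float(cy),
        cx=float(cx),
        voxel_count=count,
        threshold_used=float(threshold),
        detector="object_counter",
    )


def _quadratic_offset(fm: float, f0: float, fp: float) -> float:
    """Sub-pixel offset of a parabola through three equally spaced samples."""
    denom = fm - 2.0 * f0 + fp
    if denom >= 0:  # not a local max along this axis
        return 0.0
    off = 0.5 * (fm - fp) / denom
    return float(np.clip(off, -0.5, 0.5))


def detect_dog(
    substack,
    diameter_px: float = 11.0,
    voxel_aspect: Optional[float] = None,
    origin: tuple[int, int, int] = (0, 0, 0),
    channel: str = "",
    threshold: Optional[float] = None,
    k_mad: float = 5.0,
) -> list[SpotCentroid]:
    """Difference-of-Gaussians blob detection with sub-pixel refinement.

    ``sigma1 = diameter_px / (2*sqrt(3))`` and ``sigma2 = 1.6*sigma1`` in the
    lateral axes; axial sigmas are divided by ``voxel_aspect`` (dz/dx).  Local
    maxima of the DoG response above an auto-threshold (median + ``k_mad`` x
    MAD of the response, unless ``threshold`` is given) are refined per axis
    by a 3-point quadratic fit.  Returns detections sorted by response,
    descending.
    """
    if diameter_px <= 0:
        raise ValueError(f"diameter_px must be > 0, got {diameter_px}")
    if isinstance(substack, VoxelStack):
        data = substack.intensities.astype(np.float64)
        if voxel_aspect is None:
            voxel_aspect = substack.voxel_size[0] / substack.voxel_size[2]
    else:
        data = np.asarray(substack, dtype=np.float64)
        if voxel_aspect is None:
            voxel_aspect = 1.0
    if data.max() <= data.min():
        return []
    sigma1 = diameter_px / (2.0 * np.sqrt(3.0))
    sigma2 = 1.6 * sigma1
    s1 = (sigma1 / voxel_aspect, sigma1, sigma1)
    s2 = (sigma2 / voxel_aspect, sigma2, sigma2)
    dog = ndimage.gaussian_filter(data, s1) - ndimage.gaussian_filter(data, s2)
    if threshold is None:
        med = float(np.median(dog))
        mad = float(np.median(np.abs(dog - med)))
        threshold = med + k_mad * mad
    # strict local maxima over the 26-neighborhood
    footprint = np.ones((3, 3, 3), dtype=bool)
    maxfilt = ndimage.maximum_filter(dog, footprint=footprint, mode="constant", cval=-np.inf)
    peaks = np.argwhere((dog >= maxfilt) & (dog > threshold))
    detections = []
    for z, y, x in peaks:
        ipos = (int(z), int(y), int(x))
        pos = np.array(ipos, dtype=np.float64)
        f0 = dog[ipos]
        for ax, n in enumerate(dog.shape):
            if 0 < ipos[ax] < n - 1:
                lo = list(ipos)
                hi = list(ipos)
                lo[ax] -= 1
                hi[ax] += 1
                pos[ax] += _quadratic_offset(dog[tuple(lo)], f0, dog[tuple(hi)])
        detections.append(
            (
                float(dog[z, y, x]),
                SpotCentroid(
                    channel=channel,
                    cz=float(pos[0] + origin[0]),
                    cy=float(pos[1] + origin[1]),
                    cx=float(pos[2] + origin[2]),
                    voxel_count=1,
                    threshold_used=float(threshold),
                    detector="dog",
                ),
            )
        )
    detections.sort(key=lambda t: -t[0])
    return [c for _, c in detections]


def find_seeds(
    stack: VoxelStack,
    channel: Optional[str] = None,
    min_snr_hint: float = 5.0,
    diameter_px: float = 11.0,
    k_mad: float = 5.0,
) -> list[SpotSeed]:
    """Automated seed picking: full-stack DoG detection plus a local-contrast
    gate.

    DoG candidates are kept only if the peak intensity rises at least
    ``min_snr_hint`` robust SDs above the median of a local neighborhood —
    this rejects the shoulder responses a diffuse nuclear background
    produces at nucleus boundaries, which a global response threshold
    cannot separate from dim foci.  Candidates closer than half the spot
    diameter to an accepted seed are treated as duplicates.  Deterministic.
    """
    name = channel if channel is not None else stack.channel_name
    dets = detect_dog(stack, diameter_px=diameter_px, channel=name, k_mad=k_mad)
    data = stack.intensities.astype(np.float64)
    nz, ny, nx = stack.shape
    rad_lat = max(2, int(round(1.5 * diameter_px)))
    rad_ax = max(1, int(round(rad_lat * stack.voxel_size[2] / stack.voxel_size[0])))
    min_sep = diameter_px / 2.0
    seeds: list[SpotSeed] = []
    accepted: list[np.ndarray] = []
    for d in dets:
        z = int(np.clip(round(d.cz), 0, nz - 1))
        y = int(np.clip(round(d.cy), 0, ny - 1))
        x = int(np.clip(round(d.cx), 0, nx - 1))
        pos = np.array([z, y, x], dtype=float)
        if any(
            abs(pos[0] - a[0]) <= max(1.0, min_sep / 3.0)
            and np.hypot(pos[1] - a[1], pos[2] - a[2]) < min_sep
            for a in accepted
        ):
            continue
        box = data[
            max(0, z - rad_ax): z + rad_ax + 1,
            max(0, y - rad_lat): y + rad_lat + 1,
            max(0, x - rad_lat): x + rad_lat + 1,
        ]
        # the local window may straddle a nucleus boundary; its 90th
        # percentile tracks the brightest diffuse level present (the nucleus
        # interior), so a boundary shoulder never looks bright against its
        # own background.  The margin is scaled by the shot-noise SD at that
        # level, the dominant noise source in photon-counting images.
        bg_hi = float(np.percentile(box, 90))
        peak = float(
            data[
                max(0, z - 1): z + 2, max(0, y - 1): y + 2, max(0, x - 1): x + 2
            ].max()
        )
        if peak - bg_hi < min_snr_hint * np.sqrt(max(bg_hi, 1.0)):
            continue
        accepted.append(pos)
        seeds.append(SpotSeed(channel=name, z=z, y=y, x=x))
    return seeds
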