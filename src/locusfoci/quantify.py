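"""Per-spot SNR and per-projection labeling efficiency.

The SNR statistic is computed on the max-skew slice of a 13-slice, 40x40
ROI: the maximum pixel is located, a 14x14 box around it is deleted
(set to zero), and the mean and sample SD of the strictly positive pixels of
the 28x28 box sharing that center give the background, so that

    SNR = (MAX intensity - background mean) / background SD.

Labeling efficiency splits a Z-stack into consecutive 10-slice substacks,
MAX-projects each, segments nuclei on the DAPI projection, and scores each
nucleus as spot-positive from its FP pixel distribution; each projection
contributes one spot+/total ratio.
"""

from __future__ import annotations

import logging
import math
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed
from skimage.feature import peak_local_max

from .core import EfficiencyPoint, SnrResult, SpotSeed, VoxelStack
from .localize import extract_roi, max_skew_slice

__all__ = [
    "compute_snr",
    "batch_snr",
    "split_substacks",
    "max_project",
    "segment_nuclei",
    "score_spot_positive",
    "labeling_efficiency",
]

logger = logging.getLogger(__name__)


def compute_snr(
    stack: VoxelStack,
    seed: SpotSeed,
    xy_size: int = 40,
    n_slices: int = 13,
    delete_box: int = 14,
    bg_box: int = 28,
    min_bg_pixels: int = 10,
) -> SnrResult:
    """Per-spot SNR with all intermediates.

    Deletion is implemented as set-to-zero followed by excluding zero-valued
    pixels from the background statistics; a consequence is that genuinely
    zero background pixels are excluded too.  Background SD is the sample
    (n-1) standard deviation.
    """
    roi, box = extract_roi(stack, seed, xy_size=xy_size, n_slices=n_slices)
    k = max_skew_slice(roi)
    plane = roi.intensities[k].astype(np.float64)
    my, mx = np.unravel_index(int(np.argmax(plane)), plane.shape)
    max_intensity = float(plane[my, mx])

    dh, bh = delete_box // 2, bg_box // 2
    work = plane.copy()
    work[max(0, my - dh): my + dh, max(0, mx - dh): mx + dh] = 0.0
    bg = work[max(0, my - bh): my + bh, max(0, mx - bh): mx + bh]
    vals = bg[bg > 0]
    if vals.size < min_bg_pixels:
        raise ValueError(
            f"background exhausted: only {vals.size} positive pixels survive the deletion"
        )
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate background: zero standard deviation")
    return SnrResult(
        seed=seed,
        skew_slice=k,
        max_intensity=max_intensity,
        max_position=(int(my), int(mx)),
        background_mean=mean,
        background_sd=sd,
        snr=(max_intensity - mean) / sd,
        n_background_pixels=int(vals.size),
    )


def batch_snr(stack: VoxelStack, seeds: Sequence[SpotSeed], **kwargs) -> list[SnrResult]:
    """compute_snr over many seeds; per-seed failures are logged and skipped."""
    out = []
    for seed in seeds:
        try:
            out.append(compute_snr(stack, seed, **kwargs))
        except ValueError as exc:
            logger.warning("SNR skipped for seed %s: %s", seed, exc)
    return out


def split_substacks(stack, group_size: int = 10) -> list:
    """Consecutive non-overlapping Z groups of ``group_size`` slices, plus a
    remainder group when the depth is not divisible by ``group_size``.

    Returns ``(z_start, z_stop, substack)`` triples; substacks are views.
    """
    if group_size < 1:
        raise ValueError(f"group_size must be >= 1, got {group_size}")
    data = stack.intensities if isinstance(stack, VoxelStack) else np.asarray(stack)
    nz = data.shape[0]
    groups = []
    for z0 in range(0, nz, group_size):
        z1 = min(nz, z0 + group_size)
        groups.append((z0, z1, data[z0:z1]))
    return groups


def max_project(substack) -> np.ndarray:
    """Per-pixel maximum-intensity projection over Z."""
    data = substack.intensities if isinstance(substack, VoxelStack) else np.asarray(substack)
    if data.ndim == 2:
        return data.copy()
    return data.max(axis=0)


def segment_nuclei(
    dapi_projection: np.ndarray,
    smooth_sigma: float = 2.0,
    min_area: int = 100,
    min_peak_distance: int = 10,
) -> np.ndarray:
    """Label nuclei in a DAPI MAX projection.

    Otsu threshold on a Gaussian-smoothed image, hole filling, small-object
    removal, then a distance-transform watershed to split touching nuclei.
    Deterministic; returns an integer label image (0 = background).
    """
    img = np.asarray(dapi_projection, dtype=np.float64)
    smoothed = ndimage.gaussian_filter(img, smooth_sigma)
    if smoothed.max() <= smoothed.min():
        logger.warning("segment_nuclei: blank projection, no foreground")
        return np.zeros(img.shape, dtype=np.int32)
    thr = threshold_otsu(smoothed)
    fg = smoothed > thr
    fg = ndimage.binary_fill_holes(fg)
    if not fg.any():
        logger.warning("segment_nuclei: no foreground after thresholding")
        return np.zeros(img.shape, dtype=np.int32)
    dist = ndimage.distance_transform_edt(fg)
    peaks = peak_local_max(
        dist, min_distance=min_peak_distance, labels=fg, exclude_border=False
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (py, px) in enumerate(peaks, start=1):
        markers[py, px] = i
    if markers.max() == 0:
        labels, _ = ndimage.label(fg)
    else:
        labels = watershed(-dist, markers, mask=fg)
    # drop small fragments and relabel consecutively
    out = np.zeros(img.shape, dtype=np.int32)
    nxt = 1
    for lab in range(1, labels.max() + 1):
        comp = labels == lab
        if comp.sum() >= min_area:
            out[comp] = nxt
            nxt += 1
    if nxt == 1:
        logger.warning("segment_nuclei: no nucleus above min_area")
    return out


def score_spot_positive(
    fp_projection: np.ndarray, mask: np.ndarray, k_sigma: float = 6.0
) -> dict:
    """Spot-positive call per nucleus.

    A nucleus is positive iff its brightest in-mask pixel reaches
    ``median + k_sigma * sd`` of its own pixel distribution, with the SD
    estimated robustly as ``1.4826 * MAD`` (floored at one count so a flat
    nucleus is never trivially positive).  Returns ``{label: bool}``.
    """
    fp = np.asarray(fp_projection, dtype=np.float64)
    mask = np.asarray(mask)
    if fp.shape != mask.shape:
        raise ValueError(f"shape mismatch: fp {fp.shape} vs mask {mask.shape}")
    result = {}
    for lab in np.unique(mask):
        if lab == 0:
            continue
        vals = fp[mask == lab]
        med = float(np.median(vals))
        sd = max(1.4826 * float(np.median(np.abs(vals - med))), 1.0)
        if not math.isfinite(k_sigma):
            result[int(lab)] = False
            continue
        result[int(lab)] = bool(vals.max() >= med + k_sigma * sd)
    return result


def labeling_efficiency(
    fp_stack: VoxelStack,
    dapi_stack: VoxelStack,
    group_size: int = 10,
    k_sigma: float = 6.0,
    min_area: int = 100,
) -> list[EfficiencyPoint]:
    """Spot+/total nucleus ratio, one data point per 10-slice MAX projection."""
    points = []
    fp_groups = split_substacks(fp_stack, group_size)
    dapi_groups = split_substacks(dapi_stack, group_size)
    if len(fp_groups) != len(dapi_groups):
        raise ValueError("FP and DAPI stacks have different depths")
    for idx, ((z0, z1, fp_sub), (_, _, dapi_sub)) in enumerate(zip(fp_groups, dapi_groups)):
        fp_proj = max_project(fp_sub)
        dapi_proj = max_project(dapi_sub)
        mask = segment_nuclei(dapi_proj, min_area=min_area)
        n_nuclei = int(mask.max())
        if n_nuclei == 0:
            logger.warning("substack %d [%d, %d): no nuclei, point dropped", idx, z0, z1)
            continue
        calls = score_spot_positive(fp_proj, mask, k_sigma=k_sigma)
        points.append(
            EfficiencyPoint(
                substack_index=idx,
                z_range=(z0, z1),
                n_nuclei=n_nuclei,
                n_spot_positive=sum(calls.values()),
            )
        )
    return points
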