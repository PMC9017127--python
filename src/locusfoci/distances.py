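"""Dual-color focus pairing and 3D inter-locus distances.

Green/red focus centroids are grouped per nucleus (when a label mask is
available) or per picked ROI, groups with two same-color foci are excluded
as replicated (sister-chromatid) nuclei, sub-voxel coordinates are converted
to nm, and pair distances above the nm filter (default 750 nm, chosen to
remove pairs spanning neighboring nuclei) are flagged rather than deleted.
"""

from __future__ import annotations

import logging
from typing import Hashable, Optional, Sequence

import numpy as np

from .core import DistanceRecord, Exclusion, SpotCentroid, SpotSeed, VoxelStack
from .localize import detect_dog, detect_objects, extract_roi, find_seeds

__all__ = [
    "voxel_to_nm",
    "nm_to_voxel",
    "euclidean_3d",
    "pair_spots",
    "filter_distances",
    "distance_pipeline",
]

logger = logging.getLogger(__name__)


def voxel_to_nm(
    coord: Sequence[float], voxel_size: Sequence[float]
) -> tuple[float, float, float]:
    """Convert ``(cz, cy, cx)`` voxel coordinates to ``(x, y, z)`` nm."""
    dz, dy, dx = voxel_size
    if dz <= 0 or dy <= 0 or dx <= 0:
        raise ValueError(f"voxel_size must be positive, got {voxel_size}")
    cz, cy, cx = coord
    return (cx * dx, cy * dy, cz * dz)


def nm_to_voxel(
    point_nm: Sequence[float], voxel_size: Sequence[float]
) -> tuple[float, float, float]:
    """Inverse of :func:`voxel_to_nm`: ``(x, y, z)`` nm to ``(cz, cy, cx)``."""
    dz, dy, dx = voxel_size
    x, y, z = point_nm
    return (z / dz, y / dy, x / dx)


def euclidean_3d(p1: Sequence[float], p2: Sequence[float]) -> float:
    """3D Euclidean distance ``sqrt(dx**2 + dy**2 + dz**2)`` in nm."""
    a = np.asarray(p1, dtype=np.float64)
    b = np.asarray(p2, dtype=np.float64)
    return float(np.linalg.norm(a - b))


def _dedupe(
    centroids: list[SpotCentroid], tol_voxels: float = 1.0
) -> list[SpotCentroid]:
    """Collapse near-identical centroids (same spot seen from overlapping ROIs)."""
    kept: list[SpotCentroid] = []
    for c in centroids:
        dup = False
        for k in kept:
            if (
                abs(c.cz - k.cz) <= tol_voxels
                and abs(c.cy - k.cy) <= tol_voxels
                and abs(c.cx - k.cx) <= tol_voxels
            ):
                dup = True
                break
        if not dup:
            kept.append(c)
    return kept


def pair_spots(
    green: Sequence[SpotCentroid], red: Sequence[SpotCentroid]
) -> tuple[list[tuple[Hashable, SpotCentroid, SpotCentroid]], list[Exclusion]]:
    """Pair one green with one red focus per group.

    Centroids carry their grouping key in ``group_id`` (nucleus label or ROI
    index).  Groups with two or more foci of either color are excluded
    (``two_green``/``two_red`` — replicated nuclei); groups missing a color
    are excluded as ``missing_partner``.
    """
    groups: dict = {}
    for c in green:
        groups.setdefault(c.group_id, ([], []))[0].append(c)
    for c in red:
        groups.setdefault(c.group_id, ([], []))[1].append(c)
    pairs = []
    exclusions = []
    for gid in sorted(groups, key=lambda g: (g is None, g)):
        gs, rs = groups[gid]
        gs = _dedupe(gs)
        rs = _dedupe(rs)
        if len(gs) >= 2:
            exclusions.append(Exclusion(gid, "two_green"))
            continue
        if len(rs) >= 2:
            exclusions.append(Exclusion(gid, "two_red"))
            continue
        if not gs or not rs:
            exclusions.append(Exclusion(gid, "missing_partner"))
            continue
        pairs.append((gid, gs[0], rs[0]))
    return pairs, exclusions


def filter_distances(
    records: Sequence[DistanceRecord], threshold_nm: float = 750.0
) -> tuple[list[DistanceRecord], list[Exclusion]]:
    """Flag records by the nm threshold (kept iff strictly below).

    Nothing is deleted: every record comes back with its ``kept`` flag set,
    and each over-threshold record is logged as an exclusion.
    """
    if threshold_nm <= 0:
        raise ValueError(f"threshold_nm must be > 0, got {threshold_nm}")
    out = []
    exclusions = []
    for rec in records:
        kept = rec.distance_nm < threshold_nm
        out.append(
            DistanceRecord(
                group_id=rec.group_id,
                green=rec.green,
                red=rec.red,
                distance_nm=rec.distance_nm,
                kept=kept,
                threshold_nm=threshold_nm,
            )
        )
        if not kept:
            exclusions.append(Exclusion(rec.group_id, "over_threshold"))
    return out, exclusions


def _group_of(
    centroid: SpotCentroid, mask: Optional[np.ndarray], fallback: int
) -> Optional[int]:
    if mask is None:
        return fallback
    nz, ny, nx = mask.shape
    z = int(np.clip(round(centroid.cz), 0, nz - 1))
    y = int(np.clip(round(centroid.cy), 0, ny - 1))
    x = int(np.clip(round(centroid.cx), 0, nx - 1))
    lab = int(mask[z, y, x])
    return lab if lab > 0 else None


def distance_pipeline(
    green_stack: VoxelStack,
    red_stack: VoxelStack,
    seeds: Optional[Sequence[SpotSeed]] = None,
    mask: Optional[np.ndarray] = None,
    detector: str = "object_counter",
    xy_size: int = 40,
    n_slices: int = 15,
    threshold_frac: float = 0.7,
    min_volume: int = 20,
    dog_diameter: float = 11.0,
    threshold_nm: float = 750.0,
    merged_volume: int = 60,
    screen_volume: int = 5,
) -> tuple[list[DistanceRecord], list[Exclusion]]:
    """End-to-end dual-color distance measurement.

    Green seeds are picked first (automatically unless supplied); a
    15-slice, 40x40 ROI around each seed is cut from both channels; foci are
    localized per channel by the requested detector; centroids are grouped
    per nucleus (label mask) or per ROI; groups are paired with the
    replication-exclusion rules; distances are computed in nm from sub-voxel
    coordinates and flagged by the nm threshold.  Per-ROI failures are
    logged, never fatal.

    Replicated (sister-chromatid) nuclei are screened the way manual
    curation would see them, more sensitively than the reported centroids:
    a second same-color object is counted even when its above-threshold
    support falls below ``min_volume`` (down to ``screen_volume`` voxels,
    a size the eye still registers), and a doublet whose two foci fuse at
    the threshold appears as a single object above ``merged_volume`` voxels
    (about twice a single focus) — both exclude the group as two_green /
    two_red.  Only objects of at least ``min_volume`` voxels ever
    contribute a reported centroid.
    """
    if detector not in ("object_counter", "dog"):
        raise ValueError(f"unknown detector {detector!r}")
    if green_stack.voxel_size != red_stack.voxel_size:
        raise ValueError("green and red stacks must share voxel calibration")
    voxel_size = green_stack.voxel_size
    if seeds is None:
        seeds = find_seeds(green_stack, channel=green_stack.channel_name or "green")

    greens: list[SpotCentroid] = []
    reds: list[SpotCentroid] = []
    aspect = voxel_size[0] / voxel_size[2]
    for roi_idx, seed in enumerate(seeds):
        try:
            g_roi, g_box = extract_roi(green_stack, seed, xy_size=xy_size, n_slices=n_slices)
            r_roi, _ = extract_roi(red_stack, seed, xy_size=xy_size, n_slices=n_slices)
        except ValueError as exc:
            logger.warning("ROI %d (seed %s) skipped: %s", roi_idx, seed, exc)
            continue
        for roi, name, sink in ((g_roi, "green", greens), (r_roi, "red", reds)):
            if detector == "object_counter":
                # sensitive screen: count every object the curation eye would
                # see; the min_volume size filter is applied at pairing time
                found = detect_objects(
                    roi, threshold_frac=threshold_frac, min_volume=screen_volume,
                    origin=g_box.origin, channel=name,
                )
            else:
                found = detect_dog(
                    roi, diameter_px=dog_diameter, voxel_aspect=aspect,
                    origin=g_box.origin, channel=name,
                )
            for c in found:
                c.group_id = _group_of(c, mask, roi_idx)
                if c.group_id is not None:
                    sink.append(c)

    merged_excl: dict = {}
    if detector == "object_counter":
        for name, sink in (("green", greens), ("red", reds)):
            for c in sink:
                if c.voxel_count > merged_volume:
                    merged_excl.setdefault(c.group_id, Exclusion(c.group_id, f"two_{name}"))
    # overlapping ROIs can report the same focus twice; pair_spots dedupes
    # within each group before applying the exclusion rules
    pairs, exclusions = pair_spots(greens, reds)
    if merged_excl:
        pairs = [p for p in pairs if p[0] not in merged_excl]
        exclusions = [e for e in exclusions if e.group_id not in merged_excl]
        exclusions.extend(merged_excl.values())
    records = []
    for gid, g, r in pairs:
        if detector == "object_counter" and (
            g.voxel_count < min_volume or r.voxel_count < min_volume
        ):
            # a focus the screen saw but the size filter rejects cannot
            # anchor a reported distance
            exclusions.append(Exclusion(gid, "missing_partner"))
            continue
        records.append(
            DistanceRecord(
                group_id=gid,
                green=g,
                red=r,
                distance_nm=euclidean_3d(
                    voxel_to_nm(g.as_tuple(), voxel_size), voxel_to_nm(r.as_tuple(), voxel_size)
                ),
            )
        )
    records, over = filter_distances(records, threshold_nm=threshold_nm)
    return records, exclusions + over
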