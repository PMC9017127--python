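"""File formats and pipeline orchestration.

One channel per multi-page TIFF (plane order = Z ascending); seeds and all
result tables are CSV with 0-based voxel coordinates, except distances,
which are nm.  Voxel calibration is written to the TIFF resolution tags and
an ImageDescription JSON; on read, an explicit configuration value wins over
tags, with a warning.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .core import DistanceRecord, Exclusion, SnrResult, SpotCentroid, SpotSeed, VoxelStack
from .simulate import SimulationConfig, generate_field, nucleus_label_stack

__all__ = [
    "read_stack",
    "write_stack",
    "read_seeds",
    "write_seeds",
    "write_centroids",
    "write_snr",
    "write_efficiency",
    "write_distances",
    "write_exclusions",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

_CM_PER_NM = 1e-7


def write_stack(stack: VoxelStack, path) -> None:
    """Write one channel as a multi-page TIFF, Z ascending, with calibration."""
    dz, dy, dx = stack.voxel_size
    desc = json.dumps(
        {"voxel_size_nm": [dz, dy, dx], "channel": stack.channel_name, "axes": "ZYX"}
    )
    # resolution tags are pixels per cm
    tifffile.imwrite(
        str(path),
        stack.intensities,
        resolution=(1.0 / (dx * _CM_PER_NM), 1.0 / (dy * _CM_PER_NM)),
        resolutionunit="CENTIMETER",
        description=desc,
        photometric="minisblack",
    )


def read_stack(
    path,
    voxel_size: Optional[Sequence[float]] = None,
    channel_name: Optional[str] = None,
) -> VoxelStack:
    """Read a single-channel multi-page TIFF into a :class:`VoxelStack`.

    Calibration comes from the TIFF tags when present; an explicit
    ``voxel_size`` always wins, with a warning on conflict.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack not found: {path}")
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        tag_size = _voxel_size_from_tags(tf)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected one channel per file (Z planes only); got shape {data.shape}"
        )
    if voxel_size is not None:
        if tag_size is not None and not np.allclose(tag_size, voxel_size, rtol=1e-3):
            logger.warning(
                "%s: TIFF calibration %s differs from configured %s; using configured",
                path, tag_size, tuple(voxel_size),
            )
        size = tuple(float(v) for v in voxel_size)
    elif tag_size is not None:
        size = tag_size
    else:
        raise ValueError(f"{path}: no calibration in TIFF tags and none configured")
    name = channel_name if channel_name is not None else path.stem
    return VoxelStack(data, size, name)


def _voxel_size_from_tags(tf: "tifffile.TiffFile") -> Optional[tuple[float, float, float]]:
    try:
        desc = tf.pages[0].description
        meta = json.loads(desc) if desc else {}
        if "voxel_size_nm" in meta:
            dz, dy, dx = meta["voxel_size_nm"]
            return (float(dz), float(dy), float(dx))
    except (json.JSONDecodeError, ValueError, KeyError):
        pass
    return None


def write_seeds(seeds: Sequence[SpotSeed], path) -> None:
    pd.DataFrame(
        [{"channel": s.channel, "z": s.z, "y": s.y, "x": s.x} for s in seeds]
    ).to_csv(path, index=False, columns=["channel", "z", "y", "x"])


def read_seeds(path) -> list[SpotSeed]:
    df = pd.read_csv(path)
    return [
        SpotSeed(channel=str(r.channel), z=int(r.z), y=int(r.y), x=int(r.x))
        for r in df.itertuples()
    ]


def write_centroids(centroids: Sequence[SpotCentroid], path) -> None:
    pd.DataFrame(
        [
            {
                "channel": c.channel, "detector": c.detector,
                "cz": c.cz, "cy": c.cy, "cx": c.cx,
                "voxel_count": c.voxel_count, "threshold_used": c.threshold_used,
            }
            for c in centroids
        ]
    ).to_csv(path, index=False)


def write_snr(results: Sequence[SnrResult], path) -> None:
    pd.DataFrame(
        [
            {
                "seed_z": r.seed.z, "seed_y": r.seed.y, "seed_x": r.seed.x,
                "skew_slice": r.skew_slice, "max_intensity": r.max_intensity,
                "background_mean": r.background_mean, "background_sd": r.background_sd,
                "snr": r.snr,
            }
            for r in results
        ]
    ).to_csv(path, index=False)


def write_efficiency(points, path) -> None:
    pd.DataFrame(
        [
            {
                "substack_index": p.substack_index,
                "z_start": p.z_range[0], "z_end": p.z_range[1],
                "n_nuclei": p.n_nuclei, "n_spot_positive": p.n_spot_positive,
                "ratio": p.ratio,
            }
            for p in points
        ]
    ).to_csv(path, index=False)


def write_distances(records: Sequence[DistanceRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "group_id": r.group_id,
                "gx": r.green.cx, "gy": r.green.cy, "gz": r.green.cz,
                "rx": r.red.cx, "ry": r.red.cy, "rz": r.red.cz,
                "distance_nm": r.distance_nm, "kept": r.kept, "detector": r.green.detector,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def write_exclusions(exclusions: Sequence[Exclusion], path) -> None:
    pd.DataFrame(
        [{"group_id": e.group_id, "reason": e.reason} for e in exclusions]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# orchestration


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: dict, outdir) -> dict:
    """Simulate, localize, quantify, measure and summarize in one run.

    ``config`` mirrors :class:`SimulationConfig` plus the analysis constants;
    the resolved configuration (with provenance) is serialized next to every
    output so any result directory regenerates itself exactly.
    """
    from .distances import distance_pipeline
    from .quantify import batch_snr, labeling_efficiency
    from .localize import find_seeds
    from .stats import tukey_box

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_cfg = SimulationConfig.from_dict(config.get("simulation", {}))
    analysis = {
        "threshold_frac": 0.7, "min_volume": 20, "dog_diameter": 11.0,
        "distance_threshold_nm": 750.0, "group_size": 10, "k_sigma": 6.0,
        "detector": "object_counter",
        **config.get("analysis", {}),
    }
    resolved = {"simulation": sim_cfg.to_dict(), "analysis": analysis, "version": __version__}
    resolved["config_hash"] = _config_hash(resolved)
    with open(outdir / "config.json", "w") as fh:
        json.dump(resolved, fh, indent=2, default=str)

    stacks, truth = generate_field(sim_cfg)
    truth.to_json(outdir / "ground_truth.json")
    for name, stack in stacks.items():
        write_stack(stack, outdir / f"{name}.tif")

    fp_channels = [c for c in sim_cfg.channels if c != "dapi"]
    summary: dict = {"n_nuclei": len(truth.nuclei)}

    primary = fp_channels[0]
    seeds = find_seeds(stacks[primary], channel=primary)
    write_seeds(seeds, outdir / "seeds.csv")
    snr_results = batch_snr(stacks[primary], seeds)
    write_snr(snr_results, outdir / "snr.csv")
    if snr_results:
        summary["median_snr"] = float(np.median([r.snr for r in snr_results]))

    if "dapi" in stacks:
        points = labeling_efficiency(
            stacks[primary], stacks["dapi"],
            group_size=analysis["group_size"], k_sigma=analysis["k_sigma"],
        )
        write_efficiency(points, outdir / "efficiency.csv")
        if points:
            summary["pooled_efficiency"] = float(
                sum(p.n_spot_positive for p in points) / sum(p.n_nuclei for p in points)
            )

    if sim_cfg.dual_label and len(fp_channels) >= 2:
        mask = nucleus_label_stack(truth, sim_cfg)
        records, exclusions = distance_pipeline(
            stacks[fp_channels[0]], stacks[fp_channels[1]],
            mask=mask.intensities, detector=analysis["detector"],
            threshold_frac=analysis["threshold_frac"], min_volume=analysis["min_volume"],
            dog_diameter=analysis["dog_diameter"], threshold_nm=analysis["distance_threshold_nm"],
        )
        write_distances(records, outdir / "distances.csv")
        write_exclusions(exclusions, outdir / "exclusions.csv")
        kept = [r.distance_nm for r in records if r.kept]
        if kept:
            box = tukey_box(kept)
            summary["distance_median_nm"] = box.median
            summary["distance_q1_nm"] = box.q1
            summary["distance_q3_nm"] = box.q3
            summary["n_kept_pairs"] = len(kept)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
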