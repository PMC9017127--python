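"""Synthetic 3D microscopy fields with ground truth.

Generates multi-channel Z-stacks of epithelial-style nuclei carrying
diffraction-limited fluorescent foci, emulating FP-labeled genomic loci in
imaginal-disc tissue: a diffuse nuclear FP background, 0-2 foci per nucleus
per channel (two same-color foci model labeled sister chromatids), a tunable
labeling probability, and Poisson shot noise plus Gaussian read noise on an
anisotropic voxel grid.  Every field comes with a complete ground-truth
manifest so downstream detection, SNR, efficiency and distance estimators can
be validated against known answers.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Union

import numpy as np

from .core import VoxelStack

__all__ = [
    "NoiseModel",
    "SimulationConfig",
    "NucleusTruth",
    "SpotTruth",
    "GroundTruth",
    "generate_field",
    "render_spot",
    "apply_noise",
    "expected_snr",
    "nucleus_label_stack",
]

logger = logging.getLogger(__name__)

DTYPE = np.uint16
DTYPE_MAX = np.iinfo(DTYPE).max

# fixed stage codes so adding a channel or stage never perturbs the draws of
# another: each stream is seeded by [root_seed, stage_code, crc32(channel)]
_STAGE_PLACEMENT = 11
_STAGE_LABELS = 23
_STAGE_SPOTS = 37
_STAGE_NOISE = 53


def _stream(root_seed: int, stage: int, channel: str = "") -> np.random.Generator:
    return np.random.default_rng([int(root_seed), stage, zlib.crc32(channel.encode())])


@dataclass
class NoiseModel:
    """Detection noise: Poisson shot noise, Gaussian read noise, offset (counts)."""

    poisson: bool = True
    read_sd: float = 5.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.read_sd < 0:
            raise ValueError(f"read_sd must be >= 0, got {self.read_sd}")


#: separation spec: a fixed nm value, or ("uniform", lo, hi), or ("normal", mean, sd)
SeparationSpec = Union[float, tuple]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic field.

    Defaults describe the regime the pipeline is validated in: Airyscan-like
    (200, 65, 65) nm voxels, ~1 um-radius nuclei, foci with 150/400 nm
    lateral/axial Gaussian sigma and a peak amplitude of 300 counts over a
    100-count nuclear background with Poisson + 5-count read noise
    (analytic per-focus SNR around 27, inside the range FP labeling systems
    achieve in fixed tissue).
    """

    stack_dims: tuple[int, int, int] = (16, 256, 256)
    voxel_size: tuple[float, float, float] = (200.0, 65.0, 65.0)
    n_nuclei: int = 9
    nucleus_radius_nm: tuple[float, float] = (1000.0, 100.0)  # mean, sd
    nuclear_background: tuple[float, float] = (100.0, 10.0)  # mean counts, per-nucleus sd
    cytoplasm_background: float = 20.0
    dapi_intensity: float = 400.0
    spot_amplitude: float = 300.0
    spot_sigma_lateral_nm: float = 150.0
    spot_sigma_axial_nm: float = 400.0
    channels: tuple[str, ...] = ("green",)
    labeling_probability: Union[float, dict] = 1.0
    doublet_probability: float = 0.0
    doublet_separation_nm: float = 500.0
    dual_label: bool = False
    pair_separation_nm: SeparationSpec = 400.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    interior_only: bool = True
    xy_margin_voxels: int = 22  # spot-to-XY-border clearance when interior_only
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(d < 1 for d in self.stack_dims):
            raise ValueError(f"stack_dims must be positive, got {self.stack_dims}")
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if self.spot_sigma_lateral_nm <= 0 or self.spot_sigma_axial_nm <= 0:
            raise ValueError("spot sigmas must be > 0")
        if self.spot_amplitude < 0:
            raise ValueError("spot_amplitude must be >= 0")
        for name, p in list(self._p_by_channel().items()) + [("doublet", self.doublet_probability)]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {name!r} must be in [0, 1], got {p}")

    def _p_by_channel(self) -> dict:
        fp = [c for c in self.channels if c != "dapi"]
        if isinstance(self.labeling_probability, dict):
            return {c: float(self.labeling_probability.get(c, 1.0)) for c in fp}
        return {c: float(self.labeling_probability) for c in fp}

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("stack_dims", "voxel_size", "nucleus_radius_nm", "nuclear_background", "channels"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if isinstance(d.get("pair_separation_nm"), list):
            d["pair_separation_nm"] = tuple(d["pair_separation_nm"])
        if isinstance(d.get("noise"), dict):
            d["noise"] = NoiseModel(**d["noise"])
        return cls(**d)


@dataclass(frozen=True)
class NucleusTruth:
    id: int
    center_nm: tuple[float, float, float]  # (z, y, x) nm
    radius_nm: float


@dataclass(frozen=True)
class SpotTruth:
    nucleus_id: int
    channel: str
    center_nm: tuple[float, float, float]  # (z, y, x) nm
    amplitude: float
    is_doublet_member: bool = False


@dataclass
class GroundTruth:
    """Simulator manifest: true nuclei, true foci, true pair separations."""

    nuclei: list = field(default_factory=list)
    spots: list = field(default_factory=list)
    true_pair_distances: list = field(default_factory=list)  # (nucleus_id, nm)

    def spots_in_channel(self, channel: str) -> list:
        return [s for s in self.spots if s.channel == channel]

    def labeled_nuclei(self, channel: str) -> set:
        return {s.nucleus_id for s in self.spots if s.channel == channel}

    def to_dict(self) -> dict:
        return {
            "nuclei": [asdict(n) for n in self.nuclei],
            "spots": [asdict(s) for s in self.spots],
            "true_pair_distances": [list(t) for t in self.true_pair_distances],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# geometry helpers


def _place_nuclei(config: SimulationConfig, rng: np.random.Generator) -> list[NucleusTruth]:
    """Rejection-sample non-overlapping nucleus spheres inside the field."""
    nz, ny, nx = config.stack_dims
    dz, dy, dx = config.voxel_size
    zext, yext, xext = nz * dz, ny * dy, nx * dx
    mean_r, sd_r = config.nucleus_radius_nm
    margin_xy = config.xy_margin_voxels * max(dy, dx) if config.interior_only else 0.0

    nuclei: list[NucleusTruth] = []
    for nid in range(config.n_nuclei):
        radius = max(200.0, rng.normal(mean_r, sd_r))
        lo_y, hi_y = margin_xy + radius, yext - margin_xy - radius
        lo_x, hi_x = margin_xy + radius, xext - margin_xy - radius
        # nuclei may be optically sectioned in z (shallow stacks), but the
        # center must stay inside so foci can be placed in-bounds
        lo_z, hi_z = min(radius, zext / 2), max(zext - radius, zext / 2)
        if hi_y <= lo_y or hi_x <= lo_x:
            raise ValueError(
                f"stack XY extent ({yext:.0f} x {xext:.0f} nm) too small for a nucleus of "
                f"radius {radius:.0f} nm with margin {margin_xy:.0f} nm (violated: y/x)"
            )
        if zext < radius:
            raise ValueError(
                f"stack Z extent {zext:.0f} nm too small for a nucleus of radius "
                f"{radius:.0f} nm (violated: z)"
            )
        placed = False
        for _ in range(1000):
            cz = rng.uniform(lo_z, hi_z) if hi_z > lo_z else zext / 2
            cy = rng.uniform(lo_y, hi_y)
            cx = rng.uniform(lo_x, hi_x)
            ok = True
            for other in nuclei:
                d = np.sqrt(
                    (cz - other.center_nm[0]) ** 2
                    + (cy - other.center_nm[1]) ** 2
                    + (cx - other.center_nm[2]) ** 2
                )
                if d < radius + other.radius_nm:
                    ok = False
                    break
            if ok:
                nuclei.append(NucleusTruth(nid, (cz, cy, cx), radius))
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place nucleus {nid} after 1000 attempts; "
                f"reduce n_nuclei or enlarge stack_dims"
            )
    return nuclei


def _spot_bounds(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """(lo, hi) nm bounds for focus centers, per (z, y, x)."""
    nz, ny, nx = config.stack_dims
    dz, dy, dx = config.voxel_size
    sig_ax, sig_lat = config.spot_sigma_axial_nm, config.spot_sigma_lateral_nm
    if config.interior_only:
        mxy = config.xy_margin_voxels * max(dy, dx)
        lo = np.array([max(2.0 * sig_ax, 2 * dz), mxy, mxy])
        hi = np.array([(nz - 1) * dz - max(2.0 * sig_ax, 2 * dz), (ny - 1) * dy - mxy, (nx - 1) * dx - mxy])
    else:
        lo = np.array([0.0, 0.0, 0.0])
        hi = np.array([(nz - 1) * dz, (ny - 1) * dy, (nx - 1) * dx])
    return lo, hi


def _sample_point_in_nucleus(
    nucleus: NucleusTruth,
    lo: np.ndarray,
    hi: np.ndarray,
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> np.ndarray:
    c = np.array(nucleus.center_nm)
    for _ in range(max_tries):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        r = nucleus.radius_nm * 0.9 * rng.uniform() ** (1 / 3)
        p = c + r * u
        if np.all(p >= lo) and np.all(p <= hi):
            return p
    # fall back to the clipped nucleus center: always legal for interior nuclei
    return np.clip(c, lo, hi)


def _sample_partner(
    anchor: np.ndarray,
    separation: float,
    nucleus: NucleusTruth,
    lo: np.ndarray,
    hi: np.ndarray,
    rng: np.random.Generator,
    max_tries: int = 1000,
    lateral_only: bool = False,
) -> Optional[np.ndarray]:
    """A point at fixed separation from ``anchor``, inside nucleus and bounds.

    ``lateral_only`` restricts the displacement to the XY plane — used for
    sister-chromatid doublets, which are only observable when displaced
    laterally (an axial offset below the axial PSF extent merges the foci).
    """
    c = np.array(nucleus.center_nm)
    for _ in range(max_tries):
        u = rng.normal(size=3)
        if lateral_only:
            u[0] = 0.0
        u /= np.linalg.norm(u)
        p = anchor + separation * u
        if np.linalg.norm(p - c) <= nucleus.radius_nm and np.all(p >= lo) and np.all(p <= hi):
            return p
    return None


def _draw_separation(spec: SeparationSpec, rng: np.random.Generator) -> float:
    if isinstance(spec, (int, float)):
        return float(spec)
    kind = spec[0]
    if kind == "uniform":
        return float(rng.uniform(spec[1], spec[2]))
    if kind == "normal":
        return float(max(0.0, rng.normal(spec[1], spec[2])))
    raise ValueError(f"unknown separation spec {spec!r}")


def _sphere_mask(
    nucleus: NucleusTruth,
    dims: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
) -> tuple[tuple[slice, slice, slice], np.ndarray]:
    """Bounding-box slices + in-sphere boolean mask for one nucleus."""
    sizes = np.asarray(voxel_size, dtype=float)
    c = np.asarray(nucleus.center_nm) / sizes
    r = nucleus.radius_nm / sizes
    lo = np.maximum(np.floor(c - r).astype(int), 0)
    hi = np.minimum(np.ceil(c + r).astype(int) + 1, dims)
    box = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    zc = np.arange(lo[0], hi[0])[:, None, None] * sizes[0]
    yc = np.arange(lo[1], hi[1])[None, :, None] * sizes[1]
    xc = np.arange(lo[2], hi[2])[None, None, :] * sizes[2]
    inside = (
        (zc - nucleus.center_nm[0]) ** 2
        + (yc - nucleus.center_nm[1]) ** 2
        + (xc - nucleus.center_nm[2]) ** 2
    ) <= nucleus.radius_nm**2
    return box, inside  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# rendering


def _add_gaussian(
    field: np.ndarray,
    voxel_size: Sequence[float],
    center_nm: Sequence[float],
    amplitude: float,
    sigma_lat_nm: float,
    sigma_ax_nm: float,
) -> None:
    """Accumulate an anisotropic 3D Gaussian (evaluated at voxel centers) in place.

    Voxel ``(z, y, x)`` sits at physical position ``(z*dz, y*dy, x*dx)`` nm.
    Only a +-5 sigma window is touched; tails beyond that carry < 1e-6 of the
    mass.
    """
    if sigma_lat_nm <= 0 or sigma_ax_nm <= 0:
        raise ValueError("spot sigma must be > 0")
    if amplitude == 0:
        return
    dz, dy, dx = voxel_size
    czn, cyn, cxn = center_nm
    sig = np.array([sigma_ax_nm, sigma_lat_nm, sigma_lat_nm])
    halfw = 5.0 * sig / np.array([dz, dy, dx])
    cvox = np.array([czn / dz, cyn / dy, cxn / dx])
    lo = np.maximum(np.floor(cvox - halfw).astype(int), 0)
    hi = np.minimum(np.ceil(cvox + halfw).astype(int) + 1, field.shape)
    if np.any(lo >= hi):
        return
    zz = (np.arange(lo[0], hi[0]) * dz - czn) / sigma_ax_nm
    yy = (np.arange(lo[1], hi[1]) * dy - cyn) / sigma_lat_nm
    xx = (np.arange(lo[2], hi[2]) * dx - cxn) / sigma_lat_nm
    g = np.exp(-0.5 * zz[:, None, None] ** 2) * np.exp(-0.5 * yy[None, :, None] ** 2) * np.exp(
        -0.5 * xx[None, None, :] ** 2
    )
    field[lo[0]: hi[0], lo[1]: hi[1], lo[2]: hi[2]] += amplitude * g


def render_spot(
    stack: VoxelStack,
    center_nm: Sequence[float],
    amplitude: float,
    sigma_lat_nm: float,
    sigma_ax_nm: float,
) -> VoxelStack:
    """Return a copy of ``stack`` with one Gaussian focus added.

    ``center_nm`` is ``(z, y, x)`` in nm.  The focus is an anisotropic 3D
    Gaussian evaluated at voxel centers; the total added signal before
    clipping is approximately
    ``amplitude * (2*pi)**1.5 * sigma_lat**2 * sigma_ax / (dx*dy*dz)``.
    """
    dz, dy, dx = stack.voxel_size
    nz, ny, nx = stack.shape
    czn, cyn, cxn = center_nm
    if not (0 <= czn <= (nz - 1) * dz and 0 <= cyn <= (ny - 1) * dy and 0 <= cxn <= (nx - 1) * dx):
        raise ValueError(f"center {tuple(center_nm)} nm outside stack bounds")
    fld = stack.intensities.astype(np.float64)
    _add_gaussian(fld, stack.voxel_size, center_nm, amplitude, sigma_lat_nm, sigma_ax_nm)
    out = np.clip(np.rint(fld), 0, DTYPE_MAX).astype(stack.intensities.dtype)
    return VoxelStack(out, stack.voxel_size, stack.channel_name)


def apply_noise(stack: VoxelStack, noise: NoiseModel, rng_seed: int) -> VoxelStack:
    """Resample a stack of expected counts through the detection-noise model.

    Poisson shot noise (if enabled) treats each voxel value as the expected
    photon count; Gaussian read noise of ``read_sd`` counts and a constant
    ``offset`` are then added, and the result is rounded and clipped to the
    stack dtype.  Identity when the model is fully disabled.
    """
    if noise.read_sd < 0:
        raise ValueError("read_sd must be >= 0")
    if not noise.poisson and noise.read_sd == 0 and noise.offset == 0:
        return VoxelStack(stack.intensities.copy(), stack.voxel_size, stack.channel_name)
    rng = _stream(rng_seed, _STAGE_NOISE, stack.channel_name)
    vals = stack.intensities.astype(np.float64)
    if noise.poisson:
        vals = rng.poisson(vals).astype(np.float64)
    if noise.read_sd > 0:
        vals = vals + rng.normal(0.0, noise.read_sd, size=vals.shape)
    vals = vals + noise.offset
    dtype = stack.intensities.dtype if np.issubdtype(stack.intensities.dtype, np.integer) else DTYPE
    info_max = np.iinfo(dtype).max
    clipped = np.clip(np.rint(vals), 0, info_max)
    n_clip = int(np.count_nonzero(np.rint(vals) > info_max))
    if n_clip:
        logger.warning("apply_noise: %d voxels clipped at dtype max", n_clip)
    return VoxelStack(clipped.astype(dtype), stack.voxel_size, stack.channel_name)


def expected_snr(config: SimulationConfig) -> float:
    """Analytic SNR of a focus under the configured noise model.

    With Poisson noise the background standard deviation at a mean of ``b``
    counts is ``sqrt(b + read_sd**2)``; without it only the Gaussian read
    noise contributes.  Used as the oracle curve when validating the
    estimator, never inside the estimator itself.
    """
    bg_mean = config.nuclear_background[0]
    if config.noise.poisson:
        denom = float(np.sqrt(bg_mean + config.noise.read_sd**2))
    else:
        denom = float(config.noise.read_sd)
    if denom <= 0:
        raise ValueError("SNR undefined: background variance is zero with noise disabled")
    return float(config.spot_amplitude) / denom


# ---------------------------------------------------------------------------
# field generation


def generate_field(config: SimulationConfig) -> tuple[dict, GroundTruth]:
    """Simulate one multi-channel field.

    Returns ``(stacks, truth)`` where ``stacks`` maps channel name to
    :class:`VoxelStack`.  Per FP channel each nucleus carries a focus with
    the channel's labeling probability; a labeled nucleus additionally
    carries a second same-channel focus (sister-chromatid doublet) with
    ``doublet_probability``.  In dual-label mode a labeled nucleus carries
    one green and one red focus separated by a draw from
    ``pair_separation_nm``, and the true separation is recorded.  A channel
    named ``"dapi"`` renders the filled nuclei.  Deterministic for a fixed
    ``rng_seed``.
    """
    rng_place = _stream(config.rng_seed, _STAGE_PLACEMENT)
    nuclei = _place_nuclei(config, rng_place)
    truth = GroundTruth(nuclei=list(nuclei))

    nz, ny, nx = config.stack_dims
    dz, dy, dx = config.voxel_size
    lo, hi = _spot_bounds(config)
    fp_channels = [c for c in config.channels if c != "dapi"]
    p_by_channel = config._p_by_channel()

    # expected-count fields per channel
    fields = {c: np.full(config.stack_dims, float(config.cytoplasm_background)) for c in fp_channels}
    if "dapi" in config.channels:
        fields["dapi"] = np.full(config.stack_dims, float(config.cytoplasm_background))

    # diffuse nuclear background (FP pool) and DAPI fill
    bg_rng = _stream(config.rng_seed, _STAGE_LABELS, "background")
    for nuc in nuclei:
        box, inside = _sphere_mask(nuc, config.stack_dims, config.voxel_size)
        level = max(0.0, bg_rng.normal(*config.nuclear_background))
        for c in fp_channels:
            np.maximum(fields[c][box], np.where(inside, level, 0.0), out=fields[c][box])
        if "dapi" in fields:
            np.maximum(
                fields["dapi"][box], np.where(inside, config.dapi_intensity, 0.0), out=fields["dapi"][box]
            )

    # spot placement
    if config.dual_label:
        if len(fp_channels) < 2:
            raise ValueError("dual_label mode needs two FP channels")
        ch_a, ch_b = fp_channels[0], fp_channels[1]
        rng_lab = _stream(config.rng_seed, _STAGE_LABELS, ch_a + "+" + ch_b)
        rng_spot = _stream(config.rng_seed, _STAGE_SPOTS, ch_a + "+" + ch_b)
        p = p_by_channel[ch_a]
        for nuc in nuclei:
            if rng_lab.uniform() >= p:
                continue
            a = _sample_point_in_nucleus(nuc, lo, hi, rng_spot)
            sep = _draw_separation(config.pair_separation_nm, rng_spot)
            b = _sample_partner(a, sep, nuc, lo, hi, rng_spot)
            if b is None:
                logger.warning("nucleus %d: could not place pair at %.0f nm; skipped", nuc.id, sep)
                continue
            for ch, pos in ((ch_a, a), (ch_b, b)):
                truth.spots.append(SpotTruth(nuc.id, ch, tuple(pos), config.spot_amplitude))
                _add_gaussian(
                    fields[ch], config.voxel_size, pos, config.spot_amplitude,
                    config.spot_sigma_lateral_nm, config.spot_sigma_axial_nm,
                )
            truth.true_pair_distances.append((nuc.id, float(np.linalg.norm(a - b))))
            # sister-chromatid doublets per channel
            for ch, pos in ((ch_a, a), (ch_b, b)):
                if rng_spot.uniform() < config.doublet_probability:
                    d2 = _sample_partner(pos, config.doublet_separation_nm, nuc, lo, hi, rng_spot, lateral_only=True)
                    if d2 is not None:
                        truth.spots.append(
                            SpotTruth(nuc.id, ch, tuple(d2), config.spot_amplitude, is_doublet_member=True)
                        )
                        _add_gaussian(
                            fields[ch], config.voxel_size, d2, config.spot_amplitude,
                            config.spot_sigma_lateral_nm, config.spot_sigma_axial_nm,
                        )
    else:
        for ch in fp_channels:
            rng_lab = _stream(config.rng_seed, _STAGE_LABELS, ch)
            rng_spot = _stream(config.rng_seed, _STAGE_SPOTS, ch)
            p = p_by_channel[ch]
            for nuc in nuclei:
                if rng_lab.uniform() >= p:
                    continue
                pos = _sample_point_in_nucleus(nuc, lo, hi, rng_spot)
                doublet = rng_spot.uniform() < config.doublet_probability
                members = [pos]
                if doublet:
                    d2 = _sample_partner(pos, config.doublet_separation_nm, nuc, lo, hi, rng_spot, lateral_only=True)
                    if d2 is not None:
                        members.append(d2)
                    else:
                        doublet = False
                for m in members:
                    truth.spots.append(
                        SpotTruth(nuc.id, ch, tuple(m), config.spot_amplitude, is_doublet_member=doublet)
                    )
                    _add_gaussian(
                        fields[ch], config.voxel_size, m, config.spot_amplitude,
                        config.spot_sigma_lateral_nm, config.spot_sigma_axial_nm,
                    )

    stacks = {}
    for ch, fld in fields.items():
        expected = VoxelStack(
            np.clip(np.rint(fld), 0, DTYPE_MAX).astype(DTYPE)
            if not _noise_enabled(config.noise)
            else fld,
            config.voxel_size,
            ch,
        )
        stacks[ch] = apply_noise(expected, config.noise, config.rng_seed)
    return stacks, truth


def _noise_enabled(noise: NoiseModel) -> bool:
    return noise.poisson or noise.read_sd > 0 or noise.offset != 0


def nucleus_label_stack(truth: GroundTruth, config: SimulationConfig) -> VoxelStack:
    """Render the ground-truth nuclei as a 3D label image (label = id + 1)."""
    labels = np.zeros(config.stack_dims, dtype=np.uint16)
    for nuc in truth.nuclei:
        box, inside = _sphere_mask(nuc, config.stack_dims, config.voxel_size)
        labels[box][inside] = nuc.id + 1
    return VoxelStack(labels, config.voxel_size, "labels")
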