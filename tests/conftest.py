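"""Shared fixtures: small synthetic fields with ground truth."""

from __future__ import annotations

import numpy as np
import pytest

import locusfoci as lf


def true_voxel_positions(truth, config, channel=None):
    """Ground-truth spot centers in (z, y, x) voxel units."""
    spots = truth.spots if channel is None else truth.spots_in_channel(channel)
    return np.array(
        [[c / v for c, v in zip(s.center_nm, config.voxel_size)] for s in spots]
    ).reshape(-1, 3)


def seeds_from_truth(truth, config, channel="green"):
    """Seeds at the rounded true spot positions (emulates manual picking)."""
    out = []
    for s in truth.spots_in_channel(channel):
        z, y, x = [int(round(c / v)) for c, v in zip(s.center_nm, config.voxel_size)]
        out.append(lf.SpotSeed(channel=channel, z=z, y=y, x=x))
    return out


@pytest.fixture(scope="session")
def small_field():
    """One deterministic single-channel field with DAPI: 6 labeled nuclei."""
    config = lf.SimulationConfig(n_nuclei=6, rng_seed=3, channels=("green", "dapi"))
    stacks, truth = lf.generate_field(config)
    return config, stacks, truth


@pytest.fixture(scope="session")
def dual_field():
    """One deterministic dual-label field, fixed 400 nm pair separation."""
    config = lf.SimulationConfig(
        n_nuclei=6,
        rng_seed=5,
        channels=("green", "red"),
        dual_label=True,
        pair_separation_nm=400.0,
    )
    stacks, truth = lf.generate_field(config)
    return config, stacks, truth
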