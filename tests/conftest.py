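"""Shared fixtures: digitized spheres and a small precomputed study."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import radstab as rs
from radstab.stability_pipeline import run_study


@pytest.fixture(scope="session")
def sphere_10mm():
    """Noise-free 10 mm solid sphere on a 1 mm grid: (volume, mask)."""
    spec = rs.PhantomSpec(
        nodule_type="SN", diameter_mm=10, center_mm=(31.5, 31.5, 15.5), noise_sd_hu=0
    )
    return rs.generate_phantom(spec)


@pytest.fixture(scope="session")
def noisy_sphere_10mm():
    """10 mm solid sphere with CT-like noise: (volume, mask)."""
    spec = rs.PhantomSpec(
        nodule_type="SN", diameter_mm=10, center_mm=(31.5, 31.5, 15.5),
        noise_sd_hu=20, seed=5,
    )
    return rs.generate_phantom(spec)


def random_roi(rng, shape=None, n_levels=4, density=0.7, spacing=(1, 1, 1)):
    """A random discretizable ROI: (VolumeGrid, MaskVolume)."""
    if shape is None:
        shape = tuple(rng.integers(3, 8, size=3))
    vals = rng.integers(0, n_levels, size=shape).astype(float) * 25.0
    mask = rng.random(shape) < density
    if mask.sum() < 2:
        mask[tuple(np.unravel_index([0, 1], shape))] = True
    return (
        rs.VolumeGrid(vals, spacing, (0, 0, 0)),
        rs.MaskVolume(mask, spacing, (0, 0, 0)),
    )


@pytest.fixture(scope="session")
def small_study():
    """A 10-nodule x 4-observer study on 32-cubed grids, fixed-jitter panel.

    Small enough to run in ~20 s, reused by the pipeline-level tests.
    """
    profiles = [
        rs.ObserverProfile(name="A"),
        rs.ObserverProfile(name="B", jitter_mm=0.5, seed=11),
        rs.ObserverProfile(name="C", jitter_mm=0.9, seed=12),
        rs.ObserverProfile(name="D", jitter_mm=1.3, seed=13),
    ]
    design = rs.StudyDesign(
        n_nodules=10,
        observer_profiles=profiles,
        grid_shape=(32, 32, 32),
        master_seed=424242,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_study(design)
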