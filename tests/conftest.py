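"""Shared fixtures: digital shapes and a small trained pipeline."""

from __future__ import annotations

import numpy as np
import pytest

from agita.core_io import Calibration
from agita.descriptors import BinaryObject
from agita.synth import SimulationConfig, generate_series
from agita.train import build_training_set, train_model


@pytest.fixture(scope="session")
def unit_cal() -> Calibration:
    return Calibration(dx=1.0, dy=1.0, dz=1.0)


@pytest.fixture(scope="session")
def aniso_cal() -> Calibration:
    return Calibration(dx=0.25, dy=0.25, dz=0.5)


def digital_ellipsoid_mask(
    semi_axes_vox: tuple[float, float, float],
    rotation: np.ndarray | None = None,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Rasterise a (rotated) solid ellipsoid; semi-axes in µm over the
    given voxel spacing (defaults to voxel units)."""
    semi = np.asarray(semi_axes_vox, dtype=float)
    sp = np.asarray(spacing)
    extent = np.ceil(semi.max() / sp).astype(int) + 2
    axes_coords = [np.arange(-e, e + 1) * s for e, s in zip(extent, sp)]
    grid = np.stack(np.meshgrid(*axes_coords, indexing="ij"), axis=-1)
    if rotation is not None:
        grid = grid @ rotation
    return ((grid / semi) ** 2).sum(axis=-1) <= 1.0


def digital_ball_mask(radius_vox: float) -> np.ndarray:
    return digital_ellipsoid_mask((radius_vox,) * 3)


def ball_object(radius_vox: float, cal: Calibration) -> BinaryObject:
    return BinaryObject(mask=digital_ball_mask(radius_vox), calibration=cal)


def rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


SMALL_SIM = SimulationConfig(
    shape=(48, 140, 140),
    n_frames=4,
    n_cells=8,
    n_divisions=1,
    seed=11,
)


@pytest.fixture(scope="session")
def small_sim():
    """A 4-frame, 8-cell synthetic series with ground truth and clicks."""
    return generate_series(SMALL_SIM)


@pytest.fixture(scope="session")
def small_samples(small_sim):
    series, _gt, clicks, schedule = small_sim
    return build_training_set(series, clicks, schedule, t_step=3)


@pytest.fixture(scope="session")
def small_model(small_sim, small_samples):
    """Phase classifier trained on the small series' click table."""
    _series, _gt, _clicks, schedule = small_sim
    return train_model(small_samples, schedule, seed=3)
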