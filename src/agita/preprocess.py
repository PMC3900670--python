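"""Adaptive 3D median filtering.

The filter radius tracks the expected nucleus size: per-class nucleus
volume intervals are supplied at the first and last time points and
linearly interpolated in between; the filter radius is the radius of the
sphere of equivalent volume, capped so that early large nuclei do not
force an excessively large (and slow) neighbourhood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import ndimage

from agita.core_io import ImageStack

__all__ = [
    "VolumeSchedule",
    "interpolate_volume",
    "equivalent_radius",
    "ellipsoid_footprint",
    "adaptive_median_filter",
    "DEFAULT_MAX_RADIUS_VOX",
]

log = logging.getLogger(__name__)

#: Cap on the in-plane filter radius, in voxels.
DEFAULT_MAX_RADIUS_VOX = 12


@dataclass(frozen=True)
class ClassVolumes:
    """Volume interval (µm³) of one phase at the start and end of the series."""

    v_min_start: float
    v_max_start: float
    v_min_end: float
    v_max_end: float

    def __post_init__(self) -> None:
        for lo, hi in ((self.v_min_start, self.v_max_start),
                       (self.v_min_end, self.v_max_end)):
            if not (0 < lo <= hi):
                raise ValueError(f"invalid volume interval ({lo}, {hi})")


@dataclass(frozen=True)
class VolumeSchedule:
    """Per-class nucleus volume intervals, linearly interpolated over time."""

    classes: Mapping[str, ClassVolumes]
    t_start: int
    t_end: int

    def __post_init__(self) -> None:
        if self.t_start >= self.t_end:
            raise ValueError("t_start must precede t_end")
        if not self.classes:
            raise ValueError("schedule needs at least one class")

    @property
    def class_names(self) -> list[str]:
        return list(self.classes)


def interpolate_volume(
    schedule: VolumeSchedule, class_name: str, t: int | float
) -> tuple[float, float]:
    """Volume interval of ``class_name`` at time ``t``.

    Each bound is interpolated linearly between its start and end values;
    time points outside the schedule are clamped to the nearest endpoint
    (with a warning), so a model trained on a sub-series can still be
    applied to neighbouring frames.
    """
    cv = schedule.classes[class_name]
    if t < schedule.t_start or t > schedule.t_end:
        log.warning(
            "time %s outside schedule [%d, %d]; clamping",
            t, schedule.t_start, schedule.t_end,
        )
        t = min(max(t, schedule.t_start), schedule.t_end)
    f = (t - schedule.t_start) / (schedule.t_end - schedule.t_start)
    v_min = cv.v_min_start + f * (cv.v_min_end - cv.v_min_start)
    v_max = cv.v_max_start + f * (cv.v_max_end - cv.v_max_start)
    return (v_min, v_max)


def equivalent_radius(v: float) -> float:
    """Radius (µm) of the sphere with volume ``v`` µm³: R = (3V/4π)^(1/3)."""
    if v <= 0:
        raise ValueError(f"volume must be positive, got {v}")
    return (3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0)


def ellipsoid_footprint(r_z: int, r_y: int, r_x: int) -> np.ndarray:
    """Boolean discrete ellipsoid with the given semi-axes in voxels."""
    zz, yy, xx = np.ogrid[-r_z:r_z + 1, -r_y:r_y + 1, -r_x:r_x + 1]
    return (zz / max(r_z, 1e-12)) ** 2 + (yy / max(r_y, 1e-12)) ** 2 \
        + (xx / max(r_x, 1e-12)) ** 2 <= 1.0


def filter_radii_vox(
    stack: ImageStack,
    t: int,
    schedule: VolumeSchedule,
    max_radius_vox: int = DEFAULT_MAX_RADIUS_VOX,
) -> tuple[int, int]:
    """In-plane and axial filter radii (voxels) for time point ``t``.

    The reference volume is the mean over classes of the midpoints of the
    interpolated intervals — a single scalar that tracks how nucleus size
    shrinks over development. The axial radius rescales the in-plane one
    by the calibration ratio so the neighbourhood is physically isotropic.
    """
    mids = [
        (lo + hi) / 2.0
        for lo, hi in (
            interpolate_volume(schedule, name, t) for name in schedule.class_names
        )
    ]
    v_bar = float(np.mean(mids))
    cal = stack.calibration
    r_um = equivalent_radius(v_bar)
    r_xy = int(min(max_radius_vox, max(1, round(r_um / cal.dx))))
    r_z = int(max(1, round(r_xy * cal.dx / cal.dz)))
    return r_xy, r_z


def adaptive_median_filter(
    stack: ImageStack,
    t: int,
    schedule: VolumeSchedule,
    max_radius_vox: int = DEFAULT_MAX_RADIUS_VOX,
) -> ImageStack:
    """Median-filter a stack over an ellipsoidal, calibration-aware window.

    Reflect padding at the borders avoids dark rims that would bias the
    subsequent threshold sweep low. Output has the same shape and dtype.
    """
    r_xy, r_z = filter_radii_vox(stack, t, schedule, max_radius_vox)
    footprint = ellipsoid_footprint(r_z, r_xy, r_xy)
    out = ndimage.median_filter(stack.data, footprint=footprint, mode="reflect")
    return ImageStack(data=out.astype(stack.data.dtype), calibration=stack.calibration)
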