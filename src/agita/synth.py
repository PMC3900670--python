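"""Synthetic 4D embryo generator with instance and phase ground truth.

The simulator emulates the statistical structure the segmentation
algorithm assumes — each nucleus is segmentable by a single threshold and
has a phase-specific shape — rather than any particular microscope:

* interphase: a sphere;
* prophase: a larger, lumpy sphere (surface bumps) with brighter interior
  blobs standing in for condensed chromatin;
* metaphase: a flattened ellipsoid (metaphase plate), flatness >> 1;
* anaphase: two strongly prolate ellipsoids separating along an in-plane
  axis, with a clear background gap between them;
* telophase: two mildly prolate daughter nuclei, further apart.

Anaphase and telophase figures are rendered as *two* ground-truth
instances, since each chromatin mass is a separately detectable object.
Fluorescence decays by a constant factor per frame (mimicking dilution of
a maternal histone-GFP pool over divisions), nuclei shrink slowly, and
noise is signal-dependent (variance proportional to intensity) plus an
additive read-noise floor, optionally ramped with depth.

Every run emits, besides the image series and ground truth, a ready-made
click table (one validated click per instance) and the matching volume
schedule, so a classifier can be trained and evaluated with no manual
input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from agita.core_io import Calibration, ClickTable, ImageStack, TimeSeries
from agita.descriptors import BinaryObject
from agita.preprocess import ClassVolumes, VolumeSchedule

__all__ = [
    "PhaseShapeParams",
    "SimulationConfig",
    "GroundTruth",
    "RenderedNucleus",
    "render_nucleus",
    "generate_series",
    "PHASES",
    "DEFAULT_PHASE_SHAPES",
]

PHASES = ("interphase", "prophase", "metaphase", "anaphase", "telophase")

#: Frames spent in each phase of the cycle.
DEFAULT_PHASE_DURATIONS = {
    "interphase": 5, "prophase": 1, "metaphase": 1, "anaphase": 1, "telophase": 1,
}


@dataclass(frozen=True)
class PhaseShapeParams:
    """Geometry of one phase's rendered figure (all lengths in µm).

    ``kind`` selects the renderer: a plain ``sphere``, a ``lumpy`` sphere
    with surface bumps and bright interior blobs, a single ``ellipsoid``,
    or a ``pair`` of ellipsoids whose centres sit at ``±offset_um`` along
    a common in-plane axis.
    """

    kind: str
    semi_axes: tuple[float, float, float]
    jitter_sd: float = 0.04
    offset_um: float = 0.0
    n_bumps: int = 0
    bump_radius_um: float = 0.0
    n_blobs: int = 0
    blob_radius_um: float = 0.0
    blob_gain: float = 1.0


DEFAULT_PHASE_SHAPES: dict[str, PhaseShapeParams] = {
    "interphase": PhaseShapeParams(kind="sphere", semi_axes=(2.0, 2.0, 2.0)),
    "prophase": PhaseShapeParams(
        kind="lumpy", semi_axes=(2.3, 2.3, 2.3),
        n_bumps=5, bump_radius_um=0.8,
        n_blobs=3, blob_radius_um=0.55, blob_gain=1.18,
    ),
    "metaphase": PhaseShapeParams(kind="ellipsoid", semi_axes=(2.2, 1.9, 0.75)),
    "anaphase": PhaseShapeParams(
        kind="pair", semi_axes=(1.6, 0.8, 0.75), offset_um=2.0,
    ),
    "telophase": PhaseShapeParams(
        kind="pair", semi_axes=(1.5, 1.05, 1.0), offset_um=2.0,
    ),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic series.

    Defaults describe a small clean dividing-embryo sequence: 10 frames,
    22 mother cells (about 25–27 visible nuclei per frame once anaphase
    and telophase figures split in two), 2% fluorescence decay per frame
    and low, signal-dependent noise on an 8-bit range.
    """

    shape: tuple[int, int, int] = (48, 200, 200)  # (z, y, x) voxels
    calibration: Calibration = field(
        default_factory=lambda: Calibration(dx=0.25, dy=0.25, dz=0.5)
    )
    n_frames: int = 10
    n_cells: int = 22
    n_divisions: int = 2
    decay: float = 0.98          # fluorescence factor per frame
    size_decay: float = 0.99     # nucleus radius factor per frame
    fg_range: tuple[float, float] = (140.0, 190.0)
    background: float = 12.0
    noise_read: float = 1.5      # additive noise sd (grey levels)
    noise_gain: float = 0.02     # signal-dependent variance per grey level
    depth_noise_ramp: float = 0.0  # extra relative noise at the deepest slice
    min_dist_um: float = 8.2
    margin_xy_um: float = 5.4
    margin_z_um: float = 3.4
    seed: int = 42
    phase_durations: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PHASE_DURATIONS)
    )
    phase_shapes: dict[str, PhaseShapeParams] = field(
        default_factory=lambda: dict(DEFAULT_PHASE_SHAPES)
    )

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.n_cells < 1:
            raise ValueError("need at least one frame and one cell")
        if set(self.phase_durations) != set(PHASES):
            raise ValueError(f"phase_durations must cover {PHASES}")

    @property
    def cycle_length(self) -> int:
        return sum(self.phase_durations.values())


@dataclass
class GroundTruth:
    """Per-frame instance labels and the matching instance table.

    ``tables[t]`` has one row per instance with columns
    ``id, cell, phase, x, y, z, volume_um3`` (voxel-centre coordinates).
    """

    labels: list[np.ndarray]
    tables: list[pd.DataFrame]

    def n_instances(self, t: int) -> int:
        return len(self.tables[t])


@dataclass
class RenderedNucleus:
    """One rendered figure in a local crop centred on the nominal position.

    ``instance`` assigns each foreground voxel a part index (1, or 1/2 for
    pairs); ``texture`` is a multiplicative intensity map (1 outside
    bright blobs). ``origin_vox`` is the crop's voxel offset relative to
    the centre voxel the figure is pasted at.
    """

    instance: np.ndarray
    texture: np.ndarray
    origin_vox: tuple[int, int, int]

    @property
    def mask(self) -> np.ndarray:
        return self.instance > 0

    def part_objects(self, calibration: Calibration) -> list[BinaryObject]:
        return [
            BinaryObject(mask=self.instance == k, calibration=calibration)
            for k in range(1, int(self.instance.max()) + 1)
        ]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalised quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _rotation_about_z(angle: float) -> np.ndarray:
    """Rotation about the optical (z) axis, in (z, y, x) coordinates."""
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _ellipsoid_inside(
    grid_um: np.ndarray,
    center_um: np.ndarray,
    semi_axes: np.ndarray,
    rot: np.ndarray,
) -> np.ndarray:
    """Boolean inside-test of a rotated ellipsoid on a (z,y,x,3) µm grid."""
    rel = grid_um - center_um
    local = rel @ rot  # == rot.T applied to each row vector
    return ((local / semi_axes) ** 2).sum(axis=-1) <= 1.0


def render_nucleus(
    phase: str,
    params: PhaseShapeParams,
    rng: np.random.Generator,
    calibration: Calibration,
    scale: float = 1.0,
) -> RenderedNucleus:
    """Rasterise one phase figure at a random orientation.

    ``scale`` multiplies all lengths (used for the slow shrink of nuclei
    over developmental time). Pair phases produce two labelled parts.
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    spacing = np.asarray(calibration.spacing_zyx)
    jitter = float(np.clip(rng.normal(1.0, params.jitter_sd), 0.85, 1.15))
    axes = np.asarray(params.semi_axes) * scale * jitter
    offset = params.offset_um * scale * jitter
    bump_r = params.bump_radius_um * scale

    extent = float(axes.max() + offset + bump_r + 1.0)
    half = np.maximum(1, np.ceil(extent / spacing).astype(int))
    zc = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing)]
    grid = np.stack(np.meshgrid(*zc, indexing="ij"), axis=-1)

    texture = np.ones(grid.shape[:-1], dtype=np.float32)
    instance = np.zeros(grid.shape[:-1], dtype=np.uint8)

    if params.kind in ("sphere", "ellipsoid", "lumpy"):
        rot = _random_rotation(rng)
        body = _ellipsoid_inside(grid, np.zeros(3), axes, rot)
        if params.kind == "lumpy":
            r = axes[0]
            for _ in range(params.n_bumps):
                d = rng.normal(size=3)
                d /= np.linalg.norm(d)
                body |= _ellipsoid_inside(
                    grid, d * r, np.full(3, bump_r), np.eye(3)
                )
            for _ in range(params.n_blobs):
                d = rng.normal(size=3)
                d /= np.linalg.norm(d)
                blob = _ellipsoid_inside(
                    grid, d * 0.5 * r,
                    np.full(3, params.blob_radius_um * scale), np.eye(3),
                )
                texture[blob] = params.blob_gain
        instance[body] = 1
    elif params.kind == "pair":
        # separation axis kept in the image plane so the inter-part gap is
        # wide in the finely sampled xy directions
        angle = rng.uniform(0.0, 2.0 * np.pi)
        rot = _rotation_about_z(angle)
        axis = rot @ np.array([0.0, 0.0, 1.0])  # long (x) axis rotated in-plane
        for k, sign in ((1, 1.0), (2, -1.0)):
            part = _ellipsoid_inside(grid, sign * offset * axis, axes[::-1], rot)
            instance[part] = k
        if not (instance == 1).any() or not (instance == 2).any():
            raise RuntimeError(f"{phase}: a pair part rasterised to nothing")
    else:
        raise ValueError(f"unknown shape kind {params.kind!r}")

    if not instance.any():
        raise RuntimeError(f"{phase}: figure rasterised to nothing")
    return RenderedNucleus(
        instance=instance,
        texture=texture,
        origin_vox=tuple(int(-h) for h in half),
    )


@dataclass
class _Cell:
    cell_id: int
    center_um: np.ndarray  # (z, y, x)
    birth_t: int
    phase_offset: int
    intensity: float


def _phase_at(cfg: SimulationConfig, cell: _Cell, t: int) -> str:
    idx = (t - cell.birth_t + cell.phase_offset) % cfg.cycle_length
    acc = 0
    for phase in PHASES:
        acc += cfg.phase_durations[phase]
        if idx < acc:
            return phase
    raise AssertionError("unreachable")


def _place_centers(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample cell centres with a minimum pairwise distance."""
    nz, ny, nx = cfg.shape
    spacing = np.asarray(cfg.calibration.spacing_zyx)
    hi = (np.array([nz, ny, nx]) - 1) * spacing
    lo = np.array([cfg.margin_z_um, cfg.margin_xy_um, cfg.margin_xy_um])
    hi = hi - lo
    if (hi <= lo).any():
        raise ValueError("image too small for the configured margins")
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < cfg.n_cells:
        attempts += 1
        if attempts > 20000:
            raise RuntimeError(
                f"could not place {cfg.n_cells} cells at min distance "
                f"{cfg.min_dist_um} µm; reduce crowding"
            )
        c = rng.uniform(lo, hi)
        if all(np.linalg.norm(c - o) >= cfg.min_dist_um for o in centers):
            centers.append(c)
    return np.asarray(centers)


def _division_times(cfg: SimulationConfig) -> dict[int, int]:
    """Pick the first ``n_divisions`` cells whose telophase completes
    strictly inside the series; they divide on the following frame."""
    out: dict[int, int] = {}
    for cid in range(cfg.n_cells):
        if len(out) >= cfg.n_divisions:
            break
        offset = _default_offset(cfg, cid)
        for t in range(cfg.n_frames - 1):
            idx = (t + offset) % cfg.cycle_length
            if idx == cfg.cycle_length - 1:  # last telophase frame
                out[cid] = t + 1
                break
    return out


def _default_offset(cfg: SimulationConfig, cell_id: int) -> int:
    return (cell_id * cfg.cycle_length) // cfg.n_cells


def generate_series(
    cfg: SimulationConfig,
) -> tuple[TimeSeries, GroundTruth, ClickTable, VolumeSchedule]:
    """Simulate a 4D sequence with ground truth, clicks and volume schedule.

    All randomness flows from ``cfg.seed``. The returned schedule brackets
    the realised per-phase volumes with a ±~25% margin and follows the
    configured shrink rate between the first and last frame.
    """
    rng = np.random.default_rng(cfg.seed)
    cal = cfg.calibration
    spacing = np.asarray(cal.spacing_zyx)
    centers = _place_centers(cfg, rng)
    divisions = _division_times(cfg)

    cells = [
        _Cell(
            cell_id=i,
            center_um=centers[i],
            birth_t=0,
            phase_offset=_default_offset(cfg, i),
            intensity=float(rng.uniform(*cfg.fg_range)),
        )
        for i in range(cfg.n_cells)
    ]
    next_cell_id = cfg.n_cells

    frames: list[ImageStack] = []
    gt_labels: list[np.ndarray] = []
    gt_tables: list[pd.DataFrame] = []
    click_rows: list[dict] = []
    volumes_by_phase: dict[str, list[tuple[int, float]]] = {p: [] for p in PHASES}

    for t in range(cfg.n_frames):
        image = np.full(cfg.shape, cfg.background, dtype=np.float64)
        labels = np.zeros(cfg.shape, dtype=np.uint16)
        rows: list[dict] = []
        scale = cfg.size_decay ** t
        decay = cfg.decay ** t
        pending_divisions: list[tuple[_Cell, np.ndarray, np.ndarray]] = []

        for cell in list(cells):
            phase = _phase_at(cfg, cell, t)
            rendered = render_nucleus(
                phase, cfg.phase_shapes[phase], rng, cal, scale=scale
            )
            center_vox = np.round(cell.center_um / spacing).astype(int)
            start = center_vox + np.asarray(rendered.origin_vox)
            stop = start + np.asarray(rendered.instance.shape)
            # the local crop carries padding; clip it, but refuse to clip
            # any actual foreground voxel
            lo_clip = np.maximum(0, -start)
            hi_clip = np.maximum(0, stop - np.asarray(cfg.shape))
            inner = tuple(
                slice(int(a), int(s - b))
                for a, b, s in zip(lo_clip, hi_clip, rendered.instance.shape)
            )
            if (rendered.instance[inner] > 0).sum() != rendered.mask.sum():
                raise RuntimeError(
                    f"cell {cell.cell_id} at t={t} exceeds image bounds; "
                    "increase margins or image size"
                )
            rendered = RenderedNucleus(
                instance=rendered.instance[inner],
                texture=rendered.texture[inner],
                origin_vox=tuple(int(v) for v in
                                 (np.asarray(rendered.origin_vox) + lo_clip)),
            )
            start = start + lo_clip
            stop = stop - hi_clip
            sl = tuple(slice(int(a), int(b)) for a, b in zip(start, stop))
            fg = rendered.mask
            image[sl][fg] = cfg.background + cell.intensity * decay \
                * rendered.texture[fg]

            part_centroids = []
            n_parts = int(rendered.instance.max())
            for part in range(1, n_parts + 1):
                pmask = rendered.instance == part
                inst_id = len(rows) + 1
                labels[sl][pmask] = inst_id
                coords = np.argwhere(pmask) + start
                centroid = coords.mean(axis=0)
                click = np.round(centroid).astype(int)
                if not pmask[tuple(click - start)]:
                    d2 = ((coords - centroid) ** 2).sum(axis=1)
                    click = coords[int(np.argmin(d2))]
                volume = float(pmask.sum()) * cal.voxel_volume
                rows.append({
                    "id": inst_id, "cell": cell.cell_id, "phase": phase,
                    "x": int(click[2]), "y": int(click[1]), "z": int(click[0]),
                    "volume_um3": volume,
                })
                click_rows.append({
                    "t": t, "x": int(click[2]), "y": int(click[1]),
                    "z": int(click[0]), "class": phase, "validated": True,
                })
                volumes_by_phase[phase].append((t, volume))
                part_centroids.append(centroid * spacing)

            if (
                phase == "telophase"
                and divisions.get(cell.cell_id) == t + 1
                and len(part_centroids) == 2
            ):
                pending_divisions.append(
                    (cell, part_centroids[0], part_centroids[1])
                )

        for cell, c1, c2 in pending_divisions:
            cells.remove(cell)
            # daughters move into separate cells: keep the telophase axis
            # but space the two interphase nuclei so a background gap
            # separates them at their largest possible size
            direction = np.asarray(c1) - np.asarray(c2)
            direction /= np.linalg.norm(direction)
            r_daughter = max(cfg.phase_shapes["interphase"].semi_axes) * 1.15
            half_sep = r_daughter + 0.6
            for sign in (1.0, -1.0):
                cells.append(
                    _Cell(
                        cell_id=next_cell_id,
                        center_um=cell.center_um + sign * half_sep * direction,
                        birth_t=t + 1,
                        phase_offset=0,
                        intensity=cell.intensity,
                    )
                )
                next_cell_id += 1

        sigma = np.sqrt(cfg.noise_read ** 2 + cfg.noise_gain * image)
        if cfg.depth_noise_ramp > 0:
            ramp = 1.0 + cfg.depth_noise_ramp * (
                np.arange(cfg.shape[0]) / max(1, cfg.shape[0] - 1)
            )
            sigma = sigma * ramp[:, None, None]
        noisy = image + rng.normal(0.0, 1.0, size=image.shape) * sigma
        data = np.clip(np.round(noisy), 0, 255).astype(np.uint8)

        frames.append(ImageStack(data=data, calibration=cal))
        gt_labels.append(labels.astype(np.int64))
        gt_tables.append(
            pd.DataFrame(
                rows, columns=["id", "cell", "phase", "x", "y", "z", "volume_um3"]
            )
        )

    schedule = _schedule_from_volumes(cfg, volumes_by_phase)
    clicks = ClickTable(table=pd.DataFrame(click_rows))
    series = TimeSeries(frames=frames, t0=0)
    return series, GroundTruth(labels=gt_labels, tables=gt_tables), clicks, schedule


def _schedule_from_volumes(
    cfg: SimulationConfig,
    volumes_by_phase: dict[str, list[tuple[int, float]]],
    margin: float = 0.25,
) -> VolumeSchedule:
    """Bracket realised volumes, normalised to t=0, by ±margin."""
    shrink = cfg.size_decay ** 3  # volume factor per frame
    end_factor = shrink ** max(1, cfg.n_frames - 1)
    classes: dict[str, ClassVolumes] = {}
    for phase, vols in volumes_by_phase.items():
        if not vols:
            raise RuntimeError(f"phase {phase!r} never appeared in the simulation")
        at_t0 = [v / shrink ** t for t, v in vols]
        lo = min(at_t0) * (1.0 - margin)
        hi = max(at_t0) * (1.0 + margin)
        classes[phase] = ClassVolumes(
            v_min_start=lo, v_max_start=hi,
            v_min_end=lo * end_factor, v_max_end=hi * end_factor,
        )
    t_end = max(1, cfg.n_frames - 1)
    return VolumeSchedule(classes=classes, t_start=0, t_end=t_end)
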