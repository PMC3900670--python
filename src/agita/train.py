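"""Training of the cell-cycle phase classifier.

Training nuclei are extracted around user-supplied click positions by the
same iterative-thresholding logic used at segmentation time: the crop
around each click is thresholded at increasing levels until the component
nearest the box centre falls inside the phase's expected volume interval.
Shape descriptors of the validated samples feed a random forest; the
per-class descriptor min/max ranges double as a Boolean pre-classifier at
segmentation time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from agita.core_io import Calibration, ClickTable, ImageStack, TimeSeries
from agita.descriptors import (
    ALL_DESCRIPTOR_NAMES,
    DEFAULT_FEATURES,
    BinaryObject,
    DescriptorVector,
    describe,
)
from agita.preprocess import VolumeSchedule, equivalent_radius, interpolate_volume

__all__ = [
    "PhaseClass",
    "TrainingSample",
    "TrainedModel",
    "ExtractionError",
    "extract_sample",
    "default_box_vox",
    "build_training_set",
    "train_model",
    "evaluate_holdout",
    "save_model",
    "load_model",
]

log = logging.getLogger(__name__)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

MODEL_FORMAT_VERSION = 1


class ExtractionError(RuntimeError):
    """No threshold produced an object inside the expected volume interval."""


@dataclass(frozen=True)
class PhaseClass:
    """A cell-cycle phase; ``no_inclusion`` lists the classes this phase's
    whole-nucleus objects must not spatially contain (e.g. prophase nuclei
    must not contain separately detected prophase/metaphase fragments)."""

    name: str
    no_inclusion: tuple[str, ...] = ()


@dataclass
class TrainingSample:
    class_name: str
    descriptor: DescriptorVector
    volume: float
    t: int
    click: tuple[int, int, int]  # (x, y, z) voxel coordinates
    threshold: int
    #: Descriptors of the same nucleus probed at other thresholds of its
    #: in-interval window. The classifier never sees them; they calibrate
    #: the pre-classifier ranges, because at segmentation time the nucleus
    #: is encountered (slightly eroded) across that whole window.
    window_descriptors: list[DescriptorVector] = field(default_factory=list)


@dataclass
class TrainedModel:
    """Random forest plus the side information the segmenter needs.

    ``ranges`` maps class name -> descriptor name -> (min, max) over the
    training samples of that class; the segmenter validates candidates
    against the union of these ranges before classification.
    """

    forest: RandomForestClassifier
    classes: list[PhaseClass]
    schedule: VolumeSchedule
    ranges: dict[str, dict[str, tuple[float, float]]]
    feature_names: tuple[str, ...]
    seed: int
    n_samples_per_class: dict[str, int] = field(default_factory=dict)
    #: The empirical min/max of a finite sample underestimates the
    #: population range, so each class range is widened by this fraction
    #: of its span on both sides when validating candidates.
    range_margin: float = 0.25

    def widened_range(self, class_name: str, descriptor: str) -> tuple[float, float]:
        lo, hi = self.ranges[class_name][descriptor]
        pad = self.range_margin * (hi - lo) + 1e-9
        return (lo - pad, hi + pad)

    @property
    def class_names(self) -> list[str]:
        return [c.name for c in self.classes]

    def predict(self, descriptors: list[DescriptorVector]) -> list[tuple[str, float]]:
        """Class and posterior probability (tree-vote fraction) per object."""
        X = np.stack([d.as_array(self.feature_names) for d in descriptors])
        proba = self.forest.predict_proba(X)
        labels = self.forest.classes_
        out = []
        for row in proba:
            i = int(np.argmax(row))
            out.append((str(labels[i]), float(row[i])))
        return out


def default_box_vox(
    schedule: VolumeSchedule, t: int, calibration: Calibration
) -> int:
    """Default crop-box side: 4x the equivalent radius of the largest
    expected nucleus at ``t``, in voxels, odd so the click is the centre."""
    v_max = max(
        interpolate_volume(schedule, name, t)[1] for name in schedule.class_names
    )
    side = int(round(4.0 * equivalent_radius(v_max) / calibration.dx))
    return max(5, side | 1)


def extract_sample(
    stack: ImageStack,
    click: tuple[int, int, int],
    v_interval: tuple[float, float],
    box_vox: int | None = None,
    t_step: int = 1,
    *,
    box_vox_z: int | None = None,
    return_window: bool = False,
):
    """Extract one nucleus around a click by iterative thresholding.

    A fixed-size box centred on the click is cropped; thresholds ascend
    from the crop minimum to its maximum in steps of ``t_step``. At each
    threshold the 26-connected component whose centroid is nearest the box
    centre (ties to the larger component) is measured; the first (lowest)
    threshold whose component volume falls inside ``v_interval`` wins.

    ``click`` is (x, y, z) in voxels. Returns ``(object, threshold)``, or
    ``(object, threshold, window)`` with the remaining in-interval
    ``(object, threshold)`` pairs when ``return_window`` is set. Raises
    :class:`ExtractionError` when no threshold yields an in-interval
    object.
    """
    x, y, z = click
    nz, ny, nx = stack.shape
    if not (0 <= x < nx and 0 <= y < ny and 0 <= z < nz):
        raise ValueError(f"click {click} outside image of shape (x={nx},y={ny},z={nz})")
    if box_vox is None:
        raise ValueError("box_vox is required")
    cal = stack.calibration
    if box_vox_z is None:
        box_vox_z = max(3, int(round(box_vox * cal.dx / cal.dz)) | 1)
    hz, hy, hx = box_vox_z // 2, box_vox // 2, box_vox // 2
    z0, z1 = max(0, z - hz), min(nz, z + hz + 1)
    y0, y1 = max(0, y - hy), min(ny, y + hy + 1)
    x0, x1 = max(0, x - hx), min(nx, x + hx + 1)
    crop = stack.data[z0:z1, y0:y1, x0:x1]
    center_um = (np.array([(z1 - z0), (y1 - y0), (x1 - x0)]) - 1) / 2.0 \
        * np.asarray(cal.spacing_zyx)

    lo, hi = int(crop.min()), int(crop.max())
    if hi == lo:
        raise ExtractionError(f"click {click}: crop is constant, nothing to extract")
    vv = cal.voxel_volume
    v_lo, v_hi = v_interval
    hits = list(
        _scan_in_interval(
            crop, cal, center_um, (v_lo, v_hi), t_step, (z0, y0, x0)
        )
    )
    if not hits:
        raise ExtractionError(
            f"click {click}: no threshold in [{lo + t_step}, {hi}] gave a component "
            f"with volume in [{v_lo:.2f}, {v_hi:.2f}] µm³"
        )
    obj, thr = hits[0]
    if return_window:
        return obj, thr, hits[1:]
    return obj, thr


def _scan_in_interval(crop, cal, center_um, v_interval, t_step, origin):
    """Yield (object, threshold) for every threshold whose component
    nearest the crop centre has an in-interval volume."""
    lo, hi = int(crop.min()), int(crop.max())
    vv = cal.voxel_volume
    v_lo, v_hi = v_interval
    z0, y0, x0 = origin
    for thr in range(lo + t_step, hi + 1, t_step):
        mask = crop >= thr
        labels, n = ndimage.label(mask, structure=_STRUCT_26)
        if n == 0:
            continue
        counts = np.bincount(labels.ravel())[1:]
        centroids = np.asarray(
            ndimage.center_of_mass(mask, labels, index=np.arange(1, n + 1))
        ).reshape(n, 3) * np.asarray(cal.spacing_zyx)
        dist = np.linalg.norm(centroids - center_um, axis=1)
        # nearest centroid; ties broken toward the larger component
        order = np.lexsort((-counts, np.round(dist, 9)))
        best = order[0] + 1
        vol = counts[best - 1] * vv
        if v_lo <= vol <= v_hi:
            comp = labels == best
            sl = ndimage.find_objects(comp.astype(np.int8))[0]
            obj = BinaryObject(
                mask=comp[sl],
                calibration=cal,
                origin=(z0 + sl[0].start, y0 + sl[1].start, x0 + sl[2].start),
            )
            yield obj, thr


def build_training_set(
    series: TimeSeries,
    clicks: ClickTable,
    schedule: VolumeSchedule,
    *,
    box_vox: int | None = None,
    t_step: int = 1,
    n_window_probes: int = 4,
) -> list[TrainingSample]:
    """Extract and describe a training sample per validated click.

    Besides the extracted (lowest in-interval threshold) object, up to
    ``n_window_probes`` further thresholds spread over the sample's
    in-interval window are described; those probe descriptors calibrate
    the pre-classifier ranges (see :class:`TrainingSample`). Failed
    extractions are logged and skipped; a class that ends up with no
    sample at all is an error because the forest could never learn it.
    """
    samples: list[TrainingSample] = []
    for row in clicks.validated_rows().to_dict("records"):
        t = int(row["t"])
        frame = series.frames[t - series.t0]
        class_name = str(row["class"])
        v_interval = interpolate_volume(schedule, class_name, t)
        box = box_vox or default_box_vox(schedule, t, series.calibration)
        click = (int(row["x"]), int(row["y"]), int(row["z"]))
        try:
            obj, thr, window = extract_sample(
                frame, click, v_interval, box_vox=box, t_step=t_step,
                return_window=True,
            )
        except ExtractionError as exc:
            log.warning("skipping training click: %s", exc)
            continue
        if len(window) > n_window_probes:
            idx = np.linspace(0, len(window) - 1, n_window_probes).round()
            window = [window[int(i)] for i in idx]
        samples.append(
            TrainingSample(
                class_name=class_name,
                descriptor=describe(obj),
                volume=obj.volume,
                t=t,
                click=click,
                threshold=thr,
                window_descriptors=[describe(w_obj) for w_obj, _ in window],
            )
        )
    present = {s.class_name for s in samples}
    missing = [n for n in schedule.class_names if n not in present]
    if missing:
        raise RuntimeError(
            f"no training sample could be extracted for classes: {missing}"
        )
    return samples


def _descriptor_ranges(
    samples: list[TrainingSample],
) -> dict[str, dict[str, tuple[float, float]]]:
    ranges: dict[str, dict[str, tuple[float, float]]] = {}
    for s in samples:
        cls = ranges.setdefault(s.class_name, {})
        for desc in [s.descriptor, *s.window_descriptors]:
            d = desc.as_dict()
            for name in ALL_DESCRIPTOR_NAMES:
                v = d[name]
                lo, hi = cls.get(name, (v, v))
                cls[name] = (min(lo, v), max(hi, v))
    return ranges


def train_model(
    samples: list[TrainingSample],
    schedule: VolumeSchedule,
    classes: list[PhaseClass] | None = None,
    n_trees: int = 200,
    seed: int = 0,
    feature_names: tuple[str, ...] = DEFAULT_FEATURES,
    range_margin: float = 0.25,
) -> TrainedModel:
    """Fit the 200-tree random forest on the descriptor vectors."""
    present = sorted({s.class_name for s in samples})
    if len(present) < 2:
        raise ValueError(f"need at least 2 classes, got {present}")
    if classes is None:
        classes = [PhaseClass(name=n) for n in schedule.class_names]
    X = np.stack([s.descriptor.as_array(feature_names) for s in samples])
    y = np.array([s.class_name for s in samples])
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )
    forest.fit(X, y)
    counts = {n: int((y == n).sum()) for n in present}
    return TrainedModel(
        forest=forest,
        classes=classes,
        schedule=schedule,
        ranges=_descriptor_ranges(samples),
        feature_names=feature_names,
        seed=seed,
        n_samples_per_class=counts,
        range_margin=range_margin,
    )


def evaluate_holdout(
    samples: list[TrainingSample],
    split: tuple[float, float] = (0.66, 0.34),
    seed: int = 0,
    n_trees: int = 200,
    feature_names: tuple[str, ...] = DEFAULT_FEATURES,
) -> "np.ndarray":
    """Stratified 66/33 split evaluation; returns the confusion matrix.

    Rows are true classes, columns predictions, both in sorted class-name
    order. Classes with fewer than 3 samples cannot be split meaningfully
    and raise an error naming them.
    """
    from sklearn.metrics import confusion_matrix

    y = np.array([s.class_name for s in samples])
    names, counts = np.unique(y, return_counts=True)
    too_small = [str(n) for n, c in zip(names, counts) if c < 3]
    if too_small:
        raise ValueError(f"classes with fewer than 3 samples: {too_small}")
    X = np.stack([s.descriptor.as_array(feature_names) for s in samples])
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=split[0], stratify=y, random_state=seed
    )
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    forest.fit(X_tr, y_tr)
    pred = forest.predict(X_te)
    return confusion_matrix(y_te, pred, labels=sorted(names))


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialise the model bundle (forest, ranges, schedule, seed)."""
    bundle = {
        "format_version": MODEL_FORMAT_VERSION,
        "forest": model.forest,
        "classes": model.classes,
        "schedule": model.schedule,
        "ranges": model.ranges,
        "feature_names": model.feature_names,
        "seed": model.seed,
        "n_samples_per_class": model.n_samples_per_class,
        "range_margin": model.range_margin,
    }
    joblib.dump(bundle, path)


def load_model(path: str | Path) -> TrainedModel:
    bundle = joblib.load(path)
    version = bundle.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {version}")
    return TrainedModel(
        forest=bundle["forest"],
        classes=bundle["classes"],
        schedule=bundle["schedule"],
        ranges=bundle["ranges"],
        feature_names=tuple(bundle["feature_names"]),
        seed=bundle["seed"],
        n_samples_per_class=bundle["n_samples_per_class"],
        range_margin=bundle["range_margin"],
    )
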