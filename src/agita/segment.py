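"""Classification-guided iterative-threshold segmentation.

For each time point the image is binarised at every threshold from low to
high. Connected components pass a Boolean pre-classifier (volume inside
the union of per-phase intervals, every descriptor inside the union of
per-phase training ranges) before the random forest assigns them a phase
and a posterior probability. Validated candidates are linked into a
hierarchy across thresholds: nuclei merged at low thresholds split into
separate branches as the threshold rises. Within each branch the selected
threshold is the one inside the longest run of stable classification with
the highest posterior — i.e. the segmentation that the classifier is most
confident about.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from agita.core_io import ImageStack, TimeSeries, RESULT_COLUMNS
from agita.descriptors import BinaryObject, DescriptorVector, describe
from agita.preprocess import VolumeSchedule, adaptive_median_filter, interpolate_volume
from agita.train import PhaseClass, TrainedModel

__all__ = [
    "CandidateObject",
    "ObjectHierarchy",
    "SegmentationResult",
    "threshold_levels",
    "default_threshold_step",
    "sweep_thresholds",
    "validate_candidate",
    "classify_candidate",
    "select_best",
    "apply_inclusion_model",
    "segment_timepoint",
    "segment_series",
]

log = logging.getLogger(__name__)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

#: Posterior below which a selected object is flagged as dubious.
LOW_PROBABILITY_FLAG = 0.5


@dataclass
class CandidateObject:
    """A validated, classified connected component at one threshold."""

    node_id: int
    threshold: int
    slices: tuple[slice, slice, slice]
    mask: np.ndarray  # bool crop within `slices`
    n_voxels: int
    volume: float
    centroid_um: np.ndarray  # (z, y, x) µm
    descriptor: DescriptorVector
    class_name: str = ""
    probability: float = 0.0
    parent: int | None = None
    children: list[int] = field(default_factory=list)

    def contains_point(self, zyx_vox: tuple[int, int, int]) -> bool:
        z, y, x = zyx_vox
        sz, sy, sx = self.slices
        if not (sz.start <= z < sz.stop and sy.start <= y < sy.stop
                and sx.start <= x < sx.stop):
            return False
        return bool(self.mask[z - sz.start, y - sy.start, x - sx.start])


@dataclass
class ObjectHierarchy:
    """Forest of validated candidates linked across increasing thresholds.

    A node's parent is the candidate at the highest lower threshold that
    contains the majority of its voxels; because threshold masks are
    nested, containment is complete in practice. Invalid intermediate
    components (e.g. the whole embryo at low thresholds) are simply never
    nodes, leaving chains parentless.
    """

    nodes: dict[int, CandidateObject] = field(default_factory=dict)

    def add(self, node: CandidateObject, parent: int | None) -> None:
        node.parent = parent
        self.nodes[node.node_id] = node
        if parent is not None:
            self.nodes[parent].children.append(node.node_id)

    def leaves(self) -> list[CandidateObject]:
        return [n for n in self.nodes.values() if not n.children]

    def branch(self, leaf: CandidateObject) -> list[CandidateObject]:
        """Maximal chain from the leaf down to (excluding) the nearest
        split node, so sibling nuclei can never share a selected object."""
        chain = [leaf]
        cur = leaf
        while cur.parent is not None:
            parent = self.nodes[cur.parent]
            if len(parent.children) >= 2:
                break
            chain.append(parent)
            cur = parent
        return chain  # highest threshold first

    def ancestors(self, node: CandidateObject) -> list[CandidateObject]:
        out = []
        cur = node
        while cur.parent is not None:
            cur = self.nodes[cur.parent]
            out.append(cur)
        return out

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class SegmentationResult:
    """Label stack plus one record per selected nucleus."""

    labels: np.ndarray
    records: pd.DataFrame
    t: int


def default_threshold_step(stack: ImageStack) -> int:
    """Step 1 for 8-bit data; for 16-bit, span/512 so the sweep stays
    tractable (users may override either way via configuration)."""
    if stack.bit_depth == 8:
        return 1
    lo, hi = int(stack.data.min()), int(stack.data.max())
    return max(1, (hi - lo) // 512)


def threshold_levels(stack: ImageStack, t_step: int | None = None) -> list[int]:
    if t_step is None:
        t_step = default_threshold_step(stack)
    if t_step < 1:
        raise ValueError("threshold step must be >= 1")
    lo, hi = int(stack.data.min()), int(stack.data.max())
    return list(range(lo + t_step, hi + 1, t_step))


def _volume_intervals(model: TrainedModel, t: int) -> list[tuple[float, float]]:
    return [
        interpolate_volume(model.schedule, name, t)
        for name in model.schedule.class_names
    ]


def _volume_valid(volume: float, intervals: list[tuple[float, float]]) -> bool:
    return any(lo <= volume <= hi for lo, hi in intervals)


def _descriptors_valid(d: DescriptorVector, model: TrainedModel) -> bool:
    # Union semantics: each descriptor must lie inside at least one
    # class's (margin-widened) training range, independently per descriptor.
    values = d.as_dict()
    for name in model.feature_names:
        v = values[name]
        if not any(
            lo <= v <= hi
            for lo, hi in (
                model.widened_range(cls, name) for cls in model.ranges
            )
        ):
            return False
    return True


def validate_candidate(
    component: BinaryObject, model: TrainedModel, t: int,
    descriptor: DescriptorVector | None = None,
) -> bool:
    """Boolean pre-classifier: volume in the union of phase intervals at
    ``t`` and every descriptor inside the union of training ranges."""
    intervals = _volume_intervals(model, t)
    if not _volume_valid(component.volume, intervals):
        return False
    if descriptor is None:
        descriptor = describe(component)
    return _descriptors_valid(descriptor, model)


def classify_candidate(
    component: BinaryObject, model: TrainedModel,
    descriptor: DescriptorVector | None = None,
) -> tuple[str, float]:
    """Forest vote on a single validated candidate."""
    if descriptor is None:
        descriptor = describe(component)
    return model.predict([descriptor])[0]


def sweep_thresholds(
    filtered: ImageStack,
    model: TrainedModel,
    t: int,
    t_step: int | None = None,
) -> ObjectHierarchy:
    """Build the candidate hierarchy for one time point.

    At each threshold the image is binarised (>= threshold), 26-connected
    components are labelled, cheap volume screening prunes most of them,
    survivors are described, range-checked and classified, and accepted
    candidates are linked to the most recent accepted candidate covering
    their voxels. A candidate whose voxel set is identical to its parent's
    reuses the parent's descriptors and classification (the component did
    not change, so neither can its shape).
    """
    hierarchy = ObjectHierarchy()
    cal = filtered.calibration
    vv = cal.voxel_volume
    spacing = np.asarray(cal.spacing_zyx)
    intervals = _volume_intervals(model, t)
    v_lo = min(lo for lo, _ in intervals)
    v_hi = max(hi for _, hi in intervals)
    min_vox = max(1, int(np.floor(v_lo / vv)))
    max_vox = int(np.ceil(v_hi / vv))

    # id of the most recent accepted node covering each voxel
    node_map = np.full(filtered.shape, -1, dtype=np.int32)
    next_id = 0

    for thr in threshold_levels(filtered, t_step):
        mask = filtered.data >= thr
        labels, n = ndimage.label(mask, structure=_STRUCT_26)
        if n == 0:
            continue
        counts = np.bincount(labels.ravel())
        candidate_labels = [
            lab for lab in range(1, n + 1)
            if min_vox <= counts[lab] <= max_vox
        ]
        if not candidate_labels:
            continue
        slices_all = ndimage.find_objects(labels)
        pending: list[CandidateObject] = []
        pending_parents: list[int | None] = []
        need_classification: list[int] = []  # indices into `pending`
        for lab in candidate_labels:
            sl = slices_all[lab - 1]
            comp_mask = labels[sl] == lab
            n_vox = int(counts[lab])
            volume = n_vox * vv
            if not _volume_valid(volume, intervals):
                continue
            coords = np.argwhere(comp_mask)
            origin = np.array([s.start for s in sl])
            centroid = (coords.mean(axis=0) + origin) * spacing

            parent: int | None = None
            reuse: CandidateObject | None = None
            ids_under = node_map[sl][comp_mask]
            ids_under = ids_under[ids_under >= 0]
            if ids_under.size:
                vals, freq = np.unique(ids_under, return_counts=True)
                top = int(vals[np.argmax(freq)])
                if freq.max() * 2 >= n_vox:  # majority containment
                    parent = top
                    p = hierarchy.nodes[top]
                    if p.n_voxels == n_vox and int(freq.max()) == n_vox:
                        reuse = p  # identical voxel set

            if reuse is not None:
                node = CandidateObject(
                    node_id=next_id, threshold=thr, slices=sl,
                    mask=comp_mask, n_voxels=n_vox, volume=volume,
                    centroid_um=centroid, descriptor=reuse.descriptor,
                    class_name=reuse.class_name, probability=reuse.probability,
                )
            else:
                obj = BinaryObject(
                    mask=comp_mask, calibration=cal,
                    origin=tuple(int(v) for v in origin),
                )
                descriptor = describe(obj)
                if not _descriptors_valid(descriptor, model):
                    continue
                node = CandidateObject(
                    node_id=next_id, threshold=thr, slices=sl,
                    mask=comp_mask, n_voxels=n_vox, volume=volume,
                    centroid_um=centroid, descriptor=descriptor,
                )
                need_classification.append(len(pending))
            pending.append(node)
            pending_parents.append(parent)
            next_id += 1

        if need_classification:
            preds = model.predict(
                [pending[i].descriptor for i in need_classification]
            )
            for i, (cls, prob) in zip(need_classification, preds):
                pending[i].class_name = cls
                pending[i].probability = prob
        for node, parent in zip(pending, pending_parents):
            hierarchy.add(node, parent)
            node_map[node.slices][node.mask] = node.node_id

    if not hierarchy.nodes:
        log.info("time point %d: empty hierarchy (no valid candidates)", t)
    return hierarchy


def select_best(hierarchy: ObjectHierarchy) -> list[CandidateObject]:
    """Pick the best threshold per branch: one object per leaf.

    Scanning the branch from the highest threshold downward, the longest
    run of consecutive nodes sharing one class wins (ties to the run
    nearer the high-threshold end); within the run, the node with maximal
    posterior wins (ties to the higher threshold).
    """
    selected = []
    for leaf in sorted(hierarchy.leaves(), key=lambda n: n.node_id):
        chain = hierarchy.branch(leaf)  # highest threshold first
        best_start, best_len = 0, 1
        i = 0
        while i < len(chain):
            j = i
            while j + 1 < len(chain) and chain[j + 1].class_name == chain[i].class_name:
                j += 1
            if j - i + 1 > best_len:
                best_start, best_len = i, j - i + 1
            i = j + 1
        run = chain[best_start:best_start + best_len]
        # max probability; ties to higher threshold (earlier in run)
        best = max(run, key=lambda n: (n.probability, n.threshold))
        selected.append(best)
    return selected


def apply_inclusion_model(
    selected: list[CandidateObject],
    hierarchy: ObjectHierarchy,
    classes: list[PhaseClass],
) -> list[CandidateObject]:
    """Replace forbidden inner fragments by their whole-nucleus ancestor.

    A class flagged ``no_inclusion`` (e.g. prophase) may not contain
    separately selected objects of its forbidden classes (e.g. the
    condensed chromosomes inside, re-detected as prophase/metaphase at
    high thresholds). When such an ancestor exists in a selected object's
    ancestry, the ancestor — the whole nucleus — replaces every selected
    object whose centroid it contains, keeping the output disjoint.
    """
    forbidden_by_class = {c.name: set(c.no_inclusion) for c in classes}
    if not any(forbidden_by_class.values()):
        return list(selected)

    result = list(selected)
    # candidate replacement ancestors, outermost (lowest threshold) first
    flagged: dict[int, CandidateObject] = {}
    for obj in selected:
        for anc in hierarchy.ancestors(obj):
            if forbidden_by_class.get(anc.class_name):
                flagged[anc.node_id] = anc
    for anc in sorted(flagged.values(), key=lambda n: (n.threshold, n.node_id)):
        forbidden = forbidden_by_class[anc.class_name]
        # centroid containment is evaluated in voxel coordinates
        inside = [
            o for o in result
            if o.node_id != anc.node_id and anc.contains_point(_centroid_vox(o))
        ]
        if any(o.class_name in forbidden for o in inside):
            result = [o for o in result if o not in inside]
            if anc not in result:
                result.append(anc)
    return result


def _centroid_vox(obj: CandidateObject) -> tuple[int, int, int]:
    sz, sy, sx = obj.slices
    coords = np.argwhere(obj.mask)
    cz, cy, cx = coords.mean(axis=0)
    return (int(round(cz)) + sz.start, int(round(cy)) + sy.start,
            int(round(cx)) + sx.start)


def _touches_border(obj: CandidateObject, shape: tuple[int, int, int]) -> bool:
    sz, sy, sx = obj.slices
    return (
        sz.start == 0 or sy.start == 0 or sx.start == 0
        or sz.stop == shape[0] or sy.stop == shape[1] or sx.stop == shape[2]
    )


def segment_timepoint(
    stack: ImageStack,
    model: TrainedModel,
    t: int,
    *,
    t_step: int | None = None,
    filter_enabled: bool = False,
    max_radius_vox: int = 12,
) -> SegmentationResult:
    """Full per-frame pipeline: filter, sweep, select, inclusion, relabel.

    Selected objects are relabelled 1..N in centroid order (z, then y,
    then x) so output labels are deterministic. Objects with a low
    posterior or touching the image border are flagged in the record (and
    warned about), never removed: noisy-object filtering is deliberately
    left to downstream tools.
    """
    work = stack
    if filter_enabled:
        work = adaptive_median_filter(stack, t, model.schedule, max_radius_vox)
    hierarchy = sweep_thresholds(work, model, t, t_step)
    selected = select_best(hierarchy)
    selected = apply_inclusion_model(selected, hierarchy, model.classes)
    selected.sort(key=lambda o: tuple(o.centroid_um))

    labels = np.zeros(stack.shape, dtype=np.uint16)
    rows = []
    cal = stack.calibration
    for i, obj in enumerate(selected, start=1):
        labels[obj.slices][obj.mask] = i
        flags = []
        if obj.probability < LOW_PROBABILITY_FLAG:
            flags.append("low_probability")
            log.warning(
                "t=%d label=%d: low classification probability %.2f",
                t, i, obj.probability,
            )
        if _touches_border(obj, stack.shape):
            flags.append("border")
        d = obj.descriptor.as_dict()
        cz, cy, cx = obj.centroid_um
        rows.append({
            "label": i, "t": t, "class": obj.class_name,
            "probability": obj.probability, "threshold": obj.threshold,
            "volume_um3": obj.volume,
            "cx": cx, "cy": cy, "cz": cz,
            **d,
            "flags": ";".join(flags),
        })
    records = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return SegmentationResult(labels=labels, records=records, t=t)


def segment_series(
    series: TimeSeries,
    model: TrainedModel,
    *,
    t_step: int | None = None,
    filter_enabled: bool = False,
    max_radius_vox: int = 12,
) -> list[SegmentationResult]:
    """Segment every frame independently (no temporal coupling)."""
    results = []
    for i, frame in enumerate(series.frames):
        t = series.t0 + i
        try:
            results.append(
                segment_timepoint(
                    frame, model, t, t_step=t_step,
                    filter_enabled=filter_enabled,
                    max_radius_vox=max_radius_vox,
                )
            )
        except Exception as exc:
            raise RuntimeError(f"segmentation failed at frame t={t}: {exc}") from exc
    return results
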