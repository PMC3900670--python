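"""Threshold sweep, hierarchy, best-threshold selection and inclusion model."""

import numpy as np
import pytest

from agita.core_io import Calibration, ImageStack, TimeSeries
from agita.descriptors import BinaryObject, describe
from agita.evaluate import match_detections
from agita.segment import (
    CandidateObject,
    ObjectHierarchy,
    apply_inclusion_model,
    classify_candidate,
    segment_series,
    segment_timepoint,
    select_best,
    sweep_thresholds,
    validate_candidate,
)
from agita.synth import (
    DEFAULT_PHASE_SHAPES,
    SimulationConfig,
    generate_series,
    render_nucleus,
)
from agita.train import PhaseClass, build_training_set, train_model

from ._oracles import enumerate_selection, selection_signature


def _paste(data, rendered, center_vox, value):
    start = np.asarray(center_vox) + np.asarray(rendered.origin_vox)
    sl = tuple(
        slice(int(a), int(a + s)) for a, s in zip(start, rendered.instance.shape)
    )
    data[sl][rendered.mask] = value
    return rendered.instance > 0, sl


@pytest.fixture(scope="module")
def cal():
    return Calibration(dx=0.25, dy=0.25, dz=0.5)


@pytest.fixture(scope="module")
def two_ball_stack(cal):
    """Two interphase-like nuclei, far apart, on a dark background."""
    rng = np.random.default_rng(0)
    data = np.full((32, 96, 96), 10, dtype=np.uint8)
    r1 = render_nucleus("interphase", DEFAULT_PHASE_SHAPES["interphase"], rng, cal)
    r2 = render_nucleus("interphase", DEFAULT_PHASE_SHAPES["interphase"], rng, cal)
    m1, sl1 = _paste(data, r1, (16, 30, 30), 160)
    m2, sl2 = _paste(data, r2, (16, 66, 66), 200)
    full1 = np.zeros(data.shape, bool)
    full1[sl1][m1] = True
    full2 = np.zeros(data.shape, bool)
    full2[sl2][m2] = True
    return ImageStack(data=data, calibration=cal), full1, full2


class TestSweep:
    def test_two_separate_nuclei_make_two_chains(self, two_ball_stack, small_model):
        stack, m1, m2 = two_ball_stack
        hierarchy = sweep_thresholds(stack, small_model, t=0, t_step=25)
        leaves = hierarchy.leaves()
        assert len(leaves) == 2
        # every node belongs to a single linear chain per nucleus
        for leaf in leaves:
            chain = hierarchy.branch(leaf)
            assert all(len(n.children) <= 1 for n in chain)

    def test_blank_image_empty_hierarchy(self, cal, small_model):
        stack = ImageStack(np.full((8, 16, 16), 7, np.uint8), cal)
        hierarchy = sweep_thresholds(stack, small_model, t=0, t_step=5)
        assert len(hierarchy) == 0

    def test_parent_thresholds_strictly_increase(self, two_ball_stack, small_model):
        stack, _, _ = two_ball_stack
        hierarchy = sweep_thresholds(stack, small_model, t=0, t_step=25)
        for node in hierarchy.nodes.values():
            if node.parent is not None:
                assert hierarchy.nodes[node.parent].threshold < node.threshold


class TestValidateCandidate:
    def test_training_like_ball_valid(self, two_ball_stack, small_model, cal):
        _, m1, _ = two_ball_stack
        obj = BinaryObject(mask=m1, calibration=cal)
        assert validate_candidate(obj, small_model, t=0)

    def test_whole_embryo_blob_invalid_by_volume(self, cal, small_model):
        blob = BinaryObject(mask=np.ones((20, 60, 60), bool), calibration=cal)
        assert not validate_candidate(blob, small_model, t=0)

    def test_needle_invalid_by_descriptor_ranges(self, cal, small_model):
        # same order of volume as a nucleus but needle-shaped: the volume
        # screen passes while elongation exceeds every training range
        needle = np.zeros((6, 8, 120), bool)
        needle[2:5, 2:7, 2:118] = True
        obj = BinaryObject(mask=needle, calibration=cal)
        intervals = [
            small_model.widened_range(c, "elongation") for c in small_model.ranges
        ]
        d = describe(obj)
        assert all(d.elongation > hi for _, hi in intervals)
        assert not validate_candidate(obj, small_model, t=0)

    def test_classification_of_training_object(self, two_ball_stack, small_model):
        _, m1, _ = two_ball_stack
        obj = BinaryObject(mask=m1, calibration=Calibration(0.25, 0.25, 0.5))
        cls, prob = classify_candidate(obj, small_model)
        assert cls == "interphase"
        assert prob >= 0.5
        assert classify_candidate(obj, small_model) == (cls, prob)


def _node(node_id, thr, cls, prob, at=(0, 0, 0)):
    mask = np.ones((1, 1, 1), bool)
    return CandidateObject(
        node_id=node_id, threshold=thr,
        slices=(slice(at[0], at[0] + 1), slice(at[1], at[1] + 1),
                slice(at[2], at[2] + 1)),
        mask=mask, n_voxels=1, volume=1.0,
        centroid_um=np.array(at, dtype=float),
        descriptor=None, class_name=cls, probability=prob,
    )


def _chain(specs):
    """Build a single-chain hierarchy from (threshold, class, prob) tuples
    given low threshold first."""
    h = ObjectHierarchy()
    prev = None
    for i, (thr, cls, prob) in enumerate(specs):
        h.add(_node(i, thr, cls, prob), prev)
        prev = i
    return h


class TestSelectBest:
    def test_longest_run_then_max_probability(self):
        # low->high: (A,.6) (A,.9) (A,.7) (B,.8): run of three A wins, the
        # 0.9 node is selected
        h = _chain([(10, "A", 0.6), (20, "A", 0.9), (30, "A", 0.7), (40, "B", 0.8)])
        chosen = select_best(h)
        assert len(chosen) == 1
        assert (chosen[0].threshold, chosen[0].probability) == (20, 0.9)

    def test_single_node_chain(self):
        h = _chain([(10, "A", 0.4)])
        assert [n.node_id for n in select_best(h)] == [0]

    def test_run_tie_resolved_toward_high_threshold(self):
        # low->high (A,B,B,A,A): two runs of length 2; the high-threshold
        # A-run must win
        h = _chain([
            (10, "A", 0.99), (20, "B", 0.6), (30, "B", 0.7),
            (40, "A", 0.5), (50, "A", 0.4),
        ])
        chosen = select_best(h)
        assert chosen[0].class_name == "A"
        assert chosen[0].threshold in (40, 50)
        assert chosen[0].threshold == 40  # higher probability inside the run

    def test_probability_tie_resolved_toward_high_threshold(self):
        h = _chain([(10, "A", 0.8), (20, "A", 0.8)])
        assert select_best(h)[0].threshold == 20

    def test_split_parent_excluded_children_selected(self):
        # a valid parent with two valid children: each child is its own
        # branch; the parent (a split node) can never be selected
        h = ObjectHierarchy()
        h.add(_node(0, 10, "A", 0.99), None)
        h.add(_node(1, 20, "A", 0.5, at=(0, 0, 1)), 0)
        h.add(_node(2, 20, "A", 0.5, at=(0, 0, 5)), 0)
        chosen = select_best(h)
        assert sorted(n.node_id for n in chosen) == [1, 2]


class TestInclusionModel:
    def _shell_with_cores(self):
        h = ObjectHierarchy()
        shell = CandidateObject(
            node_id=0, threshold=10,
            slices=(slice(0, 4), slice(0, 8), slice(0, 8)),
            mask=np.ones((4, 8, 8), bool), n_voxels=256, volume=16.0,
            centroid_um=np.array([2.0, 4.0, 4.0]),
            descriptor=None, class_name="prophase", probability=0.9,
        )
        h.add(shell, None)
        cores = []
        for i, x0 in enumerate((1, 5)):
            core = CandidateObject(
                node_id=i + 1, threshold=40,
                slices=(slice(1, 3), slice(2, 6), slice(x0, x0 + 2)),
                mask=np.ones((2, 4, 2), bool), n_voxels=16, volume=1.0,
                centroid_um=np.array([2.0, 4.0, x0 + 0.5]),
                descriptor=None, class_name="metaphase", probability=0.8,
            )
            h.add(core, 0)
            cores.append(core)
        return h, shell, cores

    def test_forbidden_cores_replaced_by_whole_nucleus(self):
        h, shell, cores = self._shell_with_cores()
        classes = [
            PhaseClass("prophase", no_inclusion=("prophase", "metaphase")),
            PhaseClass("metaphase"),
        ]
        result = apply_inclusion_model(list(cores), h, classes)
        assert result == [shell]

    def test_no_flagged_classes_identity(self):
        h, _shell, cores = self._shell_with_cores()
        classes = [PhaseClass("prophase"), PhaseClass("metaphase")]
        assert apply_inclusion_model(list(cores), h, classes) == cores

    def test_non_forbidden_inner_class_untouched(self):
        h, _shell, cores = self._shell_with_cores()
        for c in cores:
            c.class_name = "interphase"
        classes = [
            PhaseClass("prophase", no_inclusion=("prophase", "metaphase")),
            PhaseClass("interphase"),
        ]
        assert apply_inclusion_model(list(cores), h, classes) == cores


class TestSegmentTimepoint:
    def test_recovers_ground_truth_instances(self, small_sim, small_model):
        series, gt, _clicks, _schedule = small_sim
        res = segment_timepoint(series.frames[0], small_model, 0, t_step=3)
        counts, pairs = match_detections(res.labels, gt.labels[0])
        assert counts.fn == 0 and counts.fp == 0
        for pl, gl in pairs:
            pm = res.labels == pl
            gm = gt.labels[0] == gl
            iou = (pm & gm).sum() / (pm | gm).sum()
            assert iou >= 0.8

    def test_selected_objects_are_threshold_components(self, small_sim, small_model):
        from scipy import ndimage

        series, _gt, _clicks, _schedule = small_sim
        frame = series.frames[0]
        res = segment_timepoint(frame, small_model, 0, t_step=3)
        for row in res.records.to_dict("records"):
            mask = res.labels == row["label"]
            labels, _ = ndimage.label(
                frame.data >= row["threshold"], structure=np.ones((3, 3, 3))
            )
            ids = np.unique(labels[mask])
            assert len(ids) == 1
            np.testing.assert_array_equal(mask, labels == ids[0])

    def test_selected_objects_pairwise_disjoint(self, small_sim, small_model):
        series, _gt, _clicks, _schedule = small_sim
        res = segment_timepoint(series.frames[0], small_model, 0, t_step=3)
        # labels are single-valued per voxel by construction; check records
        # and labels agree on sizes instead
        for row in res.records.to_dict("records"):
            size = int((res.labels == row["label"]).sum())
            vv = series.calibration.voxel_volume
            assert size * vv == pytest.approx(row["volume_um3"])

    def test_blank_frame_empty_result(self, cal, small_model):
        stack = ImageStack(np.full((8, 16, 16), 3, np.uint8), cal)
        res = segment_timepoint(stack, small_model, 0, t_step=5)
        assert res.labels.max() == 0
        assert len(res.records) == 0

    def test_determinism(self, small_sim, small_model):
        series, _gt, _clicks, _schedule = small_sim
        a = segment_timepoint(series.frames[1], small_model, 1, t_step=3)
        b = segment_timepoint(series.frames[1], small_model, 1, t_step=3)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.records.to_csv(index=False) == b.records.to_csv(index=False)

    def test_intensity_shift_moves_thresholds_not_voxels(
        self, two_ball_stack, small_model, cal
    ):
        stack, _, _ = two_ball_stack
        shifted = ImageStack((stack.data + 20).astype(np.uint8), cal)
        a = segment_timepoint(stack, small_model, 0, t_step=25)
        b = segment_timepoint(shifted, small_model, 0, t_step=25)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert (
            b.records["threshold"].to_numpy()
            == a.records["threshold"].to_numpy() + 20
        ).all()

    def test_touching_nuclei_never_merged(self, cal, small_model):
        """Anaphase-like pair with a small background gap: one label each."""
        rng = np.random.default_rng(3)
        data = np.full((32, 64, 64), 10, dtype=np.uint8)
        rendered = render_nucleus(
            "anaphase", DEFAULT_PHASE_SHAPES["anaphase"], rng, cal
        )
        _paste(data, rendered, (16, 32, 32), 180)
        stack = ImageStack(data=data, calibration=cal)
        res = segment_timepoint(stack, small_model, 0, t_step=10)
        assert res.labels.max() == 2
        # the two labels reproduce the two rendered parts exactly
        for part in (1, 2):
            pmask = np.zeros(data.shape, bool)
            start = np.asarray((16, 32, 32)) + np.asarray(rendered.origin_vox)
            sl = tuple(
                slice(int(s), int(s + n))
                for s, n in zip(start, rendered.instance.shape)
            )
            pmask[sl][rendered.instance == part] = True
            overlap_labels = np.unique(res.labels[pmask])
            assert len(overlap_labels) == 1 and overlap_labels[0] > 0


class TestBruteForceEquivalence:
    def test_selection_matches_enumeration(self, cal, small_model):
        """On a small quantised image the hierarchy + selection must match
        a literal enumeration of every threshold and component."""
        rng = np.random.default_rng(7)
        data = np.full((24, 64, 64), 10, dtype=np.uint8)
        r1 = render_nucleus("interphase", DEFAULT_PHASE_SHAPES["interphase"], rng, cal)
        r2 = render_nucleus("interphase", DEFAULT_PHASE_SHAPES["interphase"], rng, cal)
        _, sl1 = _paste(data, r1, (12, 20, 20), 160)
        _, sl2 = _paste(data, r2, (12, 44, 44), 200)
        # dim bridge connecting the nuclei at low thresholds
        data[12, 30:36, 30:36] = 60
        assert len(np.unique(data)) <= 8
        stack = ImageStack(data=data, calibration=cal)
        res = segment_timepoint(stack, small_model, 0, t_step=25)
        mine = selection_signature(res.labels, res.records)
        oracle = enumerate_selection(stack, small_model, t=0, t_step=25)
        assert mine == oracle


def test_series_with_blank_frame(cal, small_model):
    rng = np.random.default_rng(1)
    bright = np.full((24, 48, 48), 10, dtype=np.uint8)
    r = render_nucleus("interphase", DEFAULT_PHASE_SHAPES["interphase"], rng, cal)
    _paste(bright, r, (12, 24, 24), 170)
    blank = np.full((24, 48, 48), 10, dtype=np.uint8)
    series = TimeSeries(
        frames=[
            ImageStack(bright, cal),
            ImageStack(blank, cal),
        ]
    )
    results = segment_series(series, small_model, t_step=10)
    assert len(results) == 2
    assert len(results[0].records) == 1
    assert len(results[1].records) == 0


def test_zero_noise_end_to_end_recovery():
    """With no noise and no decay every instance is recovered at IoU >= 0.9."""
    cfg = SimulationConfig(
        shape=(48, 140, 140), n_frames=2, n_cells=8, n_divisions=0,
        noise_read=0.0, noise_gain=0.0, decay=1.0, size_decay=1.0, seed=5,
    )
    series, gt, clicks, schedule = generate_series(cfg)
    samples = build_training_set(series, clicks, schedule, t_step=3)
    model = train_model(samples, schedule, seed=2)
    res = segment_timepoint(series.frames[0], model, 0, t_step=3)
    counts, pairs = match_detections(res.labels, gt.labels[0])
    assert counts.fn == 0 and counts.fp == 0
    for pl, gl in pairs:
        pm = res.labels == pl
        gm = gt.labels[0] == gl
        assert (pm & gm).sum() / (pm | gm).sum() >= 0.9
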