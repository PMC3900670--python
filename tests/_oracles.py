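"""Independent brute-force oracles used to cross-check the implementation."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from agita.core_io import Calibration, ImageStack
from agita.descriptors import BinaryObject, describe
from agita.preprocess import interpolate_volume
from agita.train import TrainedModel


def brute_force_central_moments(
    mask: np.ndarray, spacing: tuple[float, float, float], max_order: int = 4
) -> dict[tuple[int, int, int], float]:
    """Central moments by an explicit loop over voxels (slow, literal)."""
    dz, dy, dx = spacing
    pts = [
        (k * dz, j * dy, i * dx)
        for (k, j, i) in np.argwhere(mask)
    ]
    n = len(pts)
    zc = sum(p[0] for p in pts) / n
    yc = sum(p[1] for p in pts) / n
    xc = sum(p[2] for p in pts) / n
    vv = dx * dy * dz
    out: dict[tuple[int, int, int], float] = {(0, 0, 0): n * vv}
    for total in range(2, max_order + 1):
        for p in range(total + 1):
            for q in range(total - p + 1):
                r = total - p - q
                acc = 0.0
                for (z, y, x) in pts:
                    acc += (x - xc) ** p * (y - yc) ** q * (z - zc) ** r
                out[(p, q, r)] = acc * vv
    return out


def enumerate_selection(
    stack: ImageStack,
    model: TrainedModel,
    t: int,
    t_step: int,
) -> set[tuple[int, str, frozenset]]:
    """Straight-line re-derivation of the per-branch best-threshold choice.

    Enumerates every threshold, keeps every component that passes the
    volume/descriptor screen, links components across levels by literal
    voxel-set subset tests, walks up each leaf's chain until a node with
    two or more children, and picks the longest high-end run / highest
    probability exactly as specified. Only the descriptor computation and
    the trained forest are shared with the implementation under test.
    """
    cal = stack.calibration
    vv = cal.voxel_volume
    intervals = [
        interpolate_volume(model.schedule, name, t)
        for name in model.schedule.class_names
    ]

    def volume_ok(v: float) -> bool:
        return any(lo <= v <= hi for lo, hi in intervals)

    def ranges_ok(d) -> bool:
        vals = d.as_dict()
        for name in model.feature_names:
            if not any(
                model.widened_range(c, name)[0]
                <= vals[name]
                <= model.widened_range(c, name)[1]
                for c in model.ranges
            ):
                return False
        return True

    lo, hi = int(stack.data.min()), int(stack.data.max())
    accepted: list[dict] = []  # in threshold order
    for thr in range(lo + t_step, hi + 1, t_step):
        labels, n = ndimage.label(stack.data >= thr, structure=np.ones((3, 3, 3)))
        for lab in range(1, n + 1):
            voxels = frozenset(map(tuple, np.argwhere(labels == lab)))
            v = len(voxels) * vv
            if not volume_ok(v):
                continue
            mask = np.zeros(stack.shape, dtype=bool)
            for p in voxels:
                mask[p] = True
            d = describe(BinaryObject(mask=mask, calibration=cal))
            if not ranges_ok(d):
                continue
            cls, prob = model.predict([d])[0]
            accepted.append(
                {"thr": thr, "voxels": voxels, "class": cls, "prob": prob,
                 "parent": None, "children": []}
            )
    # parent = accepted node at the highest lower threshold holding a
    # voxel-set majority of this node
    for i, node in enumerate(accepted):
        best = None
        for j in range(i):
            other = accepted[j]
            if other["thr"] >= node["thr"]:
                continue
            overlap = len(node["voxels"] & other["voxels"])
            if 2 * overlap >= len(node["voxels"]):
                if best is None or other["thr"] > accepted[best]["thr"]:
                    best = j
        if best is not None:
            node["parent"] = best
            accepted[best]["children"].append(i)

    selected: set[tuple[int, str, frozenset]] = set()
    for i, node in enumerate(accepted):
        if node["children"]:
            continue  # not a leaf
        chain = [i]
        cur = i
        while accepted[cur]["parent"] is not None:
            p = accepted[cur]["parent"]
            if len(accepted[p]["children"]) >= 2:
                break
            chain.append(p)
            cur = p
        # chain is highest threshold first
        runs = []
        k = 0
        while k < len(chain):
            m = k
            while (
                m + 1 < len(chain)
                and accepted[chain[m + 1]]["class"] == accepted[chain[k]]["class"]
            ):
                m += 1
            runs.append((k, m))
            k = m + 1
        start, end = max(runs, key=lambda r: r[1] - r[0])  # first max wins ties
        run_nodes = [accepted[chain[x]] for x in range(start, end + 1)]
        best = max(run_nodes, key=lambda nd: (nd["prob"], nd["thr"]))
        selected.add((best["thr"], best["class"], best["voxels"]))
    return selected


def selection_signature(result_labels: np.ndarray, records) -> set:
    """(threshold, class, voxel set) signature of a segmentation result."""
    out = set()
    for row in records.to_dict("records"):
        voxels = frozenset(map(tuple, np.argwhere(result_labels == row["label"])))
        out.add((int(row["threshold"]), row["class"], voxels))
    return out
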