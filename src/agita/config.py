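"""YAML run configuration: schema validation and (de)serialisation.

The only biological inputs a user must supply are the per-phase nucleus
volume intervals at the first and last time points; everything else has
documented defaults. Unknown keys are rejected so typos fail loudly
before any computation starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from agita.core_io import Calibration
from agita.preprocess import ClassVolumes, VolumeSchedule, DEFAULT_MAX_RADIUS_VOX
from agita.train import PhaseClass

__all__ = ["RunConfig", "ConfigError", "load_config", "dump_config"]


class ConfigError(ValueError):
    """Configuration file is malformed; the message names the bad key."""


@dataclass
class RunConfig:
    seed: int
    calibration: Calibration
    schedule: VolumeSchedule
    classes: list[PhaseClass]
    filter_enabled: bool = False
    max_radius_vox: int = DEFAULT_MAX_RADIUS_VOX
    threshold_step: int | None = None
    training_box_vox: int | None = None
    training_step: int = 1
    simulation: dict[str, Any] = field(default_factory=dict)

    @property
    def class_names(self) -> list[str]:
        return [c.name for c in self.classes]


def _require_keys(
    section: Mapping[str, Any], allowed: set[str], required: set[str], where: str
) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown key(s) {sorted(unknown)}")
    missing = required - set(section)
    if missing:
        raise ConfigError(f"{where}: missing required key(s) {sorted(missing)}")


def _parse_interval(value: Any, where: str) -> tuple[float, float]:
    if (
        not isinstance(value, (list, tuple))
        or len(value) != 2
        or not all(isinstance(v, (int, float)) for v in value)
    ):
        raise ConfigError(f"{where}: expected [min, max] volume pair, got {value!r}")
    return (float(value[0]), float(value[1]))


_SIMULATION_KEYS = {
    "shape", "n_frames", "n_cells", "n_divisions", "decay", "size_decay",
    "fg_range", "background", "noise_read", "noise_gain", "depth_noise_ramp",
    "min_dist_um", "margin_xy_um", "margin_z_um", "seed",
}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a run configuration from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _require_keys(
        raw,
        allowed={
            "seed", "calibration", "classes", "t_start", "t_end",
            "filter", "threshold", "training", "simulation",
        },
        required={"seed", "calibration", "classes", "t_start", "t_end"},
        where=str(path),
    )

    cal_raw = raw["calibration"]
    _require_keys(cal_raw, {"dx", "dy", "dz"}, {"dx", "dy", "dz"}, "calibration")
    try:
        calibration = Calibration(
            dx=float(cal_raw["dx"]), dy=float(cal_raw["dy"]), dz=float(cal_raw["dz"])
        )
    except ValueError as exc:
        raise ConfigError(f"calibration: {exc}") from exc

    classes: list[PhaseClass] = []
    volumes: dict[str, ClassVolumes] = {}
    if not isinstance(raw["classes"], dict) or not raw["classes"]:
        raise ConfigError("classes: expected a non-empty mapping of class names")
    for name, spec in raw["classes"].items():
        where = f"classes.{name}"
        _require_keys(
            spec, {"volume_start", "volume_end", "no_inclusion"},
            {"volume_start", "volume_end"}, where,
        )
        lo0, hi0 = _parse_interval(spec["volume_start"], f"{where}.volume_start")
        lo1, hi1 = _parse_interval(spec["volume_end"], f"{where}.volume_end")
        try:
            volumes[name] = ClassVolumes(
                v_min_start=lo0, v_max_start=hi0, v_min_end=lo1, v_max_end=hi1
            )
        except ValueError as exc:
            raise ConfigError(f"{where}: {exc}") from exc
        no_incl = spec.get("no_inclusion", [])
        if not isinstance(no_incl, list):
            raise ConfigError(f"{where}.no_inclusion: expected a list of class names")
        classes.append(PhaseClass(name=str(name), no_inclusion=tuple(no_incl)))
    known = {c.name for c in classes}
    for c in classes:
        bad = set(c.no_inclusion) - known
        if bad:
            raise ConfigError(
                f"classes.{c.name}.no_inclusion: unknown class(es) {sorted(bad)}"
            )

    try:
        schedule = VolumeSchedule(
            classes=volumes, t_start=int(raw["t_start"]), t_end=int(raw["t_end"])
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    filt = raw.get("filter", {}) or {}
    _require_keys(filt, {"enabled", "max_radius_vox"}, set(), "filter")
    thr = raw.get("threshold", {}) or {}
    _require_keys(thr, {"step"}, set(), "threshold")
    training = raw.get("training", {}) or {}
    _require_keys(training, {"box_vox", "step"}, set(), "training")
    sim = raw.get("simulation", {}) or {}
    _require_keys(sim, _SIMULATION_KEYS, set(), "simulation")

    step = thr.get("step")
    return RunConfig(
        seed=int(raw["seed"]),
        calibration=calibration,
        schedule=schedule,
        classes=classes,
        filter_enabled=bool(filt.get("enabled", False)),
        max_radius_vox=int(filt.get("max_radius_vox", DEFAULT_MAX_RADIUS_VOX)),
        threshold_step=None if step is None else int(step),
        training_box_vox=(
            None if training.get("box_vox") is None else int(training["box_vox"])
        ),
        training_step=int(training.get("step", 1)),
        simulation=dict(sim),
    )


def dump_config(
    *,
    seed: int,
    calibration: Calibration,
    schedule: VolumeSchedule,
    classes: list[PhaseClass],
    threshold_step: int | None = None,
    path: str | Path,
) -> None:
    """Write a run configuration (e.g. the one a simulation implies)."""
    doc: dict[str, Any] = {
        "seed": seed,
        "calibration": {
            "dx": calibration.dx, "dy": calibration.dy, "dz": calibration.dz
        },
        "t_start": schedule.t_start,
        "t_end": schedule.t_end,
        "classes": {},
    }
    for c in classes:
        cv = schedule.classes[c.name]
        entry: dict[str, Any] = {
            "volume_start": [round(cv.v_min_start, 3), round(cv.v_max_start, 3)],
            "volume_end": [round(cv.v_min_end, 3), round(cv.v_max_end, 3)],
        }
        if c.no_inclusion:
            entry["no_inclusion"] = list(c.no_inclusion)
        doc["classes"][c.name] = entry
    if threshold_step is not None:
        doc["threshold"] = {"step": threshold_step}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
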