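"""Image, calibration, click-table and results I/O.

Conventions
-----------
* Voxel arrays are indexed ``(z, y, x)``; time series are lists of stacks.
* Click CSV files use human-readable ``(t, x, y, z)`` column order; the
  conversion to internal ``(z, y, x)`` happens here and nowhere else.
* Calibration (physical voxel spacing in micrometres) is supplied
  explicitly rather than parsed from TIFF metadata, whose dialects vary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Calibration",
    "ImageStack",
    "TimeSeries",
    "ClickTable",
    "FormatError",
    "read_stack",
    "write_stack",
    "write_label_stack",
    "read_label_stack",
    "read_clicks",
    "write_clicks",
    "find_series_paths",
    "write_records",
]

_CLICK_COLUMNS = ["t", "x", "y", "z", "class", "validated"]


class FormatError(ValueError):
    """Raised for files that do not match the supported grayscale formats."""


@dataclass(frozen=True)
class Calibration:
    """Physical voxel spacing in micrometres.

    ``dx`` and ``dy`` must be equal (square pixels); ``dz`` is usually
    larger because optical sections are coarser than the pixel grid.
    """

    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0 and self.dz > 0):
            raise ValueError("voxel spacings must be positive")
        if abs(self.dx - self.dy) > 1e-9 * max(self.dx, self.dy):
            raise ValueError(
                f"square pixels required: dx={self.dx} differs from dy={self.dy}"
            )

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        return self.dx * self.dy * self.dz

    @property
    def spacing_zyx(self) -> tuple[float, float, float]:
        return (self.dz, self.dy, self.dx)


@dataclass
class ImageStack:
    """A single calibrated 3D grayscale stack, ``data`` indexed (z, y, x)."""

    data: np.ndarray
    calibration: Calibration

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("stack must be 3D with at least one slice")
        if self.data.dtype not in (np.uint8, np.uint16):
            raise FormatError(
                f"unsupported dtype {self.data.dtype}; expected uint8 or uint16"
            )

    @property
    def bit_depth(self) -> int:
        return 8 if self.data.dtype == np.uint8 else 16

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class TimeSeries:
    """An ordered sequence of equally shaped, equally calibrated stacks."""

    frames: list[ImageStack]
    t0: int = 0

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("time series needs at least one frame")
        first = self.frames[0]
        for f in self.frames[1:]:
            if f.shape != first.shape:
                raise ValueError("all frames must share one shape")
            if f.calibration != first.calibration:
                raise ValueError("all frames must share one calibration")

    @property
    def calibration(self) -> Calibration:
        return self.frames[0].calibration

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class ClickTable:
    """Training-sample positions: one row per clicked nucleus centre.

    Stored with human-facing columns ``t, x, y, z, class, validated``;
    coordinates are 0-based voxel indices.
    """

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=_CLICK_COLUMNS)
    )

    def __post_init__(self) -> None:
        missing = [c for c in _CLICK_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"click table missing columns: {missing}")
        self.table = self.table[_CLICK_COLUMNS].reset_index(drop=True)

    def validated_rows(self) -> pd.DataFrame:
        return self.table[self.table["validated"]].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)


def read_stack(path: str | Path, calibration: Calibration) -> ImageStack:
    """Read a grayscale 8/16-bit multi-page TIFF as a calibrated stack.

    Page order is taken as the z order. RGB or floating-point TIFFs are
    rejected with :class:`FormatError`.
    """
    try:
        with tifffile.TiffFile(str(path)) as tif:
            axes = tif.series[0].axes
            data = tif.series[0].asarray()
    except (OSError, ValueError, IndexError) as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if "S" in axes or "C" in axes:
        raise FormatError(f"{path}: RGB/multichannel TIFF not supported (axes {axes})")
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(
            f"{path}: expected a grayscale z-stack, got shape {data.shape}"
        )
    if data.dtype not in (np.uint8, np.uint16):
        raise FormatError(
            f"{path}: unsupported pixel type {data.dtype} (grayscale 8/16-bit only)"
        )
    return ImageStack(data=data, calibration=calibration)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an intensity stack as a multi-page TIFF (one page per slice)."""
    tifffile.imwrite(str(path), stack.data, photometric="minisblack")


def write_label_stack(labels: np.ndarray, path: str | Path) -> None:
    """Write an instance label stack as a 16-bit multi-page TIFF.

    Label 0 is background. Raises if any label exceeds the 16-bit range.
    """
    labels = np.asarray(labels)
    if labels.ndim != 3:
        raise ValueError("label stack must be 3D")
    if labels.min() < 0:
        raise ValueError("labels must be non-negative")
    if labels.max() >= 65536:
        raise ValueError(f"label {int(labels.max())} exceeds 16-bit range")
    tifffile.imwrite(str(path), labels.astype(np.uint16), photometric="minisblack")


def read_label_stack(path: str | Path) -> np.ndarray:
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    return data.astype(np.int64)


def read_clicks(path: str | Path, class_names: Sequence[str] | None = None) -> ClickTable:
    """Parse a click CSV with header ``t,x,y,z,class,validated``.

    Rows with ``validated`` false are retained but flagged. If
    ``class_names`` is given, unknown class labels raise a ``ValueError``
    naming the offending row.
    """
    df = pd.read_csv(path)
    missing = [c for c in _CLICK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: click CSV missing columns {missing}")
    if len(df):
        for col in ("t", "x", "y", "z"):
            df[col] = df[col].astype(int)
        df["class"] = df["class"].astype(str)
        df["validated"] = df["validated"].map(_parse_bool)
        if class_names is not None:
            allowed = set(class_names)
            bad = df.index[~df["class"].isin(allowed)]
            if len(bad):
                i = int(bad[0])
                raise ValueError(
                    f"{path}: row {i}: unknown class {df.loc[i, 'class']!r} "
                    f"(configured classes: {sorted(allowed)})"
                )
    else:
        df = pd.DataFrame(columns=_CLICK_COLUMNS)
    return ClickTable(table=df)


def _parse_bool(v: object) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValueError(f"cannot parse boolean value {v!r} in 'validated' column")


def write_clicks(clicks: ClickTable, path: str | Path) -> None:
    clicks.table.to_csv(path, index=False)


def find_series_paths(directory: str | Path, prefix: str = "") -> list[Path]:
    """List per-timepoint TIFFs following the ``{prefix}_t{index}.tif`` naming.

    Files are sorted by their numeric time index so lexical quirks in zero
    padding cannot reorder the series.
    """
    directory = Path(directory)
    pattern = re.compile(re.escape(prefix) + r".*_t(\d+)\.tiff?$") if prefix else re.compile(
        r".*_t(\d+)\.tiff?$"
    )
    hits: list[tuple[int, Path]] = []
    for p in sorted(directory.iterdir()):
        m = pattern.match(p.name)
        if m:
            hits.append((int(m.group(1)), p))
    hits.sort(key=lambda x: x[0])
    return [p for _, p in hits]


RESULT_COLUMNS = [
    "label", "t", "class", "probability", "threshold", "volume_um3",
    "cx", "cy", "cz",
    "compactness", "sphericity", "elongation", "flatness", "ratio",
    "m1", "m2", "m3", "m4", "m5", "m6",
    "flags",
]


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    """Write a per-timepoint results table with the documented column order."""
    out = records.reindex(columns=RESULT_COLUMNS)
    out.to_csv(path, index=False)
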