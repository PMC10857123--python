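"""Pressure-frame data model and plain-text readers/writers.

A recording is a directory of one CSV matrix per frame (``frame_000.csv``,
rows run cranial to caudal, columns subject-left to subject-right, no
header) plus an optional ``meta.json`` sidecar with keys ``shape``,
``pixel_mm``, ``sample_rate_hz``, ``subject_id`` and ``repetition_id``.
Missing sidecar fields fall back to the sensor defaults (160 x 100 grid,
5.1 mm per pixel edge, 10 Hz).

Row and column indices are 0-based throughout the package; reports convert
to the 1-based convention used in the literature.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import FormatError, InputError

DEFAULT_SHAPE = (160, 100)
DEFAULT_PIXEL_MM = 5.1
DEFAULT_SAMPLE_RATE_HZ = 10.0

_FRAME_RE = re.compile(r"frame_(\d+)\.csv$")


@dataclass
class PressureFrame:
    """One pressure matrix in raw sensor units (prv), all values >= 0.

    Row index j runs cranial to caudal, column index i runs subject-left to
    subject-right.
    """

    values: np.ndarray
    pixel_mm: float = DEFAULT_PIXEL_MM

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("frame must be a 2-D matrix")
        if not np.isfinite(self.values).all():
            raise FormatError("frame contains non-finite values")
        if (self.values < 0).any():
            j, i = np.argwhere(self.values < 0)[0]
            raise FormatError(f"negative pressure at row {j}, column {i}")
        if self.pixel_mm <= 0:
            raise FormatError("pixel_mm must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def axis_col(self) -> float:
        """Continuous column coordinate of the mirror axis (between the two
        central columns for an even-width grid)."""
        return (self.n_cols - 1) / 2.0

    def mean_intensity(self) -> float:
        return float(self.values.mean())

    def copy(self, values: np.ndarray | None = None) -> "PressureFrame":
        v = self.values.copy() if values is None else values
        return PressureFrame(values=v, pixel_mm=self.pixel_mm)


@dataclass
class Recording:
    """An ordered sequence of frames from one measurement."""

    frames: list[PressureFrame]
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    subject_id: str = ""
    repetition_id: str = ""

    def __post_init__(self) -> None:
        if not self.frames:
            raise InputError("recording holds no frames")
        shape = self.frames[0].values.shape
        pixel_mm = self.frames[0].pixel_mm
        for k, f in enumerate(self.frames):
            if f.values.shape != shape:
                raise FormatError(f"frame {k} shape {f.values.shape} != {shape}")
            if f.pixel_mm != pixel_mm:
                raise FormatError(f"frame {k} pixel_mm differs")

    def __len__(self) -> int:
        return len(self.frames)


def select_medial_frame(recording: Recording) -> PressureFrame:
    """Frame whose mean intensity has ascending rank ceil(n/2).

    For an odd frame count this is the median mean; for an even count the
    lower of the two middle ranks is taken (deterministic, no averaging of
    frames). Ties in the means are broken by frame index via a stable sort.
    """
    means = np.array([f.mean_intensity() for f in recording.frames])
    order = np.argsort(means, kind="stable")
    rank = math.ceil(len(means) / 2) - 1  # 0-based
    return recording.frames[int(order[rank])]


def _read_frame_file(path: Path, pixel_mm: float) -> PressureFrame:
    rows: list[list[float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            row = [float(tok) for tok in line.split(",")]
        except ValueError as exc:
            raise FormatError(f"{path.name}, row {lineno}: {exc}") from None
        rows.append(row)
    if not rows:
        raise FormatError(f"{path.name}: empty frame file")
    width = len(rows[0])
    for lineno, row in enumerate(rows, start=1):
        if len(row) != width:
            raise FormatError(
                f"{path.name}, row {lineno}: ragged row ({len(row)} != {width} values)"
            )
    values = np.array(rows, dtype=float)
    bad = np.argwhere(~np.isfinite(values) | (values < 0))
    if bad.size:
        j, i = bad[0]
        raise FormatError(
            f"{path.name}, row {j + 1}, column {i + 1}: "
            f"invalid pressure value {values[j, i]!r}"
        )
    return PressureFrame(values=values, pixel_mm=pixel_mm)


def read_recording(path: str | Path) -> Recording:
    """Read a recording directory written by :func:`write_recording`."""
    path = Path(path)
    if not path.is_dir():
        raise InputError(f"not a directory: {path}")
    meta: dict = {}
    meta_path = path / "meta.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    pixel_mm = float(meta.get("pixel_mm", DEFAULT_PIXEL_MM))

    frame_files = sorted(
        (p for p in path.iterdir() if _FRAME_RE.search(p.name)),
        key=lambda p: int(_FRAME_RE.search(p.name).group(1)),
    )
    if not frame_files:
        raise InputError(f"no frame_*.csv files in {path}")
    frames = [_read_frame_file(p, pixel_mm) for p in frame_files]

    if "shape" in meta:
        shape = tuple(meta["shape"])
        if frames[0].values.shape != shape:
            raise FormatError(
                f"sidecar shape {shape} != frame shape {frames[0].values.shape}"
            )
    return Recording(
        frames=frames,
        sample_rate_hz=float(meta.get("sample_rate_hz", DEFAULT_SAMPLE_RATE_HZ)),
        subject_id=str(meta.get("subject_id", "")),
        repetition_id=str(meta.get("repetition_id", "")),
    )


def write_recording(recording: Recording, path: str | Path) -> Path:
    """Write a recording as CSV frames plus a JSON sidecar; lossless for
    integer-valued matrices (uses repr-exact float formatting)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for k, frame in enumerate(recording.frames):
        np.savetxt(path / f"frame_{k:03d}.csv", frame.values, fmt="%.17g", delimiter=",")
    meta = {
        "shape": list(recording.frames[0].values.shape),
        "pixel_mm": recording.frames[0].pixel_mm,
        "sample_rate_hz": recording.sample_rate_hz,
        "subject_id": recording.subject_id,
        "repetition_id": recording.repetition_id,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    return path
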