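"""Time-lapse frame container and disk I/O.

A :class:`FrameSeries` holds the raw grayscale frames of one levitation
run together with the acquisition times, the pixel-to-mm calibration and
the region of interest covering the inner part of the cuvette.  Frames
are stored with the usual image convention (row 0 at the top); the
processing layer converts to bottom-up heights.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["Roi", "FrameSeries", "save_frames", "load_frames"]


@dataclass(frozen=True)
class Roi:
    """Pixel rectangle, half-open: rows [row_start, row_stop), cols likewise."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def __post_init__(self) -> None:
        if self.row_stop <= self.row_start or self.col_stop <= self.col_start:
            raise ValueError("ROI must be non-degenerate")
        if min(self.row_start, self.col_start) < 0:
            raise ValueError("ROI indices must be non-negative")

    @property
    def n_rows(self) -> int:
        return self.row_stop - self.row_start

    @property
    def n_cols(self) -> int:
        return self.col_stop - self.col_start

    def to_dict(self) -> dict:
        return {
            "row_start": self.row_start,
            "row_stop": self.row_stop,
            "col_start": self.col_start,
            "col_stop": self.col_stop,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Roi":
        return cls(**d)


@dataclass
class FrameSeries:
    frames: np.ndarray            # (T, H, W) float
    times: np.ndarray             # (T,) seconds, strictly increasing
    pixel_to_mm: float            # mm per pixel (vertical)
    roi: Roi
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) stack")
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.pixel_to_mm <= 0:
            raise ValueError("pixel_to_mm must be > 0")
        _, h, w = self.frames.shape
        if self.roi.row_stop > h or self.roi.col_stop > w:
            raise ValueError("ROI exceeds frame bounds")

    def __len__(self) -> int:
        return len(self.frames)

    def frame_at(self, time_s: float):
        """Frame index nearest to ``time_s`` and the time gap to it."""
        idx = int(np.argmin(np.abs(self.times - time_s)))
        return idx, abs(float(self.times[idx]) - time_s)


_FRAME_RE = re.compile(r"frame_(\d+)\.(tif|tiff|png)$", re.IGNORECASE)


def save_frames(series: FrameSeries, out_dir: str | Path) -> Path:
    """Write a series as numbered 16-bit TIFFs plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lo = float(series.frames.min())
    hi = float(series.frames.max())
    scale = 65535.0 / (hi - lo) if hi > lo else 1.0
    for i, frame in enumerate(series.frames):
        data = np.clip((frame - lo) * scale, 0, 65535).astype(np.uint16)
        tifffile.imwrite(out / f"frame_{i:04d}.tif", data)
    sidecar = {
        "times_s": series.times.tolist(),
        "pixel_to_mm": series.pixel_to_mm,
        "roi": series.roi.to_dict(),
        "intensity_offset": lo,
        "intensity_scale": scale,
        "metadata": series.metadata,
    }
    (out / "series.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return out


def load_frames(
    path: str | Path,
    roi: Roi | None = None,
    pixel_to_mm: float | None = None,
) -> FrameSeries:
    """Read a frame directory written by :func:`save_frames`.

    ``roi`` and ``pixel_to_mm`` override the sidecar values; if there is
    no sidecar they are required.
    """
    p = Path(path)
    if not p.is_dir():
        raise IOError(f"not a frame directory: {p}")
    entries = sorted(
        (int(m.group(1)), f)
        for f in p.iterdir()
        if (m := _FRAME_RE.search(f.name))
    )
    if not entries:
        raise IOError(f"no frame images found in {p}")

    sidecar: dict = {}
    sidecar_path = p / "series.json"
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())

    arrays = []
    bad = []
    for _, f in entries:
        try:
            arrays.append(np.asarray(tifffile.imread(f), dtype=float))
        except Exception:
            bad.append(f.name)
    if bad:
        raise IOError(f"unreadable frames: {bad}")
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent frame shapes: {sorted(shapes)}")
    stack = np.stack(arrays)
    if "intensity_scale" in sidecar and sidecar["intensity_scale"]:
        stack = stack / sidecar["intensity_scale"] + sidecar.get("intensity_offset", 0.0)

    times = np.asarray(sidecar.get("times_s", np.arange(len(stack))), dtype=float)
    if len(times) != len(stack):
        raise ValueError("sidecar times do not match frame count")
    if pixel_to_mm is None:
        pixel_to_mm = sidecar.get("pixel_to_mm")
        if pixel_to_mm is None:
            raise ValueError("pixel_to_mm required (absent from sidecar)")
    if roi is None:
        roi = (
            Roi.from_dict(sidecar["roi"])
            if "roi" in sidecar
            else Roi(0, stack.shape[1], 0, stack.shape[2])
        )
    return FrameSeries(
        frames=stack,
        times=times,
        pixel_to_mm=float(pixel_to_mm),
        roi=roi,
        metadata=sidecar.get("metadata", {}),
    )
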