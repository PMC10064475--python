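"""Reading and writing frame sequences.

The canonical on-disk form is a directory of 8-bit grayscale PNG frames
with zero-padded numeric filenames (``00000.png``, ``00001.png``, ...).
Animated GIF is supported as a single-file container; other video
containers (MP4/AVI) are attempted through imageio and reported as an I/O
error when no backend is available.

Colour inputs are converted to luminance with Rec.601 weights
(0.299 R + 0.587 G + 0.114 B) — the model is luminance-driven.
"""

from __future__ import annotations

import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .stimuli import FrameSequence

__all__ = ["FrameIOError", "read_frames", "write_frames", "to_luminance"]

_VIDEO_EXTS = {".gif", ".mp4", ".avi", ".mov", ".mkv", ".webm"}
_REC601 = np.array([0.299, 0.587, 0.114])


class FrameIOError(IOError):
    """A frame sequence could not be read or written."""


def to_luminance(img: np.ndarray) -> np.ndarray:
    """Convert an image array to float luminance in [0, 1] (Rec.601)."""
    arr = np.asarray(img)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float64)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _REC601
    elif arr.ndim != 2:
        raise FrameIOError(f"cannot interpret image of shape {arr.shape}")
    return np.clip(arr, 0.0, 1.0)


def _is_video_path(path: Path) -> bool:
    return path.suffix.lower() in _VIDEO_EXTS


def read_frames(path, frame_rate: float = 30.0) -> FrameSequence:
    """Read a PNG frame directory or a video file into a FrameSequence.

    For directories, files are taken in numeric order of their stem. All
    frames must share one shape. ``frame_rate`` is attached as metadata
    (PNG directories carry none of their own).
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() == ".png"),
            key=lambda p: int(re.sub(r"\D", "", p.stem) or -1),
        )
        if not files:
            raise FrameIOError(f"no PNG frames found in {path}")
        frames = []
        for p in files:
            try:
                frames.append(to_luminance(iio.imread(p)))
            except (OSError, ValueError) as exc:
                raise FrameIOError(f"cannot read frame {p}: {exc}") from exc
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise FrameIOError(f"inconsistent frame shapes in {path}: {sorted(shapes)}")
        return FrameSequence(np.stack(frames), frame_rate)
    if not path.exists():
        raise FrameIOError(f"no such file or directory: {path}")
    if _is_video_path(path):
        try:
            raw = iio.imread(path, index=None)
        except Exception as exc:  # backend-dependent error types
            raise FrameIOError(f"cannot read video {path}: {exc}") from exc
        raw = np.asarray(raw)
        if raw.ndim == 2:
            raw = raw[None]
        frames = np.stack([to_luminance(f) for f in raw])
        return FrameSequence(frames, frame_rate)
    raise FrameIOError(f"unsupported input {path}: expected a directory or video file")


def write_frames(seq: FrameSequence, path) -> Path:
    """Write a FrameSequence as 8-bit grayscale PNGs (dir) or a video file.

    Directory output uses zero-padded numeric filenames; values are
    quantised to 8 bits, so a round trip agrees within 1/255.
    """
    path = Path(path)
    data8 = np.round(np.clip(seq.frames, 0, 1) * 255).astype(np.uint8)
    if _is_video_path(path):
        path.parent.mkdir(parents=True, exist_ok=True)
        try:
            if path.suffix.lower() == ".gif":
                iio.imwrite(path, data8, duration=1000.0 / seq.frame_rate, loop=0)
            else:
                iio.imwrite(path, data8, fps=seq.frame_rate)
        except Exception as exc:
            raise FrameIOError(
                f"cannot write video {path} (no backend for {path.suffix}?): {exc}"
            ) from exc
        return path
    path.mkdir(parents=True, exist_ok=True)
    width = max(5, len(str(len(seq) - 1)))
    for t in range(len(seq)):
        iio.imwrite(path / f"{t:0{width}d}.png", data8[t])
    return path


def write_rgb_frames(frames_rgb: np.ndarray, path, frame_rate: float = 30.0) -> Path:
    """Write a (T, H, W, 3) uint8 RGB stack like :func:`write_frames`."""
    path = Path(path)
    data = np.asarray(frames_rgb, dtype=np.uint8)
    if _is_video_path(path):
        path.parent.mkdir(parents=True, exist_ok=True)
        try:
            if path.suffix.lower() == ".gif":
                iio.imwrite(path, data, duration=1000.0 / frame_rate, loop=0)
            else:
                iio.imwrite(path, data, fps=frame_rate)
        except Exception as exc:
            raise FrameIOError(f"cannot write video {path}: {exc}") from exc
        return path
    path.mkdir(parents=True, exist_ok=True)
    width = max(5, len(str(len(data) - 1)))
    for t in range(len(data)):
        iio.imwrite(path / f"{t:0{width}d}.png", data[t])
    return path
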