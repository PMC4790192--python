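"""Reading confocal frame sequences and managing regions of interest.

Acquisitions arrive as one directory per embryo, each holding a numbered
sequence of single-image TIFF files (or one multi-page TIFF), every frame
an 8-bit RGB image: green = endocardium reporter, red = blood cells, and
a gray phase image derivable as luminance. Frame timing is not reliably
stored in the TIFFs, so the frame interval is supplied by the caller
(default 15 ms, the shortest interval the acquisition hardware achieves).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "AcquisitionMeta",
    "FrameStack",
    "ROI",
    "ROI_LABELS",
    "load_frame_stack",
    "split_channel",
    "discover_embryos",
    "crop_roi",
    "read_roi_file",
]

DEFAULT_FRAME_INTERVAL_S = 0.015
MIN_FRAMES = 8

ROI_LABELS = ("atrium", "ventricle", "bulbous_arteriosus", "whole")

#: Rec. 601 luma weights used for the derived gray (phase-like) channel.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class AcquisitionMeta:
    """Timing and geometry of one acquisition.

    ``total_duration`` spans first to last frame, i.e. (n_frames - 1)
    intervals; ``effective_fps`` is the frame count over that span, which
    reproduces the nominal 67 frames/s for a 304-frame, 15 ms acquisition.
    """

    frame_interval: float  # seconds per frame
    n_frames: int
    frame_height: int
    frame_width: int

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be positive")
        if self.frame_height < 1 or self.frame_width < 1:
            raise ValueError("frame dimensions must be positive")

    @property
    def total_duration(self) -> float:
        """Seconds from the first to the last frame."""
        return (self.n_frames - 1) * self.frame_interval

    @property
    def effective_fps(self) -> float:
        if self.n_frames < 2:
            raise ValueError("effective_fps undefined for a single frame")
        return self.n_frames / self.total_duration

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class FrameStack:
    """An ordered RGB frame sequence for one embryo.

    ``frames`` is a uint8 array indexed (time, row, column, rgb).
    """

    frames: np.ndarray
    meta: AcquisitionMeta
    embryo_id: str = ""

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if f.ndim != 4 or f.shape[3] != 3:
            raise ValueError("frames must be a (time, row, col, 3) RGB stack")
        if f.dtype != np.uint8:
            raise ValueError("frames must be 8-bit (uint8)")
        if f.shape[0] != self.meta.n_frames:
            raise ValueError("frame count disagrees with metadata")
        if f.shape[1:3] != (self.meta.frame_height, self.meta.frame_width):
            raise ValueError("frame shape disagrees with metadata")
        self.frames = f

    @property
    def n_frames(self) -> int:
        return self.meta.n_frames


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest, 0-based, half-open.

    Rows ``[top, top + height)``, columns ``[left, left + width)``.
    """

    top: int
    left: int
    height: int
    width: int
    label: str = "whole"

    def __post_init__(self) -> None:
        if self.label not in ROI_LABELS:
            raise ValueError(
                f"unknown ROI label {self.label!r}; expected one of {ROI_LABELS}"
            )
        if self.height < 4 or self.width < 4:
            raise ValueError("ROI height and width must be >= 4 pixels")
        if self.top < 0 or self.left < 0:
            raise ValueError("ROI top/left must be non-negative")

    @property
    def bottom(self) -> int:
        return self.top + self.height

    @property
    def right(self) -> int:
        return self.left + self.width

    def validate_within(self, frame_height: int, frame_width: int) -> None:
        if self.top < 0:
            raise ValueError("ROI out of bounds at top edge")
        if self.left < 0:
            raise ValueError("ROI out of bounds at left edge")
        if self.bottom > frame_height:
            raise ValueError("ROI out of bounds at bottom edge")
        if self.right > frame_width:
            raise ValueError("ROI out of bounds at right edge")


_NUM_RE = re.compile(r"(\d+)")


def _natural_key(name: str):
    """Sort key treating digit runs numerically, so frame2 < frame10."""
    return tuple(
        int(tok) if tok.isdigit() else tok.lower()
        for tok in _NUM_RE.split(name)
    )


def _list_tiffs(directory: Path) -> list[Path]:
    files = [
        p
        for p in directory.iterdir()
        if p.is_file() and p.suffix.lower() in (".tif", ".tiff")
    ]
    return sorted(files, key=lambda p: _natural_key(p.name))


def _to_uint8(arr: np.ndarray, source: str) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr
    warnings.warn(
        f"{source}: converting {arr.dtype} frames to 8-bit", stacklevel=3
    )
    if arr.dtype == np.uint16:
        return (arr // 257).astype(np.uint8)
    arr = np.asarray(arr, dtype=np.float64)
    lo, hi = arr.min(), arr.max()
    if hi > lo:
        arr = (arr - lo) / (hi - lo) * 255.0
    return np.clip(np.round(arr), 0, 255).astype(np.uint8)


def _ensure_rgb(frame: np.ndarray) -> np.ndarray:
    if frame.ndim == 2:
        return np.repeat(frame[:, :, None], 3, axis=2)
    if frame.ndim == 3 and frame.shape[2] >= 3:
        return frame[:, :, :3]
    raise ValueError(f"unsupported frame shape {frame.shape}")


def load_frame_stack(
    directory,
    frame_interval: float = DEFAULT_FRAME_INTERVAL_S,
    embryo_id: str | None = None,
    min_frames: int = MIN_FRAMES,
    channel_layout: str = "rgb",
) -> FrameStack:
    """Load one embryo's TIFF frame sequence in temporal order.

    Temporal order is the natural sort of filenames (digit runs compared
    numerically). A directory holding a single multi-page TIFF is
    auto-detected and read page by page. ``channel_layout='split_folders'``
    reads per-channel subdirectories ``red``/``green`` (and optionally
    ``gray``) of single-channel frames and recomposes RGB.

    Raises ``ValueError`` with "no frames found" when the directory is
    missing, empty, or holds fewer than ``min_frames`` frames, and
    "heterogeneous stack" when frame dimensions differ.
    """
    directory = Path(directory)
    eid = embryo_id if embryo_id is not None else directory.name

    if channel_layout == "split_folders":
        frames = _load_split_folders(directory)
    elif channel_layout == "rgb":
        frames = _load_rgb_layout(directory)
    else:
        raise ValueError(f"unknown channel_layout {channel_layout!r}")

    if len(frames) < min_frames:
        raise ValueError(
            f"no frames found: {len(frames)} frame(s) in {directory}, "
            f"minimum is {min_frames}"
        )

    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise ValueError(f"heterogeneous stack: frame shapes {sorted(shapes)}")

    stack = np.stack([_ensure_rgb(f) for f in frames])
    meta = AcquisitionMeta(
        frame_interval=frame_interval,
        n_frames=stack.shape[0],
        frame_height=stack.shape[1],
        frame_width=stack.shape[2],
    )
    return FrameStack(frames=stack, meta=meta, embryo_id=eid)


def _load_rgb_layout(directory: Path) -> list[np.ndarray]:
    if not directory.is_dir():
        raise ValueError(f"no frames found: {directory} is not a directory")
    files = _list_tiffs(directory)
    if not files:
        raise ValueError(f"no frames found in {directory}")
    if len(files) == 1:
        pages = tifffile.imread(files[0])
        if pages.ndim >= 3 and (pages.ndim == 4 or pages.shape[-1] not in (3, 4)):
            # multi-page file: leading axis is time
            return [_to_uint8(p, files[0].name) for p in pages]
        return [_to_uint8(pages, files[0].name)]
    return [_to_uint8(tifffile.imread(f), f.name) for f in files]


def _load_split_folders(directory: Path) -> list[np.ndarray]:
    red_dir, green_dir = directory / "red", directory / "green"
    if not (red_dir.is_dir() and green_dir.is_dir()):
        raise ValueError(
            f"no frames found: {directory} lacks red/ and green/ subfolders"
        )
    red = _load_rgb_layout(red_dir)
    green = _load_rgb_layout(green_dir)
    if len(red) != len(green):
        raise ValueError("heterogeneous stack: channel frame counts differ")
    frames = []
    for r, g in zip(red, green):
        r2 = r if r.ndim == 2 else r[:, :, 0]
        g2 = g if g.ndim == 2 else g[:, :, 1]
        if r2.shape != g2.shape:
            raise ValueError("heterogeneous stack: channel shapes differ")
        rgb = np.zeros(r2.shape + (3,), dtype=np.uint8)
        rgb[:, :, 0] = r2
        rgb[:, :, 1] = g2
        frames.append(rgb)
    return frames


def split_channel(stack: FrameStack, channel: str) -> np.ndarray:
    """Extract one channel as a (time, row, col) uint8 stack.

    ``green`` and ``red`` are the RGB indices 1 and 0; ``gray`` is the
    luminance of the RGB triplet (equal channels map to themselves).
    """
    if channel == "green":
        return stack.frames[:, :, :, 1].copy()
    if channel == "red":
        return stack.frames[:, :, :, 0].copy()
    if channel == "gray":
        lum = stack.frames.astype(np.float64) @ _LUMA
        return np.clip(np.round(lum), 0, 255).astype(np.uint8)
    raise ValueError(f"unknown channel {channel!r}; expected green, red or gray")


def discover_embryos(root) -> list[tuple[str, Path]]:
    """List (embryo_id, directory) for every subfolder holding TIFF frames.

    One acquisition run stores each embryo of a multiwell plate in its own
    subfolder; any number of embryos is allowed. Order is deterministic
    (sorted by subfolder name). A root with no qualifying subfolder yields
    an empty list with a warning rather than an error, so batch callers
    can decide how to proceed.
    """
    root = Path(root)
    if not root.is_dir():
        raise ValueError(f"root {root} does not exist")
    found = []
    for sub in sorted(root.iterdir(), key=lambda p: p.name):
        if sub.is_dir() and _list_tiffs(sub):
            found.append((sub.name, sub))
    if not found:
        warnings.warn(f"no embryo subfolders with TIFF frames under {root}")
    return found


def crop_roi(stack: FrameStack, roi: ROI) -> FrameStack:
    """Crop every frame to the ROI; timing is unchanged."""
    roi.validate_within(stack.meta.frame_height, stack.meta.frame_width)
    cropped = stack.frames[:, roi.top : roi.bottom, roi.left : roi.right, :]
    meta = AcquisitionMeta(
        frame_interval=stack.meta.frame_interval,
        n_frames=stack.meta.n_frames,
        frame_height=roi.height,
        frame_width=roi.width,
    )
    return FrameStack(frames=cropped.copy(), meta=meta, embryo_id=stack.embryo_id)


def read_roi_file(path) -> list[ROI]:
    """Parse a plain-text ROI definition file.

    One ROI per line: ``label top left height width`` (whitespace
    separated; ``#`` starts a comment).
    """
    rois = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(
                f"{path}:{lineno}: expected 'label top left height width'"
            )
        label = parts[0]
        try:
            top, left, height, width = (int(v) for v in parts[1:])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer geometry") from exc
        rois.append(ROI(top=top, left=left, height=height, width=width, label=label))
    return rois
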