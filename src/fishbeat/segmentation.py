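"""Mode 1 ("area variation"): per-frame chamber segmentation.

The GFP-labelled endocardium is the bright structure in the green channel.
Each frame is binarized at the deepest local minimum of its smoothed
intensity histogram, cleaned with 3x3 morphological closing then opening,
reduced to its largest connected component, and outlined by Moore-neighbour
boundary tracing.  The pixel count enclosed by the traced contour, frame by
frame, is the area chronology whose dominant frequency is the heart rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from skimage.morphology import closing as _closing, opening as _opening

from .io_acquisition import AcquisitionMeta, ROI
from .spectral import Chronology

__all__ = [
    "AreaSeries",
    "Contour",
    "histogram_threshold",
    "binarize",
    "morphological_filter",
    "find_seed_point",
    "trace_boundary",
    "enclosed_area",
    "area_chronology",
]

HIST_SMOOTH_WINDOW = 9
MORPH_ITERATIONS = 1
MAX_FAIL_FRACTION = 0.25

_SQUARE3 = np.ones((3, 3), dtype=bool)

# 8-neighbour offsets in clockwise order starting due west, for an image
# with row increasing downward (clockwise on screen).
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]
_MOORE_INDEX = {off: k for k, off in enumerate(_MOORE)}


@dataclass
class Contour:
    """Ordered boundary pixels of one object, 8-connected steps."""

    points: list[tuple[int, int]]
    closed: bool = True

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class AreaSeries(Chronology):
    """Enclosed chamber area (pixel count) per frame."""


def histogram_threshold(
    gray_frame: np.ndarray, smooth_window: int = HIST_SMOOTH_WINDOW
) -> int:
    """Threshold at the deepest histogram valley between the two main modes.

    The 256-bin intensity histogram is smoothed with a moving average
    (window ``smooth_window`` bins), its two most prominent modes located,
    and the deepest local minimum strictly between them returned; ties go
    to the lower intensity.  A frame whose histogram shows no two modes
    raises "no bimodal structure" so the caller may fall back to a fixed
    threshold.
    """
    frame = np.asarray(gray_frame)
    hist = np.bincount(frame.ravel().astype(np.int64), minlength=256).astype(float)
    if np.count_nonzero(hist) < 2:
        raise ValueError("no bimodal structure: frame has < 2 intensity values")

    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        smooth = np.convolve(hist, kernel, mode="same")
    else:
        smooth = hist

    # pad so modes at intensity 0 or 255 register as peaks
    padded = np.concatenate(([0.0], smooth, [0.0]))
    peaks, props = find_peaks(padded, prominence=0.0, plateau_size=1)
    if len(peaks) < 2:
        raise ValueError("no bimodal structure in intensity histogram")
    order = np.argsort(props["prominences"])[::-1]
    m1, m2 = sorted(int(peaks[i]) - 1 for i in order[:2])
    if m2 - m1 < 2:
        raise ValueError("no bimodal structure: modes not separated")

    between = smooth[m1 + 1 : m2]
    return int(m1 + 1 + int(np.argmin(between)))


def binarize(gray_frame: np.ndarray, threshold: int) -> np.ndarray:
    """Foreground = pixels strictly brighter than the threshold."""
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must be in [0, 255]")
    return np.asarray(gray_frame) > threshold


def morphological_filter(
    mask: np.ndarray, n_iter: int = MORPH_ITERATIONS
) -> np.ndarray:
    """Closing then opening with a 3x3 square structuring element.

    Closing first fills single-pixel holes without sacrificing thin chamber
    walls; the subsequent opening removes speckle.  A mask emptied by the
    filter raises "object lost in morphology".
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("morphological_filter requires a non-empty mask")
    out = mask
    for _ in range(n_iter):
        out = _closing(out, _SQUARE3)
    for _ in range(n_iter):
        out = _opening(out, _SQUARE3)
    if not out.any():
        raise ValueError("object lost in morphology")
    return out


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_SQUARE3)
    if n == 0:
        raise ValueError("empty mask: no connected component")
    if n == 1:
        return mask.astype(bool)
    sizes = np.bincount(labels.ravel())[1:]
    return labels == (int(np.argmax(sizes)) + 1)


def find_seed_point(mask: np.ndarray) -> tuple[int, int]:
    """First pixel of the largest component in row-then-column scan order.

    The scan guarantees the returned pixel lies on the object boundary
    (its west neighbour is background), making it a valid tracing start.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: no seed point")
    comp = _largest_component(mask)
    rows, cols = np.nonzero(comp)
    i = 0  # np.nonzero is already row-major ordered
    return int(rows[i]), int(cols[i])


def _is_boundary(mask: np.ndarray, r: int, c: int) -> bool:
    h, w = mask.shape
    if not mask[r, c]:
        return False
    for dr, dc in _MOORE:
        rr, cc = r + dr, c + dc
        if rr < 0 or rr >= h or cc < 0 or cc >= w or not mask[rr, cc]:
            return True
    return False


def trace_boundary(mask: np.ndarray, seed: tuple[int, int]) -> Contour:
    """Moore-neighbour tracing with Jacob's stopping criterion.

    Starting at ``seed``, the 8-neighbourhood is scanned clockwise from the
    backtrack pixel; the first foreground pixel becomes the next contour
    point.  Tracing stops when the start pixel is re-entered from the start
    direction, yielding a closed clockwise outer contour.
    """
    mask = np.asarray(mask, dtype=bool)
    r0, c0 = seed
    h, w = mask.shape
    if not (0 <= r0 < h and 0 <= c0 < w) or not mask[r0, c0]:
        raise ValueError("seed is not a foreground pixel")
    if not _is_boundary(mask, r0, c0):
        raise ValueError("seed is not on the object boundary")

    def fg(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and mask[r, c]

    # initial backtrack: a background Moore-neighbour, preferring due west
    b_dir = None
    for k in range(8):
        dr, dc = _MOORE[k]
        if not fg(r0 + dr, c0 + dc):
            b_dir = k
            break
    assert b_dir is not None  # guaranteed by the boundary check

    start = (r0, c0)
    points = [start]
    cur = start
    first_step: tuple[int, int] | None = None
    max_steps = 8 * (int(mask.sum()) + 8)  # safety bound

    for _ in range(max_steps):
        # scan the Moore neighbourhood clockwise, starting just past the
        # backtrack pixel; remember the last background pixel examined
        found = None
        prev_bg_dir = b_dir
        for k in range(1, 9):
            d = (b_dir + k) % 8
            dr, dc = _MOORE[d]
            nr, nc = cur[0] + dr, cur[1] + dc
            if fg(nr, nc):
                found = (d, nr, nc)
                break
            prev_bg_dir = d
        if found is None:  # isolated pixel
            return Contour(points=points, closed=True)
        d, nr, nc = found
        if cur == start:
            if first_step is None:
                first_step = (nr, nc)
            elif (nr, nc) == first_step:
                # Jacob's criterion: the start pixel is left in the same
                # direction as on the first step -> the loop is complete
                return Contour(points=points, closed=True)
        bg = (cur[0] + _MOORE[prev_bg_dir][0], cur[1] + _MOORE[prev_bg_dir][1])
        # new backtrack = that background pixel, expressed from the new pixel
        # (consecutive ring positions are mutually 8-adjacent)
        cur = (nr, nc)
        b_dir = _MOORE_INDEX[(bg[0] - nr, bg[1] - nc)]
        if cur != start:  # the start pixel is recorded once, up front
            points.append(cur)
    raise RuntimeError("boundary tracing failed to terminate")


def _contour_mask(contour: Contour, shape: tuple[int, int]) -> np.ndarray:
    raster = np.zeros(shape, dtype=bool)
    pts = np.asarray(contour.points)
    raster[pts[:, 0], pts[:, 1]] = True
    return raster


def enclosed_area(contour: Contour, shape: tuple[int, int]) -> int:
    """Pixels inside or on the contour (contour rasterized, interior filled)."""
    if not contour.closed:
        raise ValueError("enclosed_area requires a closed contour")
    raster = _contour_mask(contour, shape)
    return int(ndimage.binary_fill_holes(raster).sum())


def segment_frame(
    gray_frame: np.ndarray,
    smooth_window: int = HIST_SMOOTH_WINDOW,
    morph_iterations: int = MORPH_ITERATIONS,
    fixed_threshold_fallback: int | None = None,
) -> tuple[int, Contour, np.ndarray]:
    """Full single-frame pipeline: threshold, binarize, filter, trace.

    Returns (enclosed area, contour, filtered mask of the traced component).
    """
    try:
        thr = histogram_threshold(gray_frame, smooth_window=smooth_window)
    except ValueError:
        if fixed_threshold_fallback is None:
            raise
        thr = fixed_threshold_fallback
    mask = binarize(gray_frame, thr)
    if not mask.any():
        raise ValueError("segmentation found no foreground")
    mask = morphological_filter(mask, n_iter=morph_iterations)
    comp = _largest_component(mask)
    seed = find_seed_point(comp)
    contour = trace_boundary(comp, seed)
    return enclosed_area(contour, comp.shape), contour, comp


def area_chronology(
    green_stack: np.ndarray,
    meta: AcquisitionMeta,
    roi: ROI | None = None,
    smooth_window: int = HIST_SMOOTH_WINDOW,
    morph_iterations: int = MORPH_ITERATIONS,
    fixed_threshold_fallback: int | None = None,
    max_fail_fraction: float = MAX_FAIL_FRACTION,
) -> AreaSeries:
    """Enclosed chamber area per frame across the acquisition.

    The threshold is recomputed independently for every frame so the series
    is insensitive to slow illumination drift.  Frames whose segmentation
    fails are filled by linear interpolation from their neighbours and
    flagged; more than ``max_fail_fraction`` failures raise
    "unreliable area series".
    """
    stack = np.asarray(green_stack)
    if stack.ndim != 3:
        raise ValueError("expected a single-channel (time, row, col) stack")
    if stack.shape[0] < 8:
        raise ValueError("area_chronology requires >= 8 frames")
    if roi is not None:
        roi.validate_within(stack.shape[1], stack.shape[2])
        stack = stack[:, roi.top : roi.bottom, roi.left : roi.right]

    n = stack.shape[0]
    values = np.full(n, np.nan)
    flags = np.zeros(n, dtype=bool)
    for t in range(n):
        try:
            values[t], _, _ = segment_frame(
                stack[t],
                smooth_window=smooth_window,
                morph_iterations=morph_iterations,
                fixed_threshold_fallback=fixed_threshold_fallback,
            )
        except (ValueError, RuntimeError):
            flags[t] = True

    n_fail = int(flags.sum())
    if n_fail > max_fail_fraction * n:
        raise ValueError(
            f"unreliable area series: {n_fail}/{n} frames failed segmentation"
        )
    if n_fail:
        good = ~flags
        values[flags] = np.interp(
            np.nonzero(flags)[0], np.nonzero(good)[0], values[good]
        )

    return AreaSeries(
        values=values,
        times=meta.times,
        source_mode="area_variation",
        quality_flags=flags,
        meta=meta,
    )
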