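"""Mode 2 ("blood pool variation"): over-threshold red-pixel percentage.

DsRED-labelled blood cells are the only bright structures in the red
channel; pixels of non-moving regions sit near zero.  The fraction of
pixels strictly above a fixed intensity threshold (default 50 of 255,
chosen once to suppress noise artifacts) therefore tracks how much blood
occupies the chamber, which oscillates at the cardiac frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_acquisition import AcquisitionMeta, ROI
from .spectral import Chronology

__all__ = ["BloodPoolSeries", "overthreshold_fraction", "bloodpool_chronology"]

DEFAULT_RED_THRESHOLD = 50


@dataclass
class BloodPoolSeries(Chronology):
    """Percentage of over-threshold red pixels per frame (0-100)."""

    threshold_used: int = DEFAULT_RED_THRESHOLD


def overthreshold_fraction(
    red_frame: np.ndarray, threshold: int = DEFAULT_RED_THRESHOLD
) -> float:
    """Percentage of pixels strictly brighter than the threshold."""
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must be in [0, 255]")
    frame = np.asarray(red_frame)
    if frame.size == 0:
        raise ValueError("empty frame")
    return 100.0 * float(np.count_nonzero(frame > threshold)) / frame.size


def bloodpool_chronology(
    red_stack: np.ndarray,
    meta: AcquisitionMeta,
    roi: ROI | None = None,
    threshold: int = DEFAULT_RED_THRESHOLD,
) -> BloodPoolSeries:
    """Over-threshold percentage per frame, inside the ROI when given.

    Unlike segmentation, pixel counting cannot fail on individual frames,
    so the series carries no interpolated values.
    """
    stack = np.asarray(red_stack)
    if stack.ndim != 3:
        raise ValueError("expected a single-channel (time, row, col) stack")
    if stack.shape[0] < 8:
        raise ValueError("bloodpool_chronology requires >= 8 frames")
    if roi is not None:
        roi.validate_within(stack.shape[1], stack.shape[2])
        stack = stack[:, roi.top : roi.bottom, roi.left : roi.right]
    if stack.shape[1] == 0 or stack.shape[2] == 0:
        raise ValueError("zero-area ROI")

    n_pix = stack.shape[1] * stack.shape[2]
    counts = np.count_nonzero(
        stack.reshape(stack.shape[0], -1) > threshold, axis=1
    )
    values = 100.0 * counts / n_pix
    return BloodPoolSeries(
        values=values,
        times=meta.times,
        source_mode="blood_pool",
        quality_flags=np.zeros(stack.shape[0], dtype=bool),
        meta=meta,
        threshold_used=threshold,
    )
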