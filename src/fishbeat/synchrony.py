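"""Multi-chamber coupling: per-ROI chronologies and peak-to-peak delays.

Blood moves from the atrium to the ventricle and then to the bulbous
arteriosus; the contraction peaks of the three chambers are accordingly
staggered within each cardiac cycle.  Given three manually drawn ROIs,
the same chronology extraction used for rate estimation runs per chamber,
peaks are detected cycle by cycle, and signed peak delays are reported
relative to the ventricle, in seconds and in degrees of cardiac phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .bloodpool import bloodpool_chronology
from .io_acquisition import ROI, FrameStack, split_channel
from .segmentation import area_chronology
from .spectral import Chronology

__all__ = [
    "ChamberChronologySet",
    "DelayResult",
    "chamber_chronologies",
    "detect_cycle_peaks",
    "peak_delay",
    "chamber_delays",
]

CHAMBERS = ("atrium", "ventricle", "bulbous_arteriosus")
PEAK_MIN_SEPARATION_FRAC = 0.6  # of the cardiac period
PEAK_MIN_PROMINENCE_FRAC = 0.25  # of the signal peak-to-peak range


@dataclass
class ChamberChronologySet:
    """One chronology per chamber, sharing a single time base.

    Chambers whose extraction failed are recorded in ``failures`` instead
    of silently dropping out.
    """

    chronologies: dict[str, Chronology]
    failures: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(c) for c in self.chronologies.values()}
        if len(lengths) > 1:
            raise ValueError("chamber chronologies differ in length")


@dataclass
class DelayResult:
    """Mean signed peak delay between two chambers, over matched cycles."""

    delay_s: float
    delay_deg: float  # 360 * delay / period
    per_cycle_delays: np.ndarray
    n_cycles_used: int


def _rois_overlap(a: ROI, b: ROI) -> bool:
    return not (
        a.bottom <= b.top or b.bottom <= a.top or a.right <= b.left or b.right <= a.left
    )


def chamber_chronologies(
    stack: FrameStack,
    rois: dict[str, ROI],
    mode: str = "area",
    red_threshold: int = 50,
) -> ChamberChronologySet:
    """Extract one chronology per labelled chamber ROI.

    ``mode`` is ``area`` (green-channel segmentation) or ``bloodpool``
    (red-channel pixel counting).  Overlapping ROIs are allowed but
    flagged with a warning; a chamber whose extraction fails is recorded
    as unusable without failing the others.
    """
    missing = [c for c in CHAMBERS if c not in rois]
    if missing:
        raise ValueError(f"missing chamber ROIs: {missing}")
    labels = list(rois)
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            if _rois_overlap(rois[la], rois[lb]):
                warnings.warn(f"ROIs {la} and {lb} overlap")

    if mode == "area":
        channel = split_channel(stack, "green")
    elif mode == "bloodpool":
        channel = split_channel(stack, "red")
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'area' or 'bloodpool'")

    chronologies: dict[str, Chronology] = {}
    failures: dict[str, str] = {}
    for label, roi in rois.items():
        try:
            if mode == "area":
                chronologies[label] = area_chronology(channel, stack.meta, roi=roi)
            else:
                chronologies[label] = bloodpool_chronology(
                    channel, stack.meta, roi=roi, threshold=red_threshold
                )
        except ValueError as exc:
            failures[label] = str(exc)
    return ChamberChronologySet(chronologies=chronologies, failures=failures)


def detect_cycle_peaks(
    chron: Chronology,
    f0: float,
    min_separation_frac: float = PEAK_MIN_SEPARATION_FRAC,
    min_prominence_frac: float = PEAK_MIN_PROMINENCE_FRAC,
) -> np.ndarray:
    """Times (s) of one contraction peak per cardiac cycle.

    ``f0`` is the dominant frequency already established spectrally;
    peaks must be at least ``min_separation_frac / f0`` apart and rise by
    at least ``min_prominence_frac`` of the signal range.  A count far
    from the expected number of cycles raises "irregular peaks".
    """
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    values = chron.values
    ptp = float(values.max() - values.min())
    if ptp == 0:
        raise ValueError("irregular peaks: constant signal has no peaks")
    dt = chron.dt
    distance = max(1, int(round(min_separation_frac / f0 / dt)))
    idx, _ = find_peaks(
        values, distance=distance, prominence=min_prominence_frac * ptp
    )
    expected = (chron.times[-1] - chron.times[0]) * f0
    if abs(len(idx) - expected) > 1:
        raise ValueError(
            f"irregular peaks: found {len(idx)}, expected about {expected:.1f}"
        )
    return chron.times[idx]


def peak_delay(a: np.ndarray, b: np.ndarray, period: float) -> DelayResult:
    """Signed delay of chamber ``a``'s peaks relative to reference ``b``.

    For each reference peak the nearest peak of ``a`` is taken and the
    difference wrapped to ``(-period/2, period/2]``; negative means ``a``
    peaks before the reference.  Nearest-peak matching (rather than index
    alignment) tolerates a missed peak in either train.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if period <= 0:
        raise ValueError("period must be positive")
    if len(a) == 0 or len(b) == 0:
        raise ValueError("fewer than 2 matched cycles")
    deltas = []
    for tb in b:
        raw = a[np.argmin(np.abs(a - tb))] - tb
        wrapped = raw - period * np.floor(raw / period + 0.5)
        if wrapped == -period / 2:
            wrapped = period / 2
        deltas.append(wrapped)
    deltas = np.asarray(deltas)
    if len(deltas) < 2:
        raise ValueError("fewer than 2 matched cycles")
    mean = float(deltas.mean())
    return DelayResult(
        delay_s=mean,
        delay_deg=360.0 * mean / period,
        per_cycle_delays=deltas,
        n_cycles_used=len(deltas),
    )


def chamber_delays(
    peaks: dict[str, np.ndarray], f0: float
) -> dict[str, DelayResult]:
    """Atrium and bulbous delays relative to the ventricular peaks.

    ``delay_AV`` is atrial minus ventricular peak time (negative when the
    atrium leads, the normal activation order); ``delay_VBuA`` is
    ventricular minus bulbous peak time.
    """
    period = 1.0 / f0
    av = peak_delay(peaks["atrium"], peaks["ventricle"], period)
    bua = peak_delay(peaks["bulbous_arteriosus"], peaks["ventricle"], period)
    v_minus_bua = DelayResult(
        delay_s=-bua.delay_s,
        delay_deg=-bua.delay_deg,
        per_cycle_delays=-bua.per_cycle_delays,
        n_cycles_used=bua.n_cycles_used,
    )
    return {"delay_AV": av, "delay_VBuA": v_minus_bua}
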