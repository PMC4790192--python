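"""Single-embryo and batch analysis with CSV reporting.

Mirrors the screening workflow: point at a folder (one embryo) or at a
multiwell root (one subfolder per embryo, no upper limit) and get the
cardiac rate of every embryo back as a report.  In batch mode a failing
embryo becomes a row with a status and message, never an aborted run —
fault isolation is what makes 96-well screening usable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bloodpool import DEFAULT_RED_THRESHOLD, bloodpool_chronology
from .io_acquisition import (
    DEFAULT_FRAME_INTERVAL_S,
    ROI,
    FrameStack,
    discover_embryos,
    load_frame_stack,
    split_channel,
)
from .segmentation import area_chronology
from .spectral import (
    DEFAULT_BAND_HZ,
    Chronology,
    HeartRateResult,
    compute_psd,
    heart_rate,
)

__all__ = [
    "AnalysisConfig",
    "REPORT_COLUMNS",
    "analyze_stack",
    "run_single",
    "run_batch",
    "compare_conditions",
]

REPORT_COLUMNS = [
    "embryo_id",
    "source_mode",
    "dominant_freq_hz",
    "bpm",
    "peak_prominence",
    "n_frames",
    "effective_fps",
    "status",
    "error_message",
]

MODES = ("area", "bloodpool")


@dataclass(frozen=True)
class AnalysisConfig:
    """Run-level knobs shared by single and batch analysis."""

    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
    mode: str = "bloodpool"
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ
    red_threshold: int = DEFAULT_RED_THRESHOLD
    window: str = "none"
    channel_layout: str = "rgb"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")


def extract_chronology(
    stack: FrameStack, config: AnalysisConfig, roi: ROI | None = None
) -> Chronology:
    if config.mode == "area":
        return area_chronology(split_channel(stack, "green"), stack.meta, roi=roi)
    return bloodpool_chronology(
        split_channel(stack, "red"),
        stack.meta,
        roi=roi,
        threshold=config.red_threshold,
    )


def analyze_stack(
    stack: FrameStack, config: AnalysisConfig, roi: ROI | None = None
) -> HeartRateResult:
    """Full pipeline on an in-memory stack: chronology -> PSD -> bpm."""
    chron = extract_chronology(stack, config, roi=roi)
    return heart_rate(
        chron, band=config.band_hz, window=config.window, embryo_id=stack.embryo_id
    )


def run_single(
    directory,
    config: AnalysisConfig | None = None,
    roi: ROI | None = None,
    out_dir=None,
) -> HeartRateResult:
    """Analyze one embryo folder; optionally export its traces.

    When ``out_dir`` is given the chronology and the normalized spectrum
    are written as two-column tab-separated text so they can be replotted
    or fed to any downstream statistics tool.
    """
    config = config or AnalysisConfig()
    stack = load_frame_stack(
        directory,
        frame_interval=config.frame_interval_s,
        channel_layout=config.channel_layout,
    )
    chron = extract_chronology(stack, config, roi=roi)
    result = heart_rate(
        chron, band=config.band_hz, window=config.window, embryo_id=stack.embryo_id
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        np.savetxt(
            out_dir / f"{stack.embryo_id}_chronology.tsv",
            np.column_stack([chron.times, chron.values]),
            delimiter="\t",
            header="time_s\tvalue",
            comments="",
        )
        spec = compute_psd(chron, window=config.window)
        np.savetxt(
            out_dir / f"{stack.embryo_id}_spectrum.tsv",
            np.column_stack([spec.frequencies, spec.psd]),
            delimiter="\t",
            header="freq_hz\tnormalized_psd",
            comments="",
        )
    return result


def run_batch(
    root,
    config: AnalysisConfig | None = None,
    csv_path=None,
) -> pd.DataFrame:
    """Analyze every embryo subfolder under a multiwell root.

    Returns (and optionally writes) one row per discovered embryo; rows
    for failed embryos carry ``status='error'`` and the message, with
    empty metrics.
    """
    config = config or AnalysisConfig()
    embryos = discover_embryos(root)
    mode_name = "area_variation" if config.mode == "area" else "blood_pool"
    rows = []
    for embryo_id, directory in embryos:
        row = {
            "embryo_id": embryo_id,
            "source_mode": mode_name,
            "dominant_freq_hz": np.nan,
            "bpm": np.nan,
            "peak_prominence": np.nan,
            "n_frames": 0,
            "effective_fps": np.nan,
            "status": "ok",
            "error_message": "",
        }
        try:
            stack = load_frame_stack(
                directory,
                frame_interval=config.frame_interval_s,
                channel_layout=config.channel_layout,
            )
            row["n_frames"] = stack.n_frames
            row["effective_fps"] = stack.meta.effective_fps
            result = analyze_stack(stack, config)
            row["dominant_freq_hz"] = result.dominant_freq
            row["bpm"] = result.bpm
            row["peak_prominence"] = result.peak_prominence
        except (ValueError, RuntimeError, OSError) as exc:
            row["status"] = "error"
            row["error_message"] = str(exc)
        rows.append(row)

    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if csv_path is not None:
        report.to_csv(csv_path, index=False, encoding="utf-8")
    return report


def compare_conditions(
    report_pre: pd.DataFrame, report_post: pd.DataFrame
) -> pd.DataFrame:
    """Per-embryo percent rate change between two paired reports.

    percent_change = 100 * (post - pre) / pre, negative meaning the rate
    slowed after treatment.  The returned frame carries one row per
    embryo plus a summary attribute ``(mean, sd)`` in
    ``df.attrs['mean_percent_change']`` / ``df.attrs['sd_percent_change']``.
    """
    pre_ok = report_pre[report_pre["status"] == "ok"].set_index("embryo_id")
    post_ok = report_post[report_post["status"] == "ok"].set_index("embryo_id")
    unmatched = set(pre_ok.index).symmetric_difference(post_ok.index)
    if unmatched:
        raise ValueError(f"embryo id mismatch between reports: {sorted(unmatched)}")
    if len(pre_ok) == 0:
        raise ValueError("no paired embryos to compare")

    ids = sorted(pre_ok.index)
    pre_bpm = pre_ok.loc[ids, "bpm"].to_numpy(dtype=float)
    post_bpm = post_ok.loc[ids, "bpm"].to_numpy(dtype=float)
    change = 100.0 * (post_bpm - pre_bpm) / pre_bpm
    out = pd.DataFrame(
        {
            "embryo_id": ids,
            "bpm_pre": pre_bpm,
            "bpm_post": post_bpm,
            "percent_change": change,
        }
    )
    out.attrs["mean_percent_change"] = float(change.mean())
    out.attrs["sd_percent_change"] = float(change.std(ddof=1)) if len(change) > 1 else 0.0
    return out
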