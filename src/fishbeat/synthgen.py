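"""Synthetic beating-heart acquisitions with known ground truth.

Real acquisitions image a two-colour transgenic embryo: green endocardium
and red blood cells.  The generator emulates the two signals the analysis
actually consumes: a bright green disk whose radius follows
``r(t) = base_radius + radius_amplitude * sin(2*pi*(bpm/60)*t)``, and a
red blob field whose over-threshold pixel occupancy oscillates at the same
frequency, delayed by ``bloodpool_phase_lag`` (blood content lags the wall
motion in real hearts).  Gaussian read noise is added before 8-bit
quantization.  Everything is deterministic given ``rng_seed``.

Blob positions are drawn once per acquisition; each frame reveals the
first k(t) of the pool, with k(t) modulated sinusoidally.  A frozen scene
(zero noise, zero radius amplitude) therefore reproduces bit-identical
frames, and cell counts remain discrete blob counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

from .io_acquisition import ROI, AcquisitionMeta, FrameStack

__all__ = [
    "SyntheticEmbryoConfig",
    "GroundTruth",
    "generate_embryo",
    "generate_three_chamber",
    "generate_multiwell",
    "write_frame_stack",
]

CHAMBER_INTENSITY = 200  # green wall level, well above any histogram valley
BLOB_RADIUS = 2  # px; one "blood cell" stamp
DEFAULT_BPM_RANGE = (120.0, 180.0)  # wild-type embryonic band
#: mean fraction of the chamber covered by blood at rest
BASE_OCCUPANCY = 0.20


@dataclass(frozen=True)
class SyntheticEmbryoConfig:
    """Ground-truth parameters for one synthetic acquisition.

    Defaults mirror a routine confocal run: 67 frames/s for 4.54 s at a
    frame of 200 rows x 500 columns.  ``bloodpool_phase_lag`` is in
    radians of cardiac phase (positive = red signal delayed vs. area).
    ``chamber_lags`` are the atrium/ventricle/outflow-tract activation
    offsets in seconds, used only by :func:`generate_three_chamber`.
    """

    true_bpm: float = 150.0
    duration_s: float = 4.54
    fps: float = 67.0
    frame_shape: tuple[int, int] = (200, 500)
    chamber_center: tuple[int, int] | None = None
    base_radius: float = 40.0
    radius_amplitude: float = 10.0
    bloodpool_phase_lag: float = 0.6
    chamber_lags: tuple[float, float, float] = (0.0, 0.10, 0.16)
    noise_sigma: float = 8.0
    cell_intensity: int = 200
    rng_seed: int = 0

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    @property
    def frame_interval(self) -> float:
        return 1.0 / self.fps

    @property
    def freq_hz(self) -> float:
        return self.true_bpm / 60.0

    def validate(self) -> None:
        if self.freq_hz >= self.fps / 2:
            raise ValueError(
                f"Nyquist violation: {self.true_bpm} bpm = {self.freq_hz:.3g} Hz "
                f">= fps/2 = {self.fps / 2:.3g} Hz"
            )
        if self.radius_amplitude >= self.base_radius:
            raise ValueError("radius_amplitude must be below base_radius")
        if self.radius_amplitude < 0 or self.base_radius <= 0:
            raise ValueError("radii must be non-negative, base_radius positive")
        if self.n_frames < 8:
            raise ValueError("duration too short: fewer than 8 frames")


@dataclass
class GroundTruth:
    """Per-frame truths recorded while rendering a synthetic acquisition."""

    area: np.ndarray  # true chamber pixel count per frame
    bloodpool_pct: np.ndarray  # true over-threshold red fraction (%)
    true_bpm: float
    peak_times: dict[str, np.ndarray]  # contraction peak times per chamber
    rng_seed: int
    chamber_rois: dict[str, ROI] | None = None


def _default_center(cfg: SyntheticEmbryoConfig) -> tuple[int, int]:
    if cfg.chamber_center is not None:
        return cfg.chamber_center
    return (cfg.frame_shape[0] // 2, cfg.frame_shape[1] // 2)


def _check_geometry(center, max_radius, shape) -> None:
    cy, cx = center
    h, w = shape
    if (
        cy - max_radius < 0
        or cx - max_radius < 0
        or cy + max_radius >= h
        or cx + max_radius >= w
    ):
        raise ValueError("chamber geometry exceeds frame bounds")


def _blob_stamp() -> tuple[np.ndarray, np.ndarray]:
    r = BLOB_RADIUS
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dy**2 + dx**2 <= r**2
    return dy[keep], dx[keep]


_STAMP_DY, _STAMP_DX = _blob_stamp()
_STAMP_AREA = len(_STAMP_DY)


def _blob_pool(
    rng: np.random.Generator, center, radius: float, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform blob centres inside the chamber, clear of its rim."""
    cy, cx = center
    rmax = max(radius - BLOB_RADIUS, 1.0)
    rr = rmax * np.sqrt(rng.uniform(size=n))
    th = rng.uniform(0, 2 * np.pi, size=n)
    ys = np.round(cy + rr * np.sin(th)).astype(int)
    xs = np.round(cx + rr * np.cos(th)).astype(int)
    return ys, xs


def _peak_times(f0: float, lag: float, duration: float) -> np.ndarray:
    """Times of radius maxima: sin phase = pi/2, shifted by the lag."""
    first = lag + 0.25 / f0
    ks = np.arange(0, int(np.ceil(duration * f0)) + 2)
    times = first + ks / f0
    return times[(times >= 0) & (times <= duration)]


@dataclass
class _Chamber:
    center: tuple[int, int]
    base_radius: float
    radius_amplitude: float
    lag_s: float


def _render(
    cfg: SyntheticEmbryoConfig,
    chambers: list[_Chamber],
    embryo_id: str,
) -> tuple[FrameStack, np.ndarray, np.ndarray]:
    """Render frames for a set of chambers; returns (stack, area, blood%)."""
    rng = np.random.default_rng(cfg.rng_seed)
    h, w = cfg.frame_shape
    n = cfg.n_frames
    t = np.arange(n) * cfg.frame_interval
    f0 = cfg.freq_hz
    two_pi_f = 2 * np.pi * f0

    yy, xx = np.mgrid[0:h, 0:w]
    per_chamber = []
    for ch in chambers:
        dist2 = (yy - ch.center[0]) ** 2 + (xx - ch.center[1]) ** 2
        radii = ch.base_radius + ch.radius_amplitude * np.sin(
            two_pi_f * (t - ch.lag_s)
        )
        # blood occupancy: same frequency, extra lag, depth tied to the
        # contraction amplitude so a frozen heart gives a frozen pool
        rel = ch.radius_amplitude / ch.base_radius
        depth = min(0.8, 2.0 * rel)
        chamber_area = np.pi * ch.base_radius**2
        lam = (
            BASE_OCCUPANCY
            * chamber_area
            / _STAMP_AREA
            * (1.0 + depth * np.sin(two_pi_f * (t - ch.lag_s) - cfg.bloodpool_phase_lag))
        )
        k = np.maximum(np.round(lam).astype(int), 0)
        pool_n = int(k.max()) if len(k) else 0
        ys, xs = _blob_pool(rng, ch.center, ch.base_radius, max(pool_n, 1))
        per_chamber.append((dist2, radii, k, ys, xs))

    frames = np.zeros((n, h, w, 3), dtype=np.uint8)
    area = np.zeros(n)
    blood = np.zeros(n)
    for i in range(n):
        green = np.zeros((h, w), dtype=np.float32)
        red = np.zeros((h, w), dtype=np.float32)
        for dist2, radii, k, ys, xs in per_chamber:
            mask = dist2 <= radii[i] ** 2
            green[mask] = CHAMBER_INTENSITY
            area[i] += int(mask.sum())
            ki = k[i]
            if ki > 0:
                by = (ys[:ki, None] + _STAMP_DY[None, :]).ravel()
                bx = (xs[:ki, None] + _STAMP_DX[None, :]).ravel()
                red[by, bx] = cfg.cell_intensity
        blood[i] = 100.0 * np.count_nonzero(red > 50) / (h * w)
        if cfg.noise_sigma > 0:
            green += rng.normal(0.0, cfg.noise_sigma, (h, w))
            red += rng.normal(0.0, cfg.noise_sigma, (h, w))
        frames[i, :, :, 0] = np.clip(np.round(red), 0, 255)
        frames[i, :, :, 1] = np.clip(np.round(green), 0, 255)

    meta = AcquisitionMeta(
        frame_interval=cfg.frame_interval,
        n_frames=n,
        frame_height=h,
        frame_width=w,
    )
    return FrameStack(frames=frames, meta=meta, embryo_id=embryo_id), area, blood


def generate_embryo(
    cfg: SyntheticEmbryoConfig, embryo_id: str = "synthetic"
) -> tuple[FrameStack, GroundTruth]:
    """One single-chamber acquisition plus its ground truth."""
    cfg.validate()
    center = _default_center(cfg)
    _check_geometry(center, cfg.base_radius + cfg.radius_amplitude, cfg.frame_shape)
    chamber = _Chamber(center, cfg.base_radius, cfg.radius_amplitude, 0.0)
    stack, area, blood = _render(cfg, [chamber], embryo_id)
    gt = GroundTruth(
        area=area,
        bloodpool_pct=blood,
        true_bpm=cfg.true_bpm,
        peak_times={"whole": _peak_times(cfg.freq_hz, 0.0, cfg.duration_s)},
        rng_seed=cfg.rng_seed,
    )
    return stack, gt


_CHAMBER_LABELS = ("atrium", "ventricle", "bulbous_arteriosus")


def generate_three_chamber(
    cfg: SyntheticEmbryoConfig, embryo_id: str = "synthetic3"
) -> tuple[FrameStack, GroundTruth]:
    """Atrium, ventricle and outflow tract beating with staggered lags.

    The three chambers share the true frequency; their contraction peaks
    are offset by ``cfg.chamber_lags`` seconds, emulating the
    atrium-to-ventricle-to-bulbous activation sequence.
    """
    cfg.validate()
    if len(cfg.chamber_lags) != 3:
        raise ValueError("three chamber_lags required")
    h, w = cfg.frame_shape
    rmax = cfg.base_radius + cfg.radius_amplitude
    spacing = w // 4
    if spacing <= 2 * rmax:
        raise ValueError("overlapping chambers: frame too narrow for geometry")
    centers = [(h // 2, spacing), (h // 2, 2 * spacing), (h // 2, 3 * spacing)]
    for c in centers:
        _check_geometry(c, rmax, cfg.frame_shape)

    chambers = [
        _Chamber(c, cfg.base_radius, cfg.radius_amplitude, lag)
        for c, lag in zip(centers, cfg.chamber_lags)
    ]
    stack, area, blood = _render(cfg, chambers, embryo_id)

    half = int(np.ceil(rmax)) + 4
    rois = {
        label: ROI(
            top=h // 2 - half,
            left=cx - half,
            height=2 * half,
            width=2 * half,
            label=label,
        )
        for label, (cy, cx) in zip(_CHAMBER_LABELS, centers)
    }
    gt = GroundTruth(
        area=area,
        bloodpool_pct=blood,
        true_bpm=cfg.true_bpm,
        peak_times={
            label: _peak_times(cfg.freq_hz, lag, cfg.duration_s)
            for label, lag in zip(_CHAMBER_LABELS, cfg.chamber_lags)
        },
        rng_seed=cfg.rng_seed,
        chamber_rois=rois,
    )
    return stack, gt


def write_frame_stack(
    stack: FrameStack, directory, multipage: bool = False
) -> None:
    """Write a stack as single-image-per-file TIFFs (or one multi-page file)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if multipage:
        tifffile.imwrite(directory / "stack.tif", stack.frames, photometric="rgb")
        return
    digits = max(4, len(str(stack.n_frames)))
    for i in range(stack.n_frames):
        tifffile.imwrite(
            directory / f"frame_{i:0{digits}d}.tif",
            stack.frames[i],
            photometric="rgb",
        )


def generate_multiwell(
    root,
    n_embryos: int = 12,
    bpm_range: tuple[float, float] = DEFAULT_BPM_RANGE,
    rng_seed: int = 0,
    template: SyntheticEmbryoConfig | None = None,
    force: bool = False,
    multipage: bool = False,
) -> dict:
    """Write a multiwell folder tree of synthetic embryos plus a manifest.

    One subfolder per embryo; true rates are sampled uniformly from
    ``bpm_range`` (the wild-type embryonic band by default).  The manifest
    (``manifest.json``) maps embryo ids to their true bpm and seed, the
    oracle for end-to-end recovery tests.
    """
    root = Path(root)
    if root.exists() and any(root.iterdir()) and not force:
        raise ValueError(f"refusing to write into non-empty {root} (use force)")
    root.mkdir(parents=True, exist_ok=True)

    template = template or SyntheticEmbryoConfig()
    rng = np.random.default_rng(rng_seed)
    digits = max(2, len(str(n_embryos)))
    manifest: dict = {"rng_seed": int(rng_seed), "embryos": {}}
    for i in range(n_embryos):
        eid = f"e{i + 1:0{digits}d}"
        bpm = float(rng.uniform(*bpm_range))
        seed = int(rng.integers(0, 2**31 - 1))
        cfg = replace(template, true_bpm=bpm, rng_seed=seed)
        stack, _ = generate_embryo(cfg, embryo_id=eid)
        write_frame_stack(stack, root / eid, multipage=multipage)
        manifest["embryos"][eid] = {"true_bpm": bpm, "rng_seed": seed}
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
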