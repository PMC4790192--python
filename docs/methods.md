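# Methods

## The measurement problem

The embryonic zebrafish heart beats at 120–180 bpm under normal
conditions, within a factor of ~2 of the human rate, which makes the
embryo a practical model for cardiac pharmacology. The measurement task
is to estimate that rate from fluorescence time-lapse sequences alone:
each acquisition is a per-embryo folder of 8-bit RGB TIFF frames in
which the green channel carries the GFP-labelled endocardium, the red
channel carries labelled blood cells, and the frame interval is supplied
by the operator (default 15 ms; a typical acquisition is 304 frames,
spanning 4.545 s first-to-last).

## Mode 1: area variation

Per frame, on the green channel (optionally inside an ROI):

1. **Histogram thresholding.** The 256-bin intensity histogram is
   smoothed with a 9-bin moving average; the two most prominent modes
   are located (`scipy.signal.find_peaks` on the zero-padded histogram,
   ranked by prominence), and the threshold is the deepest local minimum
   strictly between them, ties resolved toward the lower intensity.
   The 9-bin window suppresses the bin-level jitter of small-ROI
   histograms while leaving well-separated tissue/background modes
   intact. A frame without two separated modes (constant or unimodal)
   raises an error; callers may configure a fixed fallback threshold.
2. **Binarization.** Foreground = intensity strictly greater than the
   threshold. The bright GFP tissue is the object; strict inequality is
   fixed so boundary cases are unambiguous and consistent with mode 2.
3. **Morphological filtering.** Closing then opening, each with a 3 × 3
   square structuring element, one iteration by default (configurable).
   Closing first fills pinholes in thin chamber walls before the opening
   removes speckle; doing the opening first could erase a one-pixel-wide
   wall segment.
4. **Largest component and boundary tracing.** Connected components use
   8-connectivity; only the largest is traced (the ROI may contain
   debris or a second structure). The seed is the component's first
   pixel in row-major scan order — necessarily a boundary pixel with a
   background west neighbour. Moore-neighbour tracing proceeds
   clockwise from the backtrack pixel and stops by Jacob's criterion
   (the start pixel is left in the same direction as on the first
   step), which terminates correctly on spurs and one-pixel-wide
   bridges where a naive "reached the start again" stop does not.
5. **Enclosed area.** The traced contour is rasterized and its interior
   filled (`scipy.ndimage.binary_fill_holes`); the filled pixel count is
   the chamber area. On every shape tested this equals the flood-fill
   area of the traced component, and the test suite asserts that
   equivalence on randomized masks.

Thresholds are recomputed independently per frame, so slow photobleaching
or illumination drift cannot masquerade as area change. Frames whose
segmentation fails are linearly interpolated from their neighbours and
flagged; more than 25 % failures abort the series as unreliable, since
beyond that the interpolation would begin to shape the spectrum.

## Mode 2: blood pool variation

Per frame, on the red channel: the percentage of pixels strictly above
intensity 50 (of 255). Non-moving background sits near zero, so the
over-threshold fraction tracks blood occupancy of the chamber. The
threshold is deliberately a fixed constant rather than per-frame
adaptive — the red channel is sparse and often effectively unimodal, and
the quantity of interest is the *variation* of occupancy, which a fixed
cut preserves. Recovered rates are insensitive to the exact value across
40–60 for blob intensities near 200 and noise σ ≤ 10 (tested). When an
ROI is supplied the percentage is computed within it, so the same
operation serves per-chamber synchrony analysis.

## Spectral rate estimation

The chronology is mean-subtracted (the static offset otherwise dominates
the spectrum), optionally Hann-windowed (off by default), zero-padded
4× and Fourier transformed; the squared magnitude normalized to unit
maximum is the reported PSD. The heart rate is the PSD argmax within
0.5–8 Hz (30–480 bpm), refined by three-point parabolic interpolation,
times 60.

- **Band.** 0.5 Hz excludes DC and respiratory/stage drift; 8 Hz is far
  above any drug-accelerated embryonic rate. Both ends configurable.
- **Sub-bin refinement.** A 4.545 s window has a native resolution of
  0.22 Hz ≈ 13 bpm; zero-padding plus parabolic interpolation recovers
  noiseless tones to better than half a native bin anywhere in the band
  (property-tested), which is what makes few-percent rate differences
  measurable on longer windows.
- **No-signal detection.** A chronology with no periodic content must
  error rather than return a number. Two guards are applied: the global
  PSD argmax (over f > 0) must fall inside the search band, and the
  in-band peak must exceed 10× the median out-of-band power. The first
  guard is what actually catches slow drift: spectral leakage from a
  strong out-of-band line into the band edge can exceed the far-field
  median by orders of magnitude, so a ratio test alone cannot reject it.
- `peak_prominence` (dominant peak over median in-band power) is carried
  on every result as a quality metric.
- `effective_fps` in the metadata is frame count divided by the
  first-to-last span (n − 1 intervals), the convention under which a
  304-frame, 15 ms acquisition reports the nominal 67 frames/s; the
  spectral grid itself is built from the true sample interval.

## Chamber synchrony

Blood enters at the atrium, passes to the ventricle and leaves through
the bulbous arteriosus; the three contraction peaks are staggered within
each cycle. Given three labelled ROIs (drawn manually; a plain-text
`label top left height width` file is supported), the selected mode runs
per ROI on a shared time base. Peaks are detected per chronology with a
minimum separation of 0.6 cardiac periods and a prominence of 25 % of
the signal range, using the spectrally estimated rate as prior; a peak
count deviating from the expected cycle count by more than one is
rejected as irregular. Delays are signed relative to the ventricle:
for each ventricular peak the nearest peak of the other chamber is
taken and the difference wrapped to (−T/2, T/2], so a single missed
peak shifts one matched cycle rather than de-phasing the whole train.
Delays are reported in seconds and in degrees of cardiac phase
(360 · delay / T). Negative `delay_AV` means the atrium leads.

## Synthetic acquisitions

The generator renders what the pipeline consumes, not cardiac anatomy:

- **Green:** a filled disk of intensity 200 whose radius follows
  r(t) = r₀ + a·sin(2π f₀ t); per-frame true pixel areas are recorded.
- **Red:** blob "cells" (radius 2 px, intensity 200 by default) inside
  the chamber. Blob centres are drawn once per acquisition; frame *t*
  reveals the first k(t) of the pool, with k(t) modulated sinusoidally
  at f₀, delayed by a configurable phase lag (default 0.6 rad — blood
  occupancy lags wall motion), and with modulation depth tied to the
  relative contraction amplitude so a frozen heart yields bit-identical
  frames. The per-frame count is the rounded expected density rather
  than a fresh Poisson draw, keeping the frozen-scene and determinism
  contracts exact.
- Gaussian noise (default σ = 8 intensity units, a realistic confocal
  read-noise level well below the 200-level signal and the 50-level
  threshold) is added before clipping to [0, 255] and 8-bit rounding.
- Three-chamber scenes place three disjoint disks with per-chamber time
  lags and record true per-chamber peak times and bounding ROIs.
- Multiwell trees write one TIFF-sequence subfolder per embryo plus a
  JSON manifest of true rates and seeds; rates default to uniform
  120–180 bpm, the wild-type band.

What the generator does *not* emulate: cardiac looping geometry, optical
point-spread blur, motion artefacts from an unanaesthetised embryo,
pigmentation shadows, or advected individual cells. Passing tests
therefore demonstrate correct signal extraction and frequency estimation
under controlled periodicity and noise — not robustness to every failure
mode of live imaging.

## Problem sizes and reproducibility

Validation runs use 64 × 64 px frames (geometry scaled down from the
500 × 200 acquisition format; frame size affects only pixel counts, not
timing or frequencies), 67 fps throughout, 30 s sequences for
effect-size recovery (native resolution ~2 bpm, finer than the smallest
injected effect of 12 %), 10 s for cohort-level checks, and the
paper-format 304-frame window for mode-agreement checks. All randomness
flows through explicit integer seeds (`numpy.random.default_rng`);
`scripts/acceptance.py` derives every generator seed from its `--seed`
argument, and repeated runs with the same seed are bit-identical.

## Known limitations

- Mode 1 assumes a bimodal green histogram; a saturated or empty ROI
  falls back to interpolation/error handling rather than recovering.
- Arrhythmic or beat-to-beat-variable rhythms are reported as a single
  dominant frequency; no HRV or interval analysis is attempted.
- ROIs are axis-aligned rectangles selected by the user; no automatic
  chamber detection is provided.
- The PSD peak is assumed to be the fundamental; a pathological signal
  whose second harmonic dominates would be reported at double rate.
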