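# fishbeat

Automated, non-invasive cardiac-rate estimation for embryonic zebrafish
from two-channel fluorescence time-lapse image sequences.

Embryonic zebrafish carrying an endothelial GFP reporter and a red
blood-cell reporter (e.g. *kdrl:GFP* together with *gata1:DsRED*) are
imaged in multiwell plates on a confocal microscope, typically at 67
frames/s with a 500 × 200 px field. `fishbeat` turns each per-embryo TIFF
frame sequence into a heart rate in beats per minute, without touching or
pacing the embryo, and scales from a single acquisition to a whole plate
of them. It is aimed at cardiovascular screening labs that need the beat
rate of tens of embryos per plate, reproducibly, from images alone.

## Method

Two independent measurement modes produce a per-frame scalar time series
(a *chronology*) over the cardiac cycles:

- **Mode 1 — area variation.** In every green-channel frame, the chamber
  wall is segmented by thresholding at the deepest local minimum of the
  smoothed 256-bin intensity histogram, cleaning the binary image with
  3 × 3 morphological closing then opening, and tracing the outer boundary
  of the largest connected component (Moore-neighbour tracing with
  Jacob's stopping criterion). The pixel count enclosed by the traced
  contour is the chamber area *A(t)*.
- **Mode 2 — blood pool variation.** In every red-channel frame, the
  percentage of pixels with intensity strictly above a fixed threshold
  (50 of 255) measures blood-cell occupancy *B(t)*.

Either chronology *x(t)*, sampled at interval Δt over *N* frames, is
mean-subtracted and converted to a power spectral density by FFT with
4× zero-padding,

    P(f) = |Σₙ (x(tₙ) − x̄) e^(−2πi f tₙ)|²,   normalized so max P = 1,

and the heart rate is 60 × argmax P(f) over the physiological band
0.5–8 Hz, refined by three-point parabolic interpolation around the peak
bin. Multi-chamber coupling (atrium → ventricle → bulbous arteriosus) is
quantified by extracting one chronology per manually drawn chamber ROI
and measuring signed peak-to-peak delays relative to the ventricle.

A fully parameterized synthetic-acquisition generator (`fishbeat.synthgen`)
renders beating two-channel embryos with known true rate, chamber lags and
noise, and is the ground-truth oracle for the whole test suite.

## Worked example

Generate a small synthetic plate of three embryos (10 s at 67 fps,
64 × 64 px frames, true rates drawn uniformly from the wild-type
120–180 bpm band), then run the batch pipeline:

```
$ fishbeat synth demo/plate --n-embryos 3 --duration-s 10 --frame-shape 64,64 --seed 4
wrote 3 embryos under demo/plate

$ fishbeat batch demo/plate --interval-s 0.014925 --out demo/report.csv
3/3 embryos analyzed ok; report written to demo/report.csv
```

The report holds one row per embryo:

```
embryo_id,source_mode,dominant_freq_hz,bpm,peak_prominence,n_frames,effective_fps,status,error_message
e01,blood_pool,2.943644059452772,176.61864356716632,5442.70400347155,670,67.10182702250665,ok,
e02,blood_pool,2.975577872056076,178.53467232336456,6333.0789165680235,670,67.10182702250665,ok,
e03,blood_pool,2.0806242274639484,124.8374536478369,5582.809222828354,670,67.10182702250665,ok,
```

The generator's manifest records true rates of 176.58, 178.57 and
124.85 bpm for e01–e03: the blood-pool pipeline recovers each within
0.1 bpm. The same folder analyzed in mode 1 agrees:

```
$ fishbeat single demo/plate/e01 --interval-s 0.014925 --mode area
e01: 176.6 bpm (2.943 Hz, mode=area_variation, peak prominence 7616.7)
```

`bpm` is 60 × the dominant PSD frequency; `peak_prominence` is the ratio
of the dominant peak to the median in-band power (a quality metric —
values ≫ 10 indicate a clean periodic signal); a `status` of `error`
marks an embryo whose analysis failed without aborting the batch.

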