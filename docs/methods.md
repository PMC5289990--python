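# Methods

This note documents the models, parameters, numerical choices and known
limitations of the blink-extraction pipeline, and what the synthetic
generator does and does not emulate.

## Signal model and conventions

A *candidate signal* is a single time series — EEG channel, EOG lead, or
IC activation — sampled at a fixed rate. Frames are zero-based; the time
of frame `i` is `i/srate` seconds. Blink excursions are taken to be
positive; IC activations whose blink excursions are negative should be
sign-flipped by the caller (for scalp maps, `ic_figure_of_merit` performs
this reorientation automatically from the frontal/rear hemisphere means).

All detection, landmark fitting and index computation operate on the
band-passed trace. This keeps the threshold, the zero crossings and the
velocity estimates mutually consistent, at the cost of a systematic
narrowing of measured widths (quantified below).

## Detection

* Band-pass [1, 20] Hz, zero-phase FIR, Hamming window, order
  `≈ 3·srate/low` (odd taps, reflection-padded convolution). The order
  scales with `srate/low` so the normalized transition width is
  rate-independent: gain is within ±5% across 2–18 Hz and ≥20 dB down one
  octave outside the band (≈ −40 dB at 0.5 Hz, ≈ −80 dB at 40 Hz at
  256 Hz).
* Threshold `mean + 1.5·SD` of the filtered trace over all frames —
  invariant to gain and offset. Runs separated by less than 50 ms are
  merged (the alternative, dropping both, is selectable via
  `separation_mode="drop"`); runs lasting ≤ 50 ms are then discarded.
  Merging is the default because a noise notch can split one true blink
  into two sub-runs, and merging restores it.
* A constant trace (SD = 0) yields no potential blinks rather than an
  error.

## Landmarks

* `maxFrame`: first frame attaining the interval maximum.
* `leftZero`: last non-positive frame before the peak, searched down to
  the previous blink's `rightZero`; if the trace never touches zero
  there, the frame of lowest amplitude in the region. `rightZero`
  symmetric, bounded by the next potential blink's start. Zero crossings
  are kept at frame resolution; sub-frame interpolation is reserved for
  the duration measures, where the ≈4 ms frame quantum at 256 Hz would
  otherwise be a large fraction of a 120 ms blink.
* Velocity is the forward first difference of the filtered trace times
  `srate` (µV/s), with no additional smoothing.
* Bases are the first *strict* local minima scanning outward from the
  maximum-velocity frames; plateaus are traversed (determinism on
  quantized data). The scan is bounded by the inter-blink search region,
  not by the zero crossing: a pre-blink dip below zero legitimately
  places the base before `leftZero`. With background noise this settles
  the bases just outside the zeros, which is why the half-base duration
  measures slightly longer than the half-zero duration.
* Tent fit: for each stroke, frames whose amplitude lies between 10% and
  90% of the stroke's rise above its own minimum are fitted by ordinary
  least squares; R² is the squared Pearson correlation. The amplitude
  window (rather than the middle 80% of frames, selectable via
  `inner_fit_mode="frame"`) is robust to asymmetric sampling of fast
  strokes. Fewer than three usable frames on either stroke marks the
  blink unfittable (R² = 0, excluded from every tier). Degenerate line
  intersections and zero slopes leave the tent peak / x-intercepts NaN,
  and the tent duration missing for that blink.

## Signal quality and blink discrimination

Defaults (all inclusive at their boundaries):

| parameter | default | meaning |
|---|---|---|
| `bar_range` | [3, 50] | blink-amplitude ratio gate (values 5–20 typical of good blink channels) |
| `r2_good/better/best` | 0.90 / 0.95 / 0.98 | stroke-R² tiers, weaker stroke decides |
| `z_best`, `z_good` | 5, 2 | robust-SD multiples around the best-blink median |
| `pavr_min` | 3 cs | at or below ⇒ saccade, excluded |
| `good_ratio_min` | 0.70 | fraction of potential blinks inside the ±2 robust-SD band required for full (non-marginal) selection |
| `group_threshold_sd` | 1.5 | robust SDs above zero seeding cross-signal blink groups |

The robust SD is `1.4826 × median(|x − median(x)|)`, the MAD scaled to
estimate a normal SD without being dragged by the outliers it is meant to
flag. BAR pools samples over all in-blink/out-of-blink regions
(`bar_pooling="per_blink"` averages per-blink means instead); an
undefined BAR (no positive background sample) rejects the signal. The
good-blink ratio counts *all* potential blinks in the amplitude band by
default; requiring the good tier as well is selectable
(`good_ratio_numerator="good_tier"`), since usage varies between the
ratio's two published descriptions. Selection ties break by larger good
ratio, then input order, for determinism.

## Ocular indices

Per blink: zero duration (`rightZero − leftZero`), base duration
(`rightBase − leftBase`), half-zero and half-base widths (levels at half
the peak measured from zero and from the left-base amplitude, crossings
linearly interpolated between frames), tent duration (distance between
the tent lines' x-intercepts), and pAVR/nAVR
(`100 × peak / extreme stroke velocity`, centiseconds; amplitude units
cancel). A half level never crossed on one side, or a flat stroke,
leaves that measure missing for the blink; summaries exclude missing
values pairwise and use sample (n−1) SDs. Percent time closed is defined
here — no formula is standard — as the percent of the recording covered
by the half-zero widths of used blinks: the half-zero onset tracks the
moment the eyelid first crosses the pupil, the conventional eyes-closed
proxy. Blink rate is used blinks per recording minute.

## Synthetic generator

The generator emulates exactly what the detector models: rounded
tent-shaped positive blinks, sharp saccade ramps, and stationary Gaussian
background noise, from one seeded generator (same seed ⇒ bit-identical
trace).

Defaults — the study conditions used by the tests and the acceptance
script, chosen once:

* 256 Hz, 5-minute recordings; blink rate 20/min (Poisson, or an exact
  count on request), events ≥ 0.5 s apart.
* Half-zero duration 0.12 ± 0.02 s per blink; a tent of base
  `2 × halfZero` has half-amplitude width `halfZero` for any rise/fall
  split. The closing stroke takes 40% of the base (eyelid closing is
  faster than reopening).
* Peak amplitude 220 ± 40 µV — the scale and relative spread of upper
  vertical EOG blinks.
* Background noise SD 22 µV = amplitude/10, white Gaussian; optional
  slow sinusoidal drift (0.05 Hz) that the 1 Hz high-pass removes.
* Blinks are tents convolved with a 25 ms Hann kernel (strokes stay
  linear over the inner 80%, R² ≥ 0.98 at zero noise); saccades are
  unsmoothed ramps rising in 15–25 ms at about half the blink amplitude,
  which places their measured pAVR at or below 3 cs.

What it does **not** emulate: 1/f EEG background, alpha bursts,
non-stationary noise, amplitude drift across the recording, blink pairs
closer than 0.5 s, overlapping blink+saccade complexes, and channel
cross-talk. Passing tests therefore demonstrate the algorithm's
correctness and its behaviour under controlled SNR — not performance on
every pathology of real recordings.

## Measurement-chain bias (important caveat)

Durations are measured on the [1, 20] Hz trace. Removing the sub-1 Hz
content of a ~0.24 s-base pulse lowers its peak and pulls its zero
crossings and half-level crossings inward: an ideal brick-wall [1, 20] Hz
filter turns a clean tent of true half-width 0.121 s into a measured
half-width 0.097 s (−19%); this package's FIR gives 0.096–0.099 s on the
same blinks. The bias is a deterministic property of any filter with this
passband, not of noise — recovered *rates* are unaffected, and duration
*comparisons* across conditions remain valid, but absolute durations read
systematically low by roughly 15–20% for physiological blink widths. The
same mechanism leaves measured blink intervals slightly inside the true
event support.

At background noise of one tenth of the blink amplitude, per-stroke R²
values concentrate near 0.97, so a minority of true blinks fall below
the 0.90 good tier and the best tier samples the amplitude distribution
unevenly; the pipeline then reports 83–90% of the true blinks as used.
This is the documented behaviour of the published criteria at that SNR,
comparable to the miss rates reported for the original method, and is
reproduced, not hidden, by the acceptance script.

## Problem sizes

Unit and property tests run on constructed traces (≤ a few thousand
frames) and 30–120 s synthetic recordings; end-to-end and selection
checks use 5-minute recordings, with selection robustness estimated over
100 seeded two-channel trials. The full suite completes in well under a
minute; the acceptance script in about half a minute.
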