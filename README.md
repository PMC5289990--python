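# ocublink

Automated extraction of eye blinks and ocular indices — blink rate, five
blink-duration measures, amplitude–velocity ratios, percent time closed —
from EEG channels, EOG leads, or independent-component activations.

Eye blinks appear in frontal EEG and upper vertical EOG as large, positive,
rounded tent-shaped excursions. Their rate, duration and velocity profile
index drowsiness and fatigue, but hand-marking them across hours of
recording is impractical. `ocublink` turns raw multichannel recordings into
per-blink tables and per-recording summaries fully automatically, and —
just as importantly — tells you when its result should not be trusted
(signal rejected, marginal selection, dataset failed).

## The method

For every candidate time series ("signal") the pipeline:

1. **Detects potential blinks.** The signal is band-pass filtered to
   [1, 20] Hz (zero-phase FIR); maximal runs above
   `mean + 1.5·SD` of the filtered trace become *potential blinks*,
   after merging runs closer than 50 ms and discarding runs not longer
   than 50 ms.
2. **Fits blink landmarks.** Per blink: the peak (`maxFrame`, first frame
   on ties); the flanking zero crossings `leftZero`/`rightZero` (falling
   back to the inter-blink amplitude minimum when the trace never returns
   to zero); the bases — first strict local minima outward of the
   maximum-velocity frames of the up- and down-strokes; and a **tent
   fit**: ordinary least-squares lines through the inner 80% (by
   amplitude) of each stroke. The lines' intersection is the `tentPeak`;
   their fit quality `leftR2`/`rightR2` measures how blink-like the
   excursion is.
3. **Gates the signal.** The blink–amplitude ratio
   `BAR = mean(in-blink amplitude) / mean(positive out-of-blink amplitude)`
   must lie in [3, 50]; outside that range the signal is rejected as too
   noisy or too empty.
4. **Discriminates blinks from other eye movements.** Blinks are tiered
   *good/better/best* at stroke R² ≥ 0.90/0.95/0.98 (the weaker stroke
   decides). With `m` = median and `s` = robust SD
   (`1.4826 × MAD`) of the best-tier peak amplitudes, best blinks outside
   `m ± 5s` and good blinks outside `m ± 2s` are dropped (amplitude
   distribution criterion), and candidates with
   `pAVR = 100·peak/max-up-stroke-velocity ≤ 3` centiseconds are dropped
   as saccades (alert-subject blinks sit near 4 cs).
5. **Selects the best signal.** Among gated signals with a good-blink
   ratio ≥ 70%, the one with the most good blinks wins; if none reaches
   70% the winner is flagged *marginal*. No survivor ⇒ the dataset
   *fails* (e.g. eyes-closed recordings), which is a status, not an error.
6. **Reports indices** over the selected signal's used blinks: blink
   rate (blinks/min), zero/base/half-zero/half-base/tent durations
   (seconds, sub-frame interpolated at the half levels), pAVR/nAVR
   (centiseconds), and percent time closed (sum of half-zero widths over
   the recording length).

Blinks found on several usable signals are merged into cross-signal
groups (seeded where any usable signal exceeds 1.5 robust SDs above
zero), with member counts per group. For IC scalp maps a frontality
figure of merit (frontal-minus-rear hemisphere mean, after sign
reorientation) ranks blink-related components.

## Worked example

Generate a 5-minute synthetic recording (one blink channel at 20
blinks/min plus one pure-noise channel), run the pipeline, and read the
summary:

```bash
blink synth --out rec.tsv --duration 300 --with-noise-channel --seed 7
blink run rec.tsv --srate 256 --out-dir out
```

```
status: selected
selected signal: s1
used blinks: 94  rate: 18.80/min  %TEC: 3.03
outputs: out/summary.json, out/blinks.tsv, out/signals.tsv
```

The noise channel is rejected at the BAR gate; the blink channel is
selected with 94 used blinks, i.e. a blink rate of 18.8/min. From
`out/summary.json`:

```json
"blinkRatePerMin": 18.8,
"pctTimeClosed": 3.0286,
"means": {
  "halfZeroDur": 0.0967, "halfBaseDur": 0.1244,
  "zeroDur": 0.1889, "baseDur": 0.2611, "tentDur": 0.1867,
  "pAVR": 5.12, "nAVR": 6.52
}
```

The half-zero duration has the smallest spread of the five duration
measures (SD 0.014 s here) and the half-base duration is slightly longer
than the half-zero duration — both expected of the measure definitions.
`out/blinks.tsv` holds one row per potential blink with all landmark
frames, stroke R² values, tier, used-flag, durations and AVRs.

The same pipeline runs on real data: `blink run recording.edf` reads
EDF/EDF+/BDF directly (channel kinds inferred from labels, EOG leads
recognised case-insensitively), and `blink batch *.edf --out
collection.tsv` tabulates a whole collection with per-dataset status
counts.

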