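# Methods

## Signal model

The dynamometer pedal, loaded by a strain-gauge bridge, outputs a voltage
proportional to ankle torque. A recording of one measurement is a
concatenation of one-second oscilloscope memory buffers (32 by default)
sampled at fs = 6103.5469 Hz and digitized at 8 bits over a symmetric
±2 V full scale, so the quantum is 4 V / 256 = 15.625 mV. A correct
measurement contains three maximal voluntary isometric contractions
(MVICs): near-rectangular plateaus held for several seconds, one per
~10 s period, riding on a relaxed-pedal offset of a few hundred
millivolts. Plantar flexion deflects the voltage above the offset,
dorsiflexion below it. The signal spans roughly 1–2 V peak to peak, its
useful energy lies well below 10 Hz, and mains-powered acquisition adds
50 Hz hum plus wideband noise.

The synthetic generator (`synth`) reproduces exactly these conditions as
its defaults: offset 0.5 V, plateau amplitudes (1.2, 1.3, 1.25) V, 10 s
period, 5 s holds, 50 mV hum at 50 Hz, 20 mV Gaussian noise, 8-bit
quantization, seeded RNG. Plateau edges are raised-cosine ramps of 0.3 s
because instantaneous edges are unphysiological and would ring
unrealistically under IIR filtering. What the generator does **not**
emulate: true motor-unit force variability, electrode-free mechanical
resonances of the rig, serially correlated baseline wander, or clinical
DPN signatures — its drift/tremor/fatigue modes are parametric stand-ins.
Passing tests therefore demonstrate correctness of the *chain*, not
clinical validity on patient data.

## Filter design

The low-pass must keep at least 12 Hz of bandwidth (11th harmonic of a
1 s pedal action) while rejecting the electric network frequency (ENF).
A Chebyshev type II (inverse Chebyshev) filter has a flat passband and
equiripple stopband whose ripple touches exact zeros. The 5th-order
design `cheby2(5, 50, 29.3935/(fs/2))` has finite zeros at
ws/cos(π/10) and ws/cos(3π/10); the design cut of 29.3935 Hz is chosen
so the *second* zero lands exactly on 50 Hz — the second notch is wider
and tolerates the ENF's natural variation. Measured from the
coefficients at fs = 6103.5469 Hz:

- minimum attenuation over 49.5–50.5 Hz: 78.68 dB,
- −3 dB cut-off: 15.04 Hz (bandwidth condition satisfied),
- lowest notch: 30.91 Hz (it has no filtering role of its own).

These numbers are recomputed at run time by `scripts/acceptance.py` and
asserted in the test suite; the design was additionally cross-checked
against an independent implementation (R's `signal::cheby2`), which
agrees to ~1e-5 dB.

Numerical choices:

- **Zero-phase application.** Processing is offline, so the filter runs
  forward–backward (`sosfiltfilt`); plateau timing and peak locations are
  undelayed and the effective stopband attenuation doubles in dB. A
  causal single-pass mode is available (`zero_phase=False`).
- **Second-order sections.** The filter is designed in b/a form (the
  classical command) but applied as cascaded biquads. The b/a expansion
  of a 5th-order design carries ~1e-5 dB of coefficient-rounding error at
  DC; the two realizations are asserted equivalent over the passband to
  1e-4 dB, the level that rounding permits.
- **Stability.** `check_stability` tests pole moduli exactly. In double
  precision the design remains stable well beyond 50 kHz sampling (max
  pole modulus 0.9994 at 80 kHz); instability reported for single-precision
  or less careful realizations is not reproduced by the sos path, but
  `design_cheby2` still raises `UnstableDesign` if a pole modulus reaches
  1 and warns below 4 kHz, where the rejection notch shifts off the ENF.
- **Notch reporting.** Exact zeros are −∞ dB; reported magnitude is
  floored at −300 dB for serialization and plotting.

## Offset detection

The relaxed-pedal offset occupies ~50% of a correct recording and is its
most stable level, so the mode of the amplitude histogram is the most
probable offset. Histogram bins default to one ADC quantum (15.625 mV)
wide and are aligned so quantized code levels fall at bin centers; ties
between equal-count bins break toward the lower-voltage bin (the offset
lies below plantar plateaus; after direction detection the orientation
handling is symmetric). The histogram is computed on the filtered signal,
which precedes offset detection in the chain.

When the baseline wanders, plateau samples can out-count baseline samples
and the full-range mode lands on the plateau — a fake offset. **Level
windowing** restricts the histogram to expected_offset ± half-width
(defaults 0.5 ± 0.3 V, both per-cohort configurable); plateau levels then
cannot compete. On a seeded 200-recording benchmark with 10% drifting
baselines, the windowed detector makes strictly fewer fake calls than the
full-range one (0 vs. one per drifting case at defaults) — the synthetic
analogue of the order-of-magnitude improvement seen on real cohorts,
reproducible only qualitatively because no recordings are deposited and
the original window bounds are unpublished.

Offset stability re-detects the offset per baseline interval (windowed
around the global estimate) and reports the max−min drift; drift above
0.1 V (default) flags the recording, with DPN-context routing to operator
review rather than rejection.

## Feature extraction

Direction is whichever excursion about the offset is larger;
excursions differing by less than one quantum are indeterminate (flat or
faulty signal). Contractions are maximal runs where the
direction-oriented excursion exceeds 50% (default) of the global
excursion and lasts ≥1 s — the shortest plausible pedal action. Plateau
statistics use the central 80% of each segment to exclude rise/fall
transients. Per-contraction MVIC amplitude is the oriented difference
between segment peak and offset; both the best and the mean across
contractions are exported, since either convention appears in practice.
Inter-MVIC variation is (max−min)/mean plus the SD of the amplitudes;
intra-MVIC steadiness is plateau SD divided by the plateau's mean
*excursion about the offset* — the offset-relative form makes the metric
exactly invariant under reflecting a recording about its offset, which
the raw-mean form would not be. "Steadiness" has no canonical formula in
this field; these are this package's definitions, labelled as such.
Torque is a linear, origin-preserving gain (Nm/V) supplied by pedal
calibration; no default gain ships because calibration is rig-specific
(the 8-bit quantum corresponding to ≈0.5 Nm implies ≈32 Nm/V for the
original rig, used in tests only).

Symmetry contracts (tested): scaling the excursion about the offset by
c > 0 scales every amplitude by c; reflection about the offset flips the
direction and preserves all amplitudes and steadiness metrics. Both hold
to floating-point rounding (asserted at rtol 1e-9).

## Validation gate

All quality problems are report codes, never exceptions, so cohort
batches always complete. Trigger defaults (all configurable):

| check | default trigger |
|---|---|
| WRONG_CONTRACTION_COUNT | detected ≠ 3 expected |
| DIRECTION_KEYWORD_MISMATCH | detected direction ≠ folder keyword |
| SHORT_HOLD | any contraction-like run (0.2 s detection floor) < 1 s |
| DELAYED_ONSET | inter-onset period CV > 0.5 (weak proxy; command timing is unrecorded) |
| OFFSET_UNSTABLE | baseline drift > 0.1 V |
| OFFSET_UNDETECTABLE | no samples in the detection window |
| BODY_MOVEMENT_SPIKE | any sample > 6 robust SDs from its linearly detrended segment level |
| FATIGUE_DECREMENT | monotone amplitude decrease > 15% overall |
| TREMOR_OSCILLATION | 4–12 Hz plateau band variance > 1e-3 of the plateau's mean-square excursion |
| SUBMAXIMAL_EFFORT | weakest amplitude < 60% of the best |
| TECHNICAL_SIGNAL_FAULT | peak-to-peak < 0.2 V, ADC-rail pinning > 1%, or an unreadable/indeterminate signal |

Notes on the less obvious choices:

- The **spike** detector linearly detrends each scanned interval so slow
  baseline drift does not mimic a spike, floors the robust SD at half a
  quantum (quantized plateaus can have zero MAD), and excludes the first
  and last 0.25 s of the recording, where zero-phase filtering leaves a
  short hum-phase-dependent edge transient.
- The **tremor** fraction is normalized by the plateau's mean-square
  excursion about the offset rather than by its AC variance: after a
  15 Hz low-pass, most residual noise variance lies inside 4–12 Hz
  anyway, so an AC-relative fraction cannot separate tremor from clean
  noise; excursion-relative power can (clean ≈ 1e-6, 0.1 V tremor
  ≈ 3e-3 at default amplitudes).
- **Short holds** cannot be seen in the feature segments (segmentation
  already drops runs under the minimum hold), so the validator re-scans
  with a 0.2 s floor; a shortened contraction may therefore also fire
  WRONG_CONTRACTION_COUNT, which is correct — both statements are true.
- Whether a missing contraction is the participant's or the tester's
  fault is not decidable from the signal; one code covers both, with an
  operator-attribution note.
- With `dpn_context`, measurements whose *only* codes are
  OFFSET_UNSTABLE, FATIGUE_DECREMENT or TREMOR_OSCILLATION become
  `needs_review` instead of `invalid`: those patterns are expected in
  DPN and must not be auto-rejected. No quantitative rule separates
  pathological from erroneous instances — that judgement is explicitly
  the operator's, and no classifier is provided.

## Batch driver

`process_cohort` runs parse → read → filter → offset → features →
validate per folder, appends one summary row per measurement, and writes
CSV (canonical, byte-stable across reruns) plus a mirrored XLSX and a
per-folder log. One malformed folder flags one row and never aborts the
batch. Rows are cached keyed by a content hash of the folder's files, so
reruns over unchanged cohorts skip recomputation.

## Problem sizes in the test suite

The statistical benchmarks run on 200 seeded 32 s recordings (offset
recovery and the windowed-vs-full comparison), 20 recordings for MVIC
recovery at 20 mV noise, and one clean fixture plus one corrupted
recording per error mode for the validation registry. I/O-heavy batch
tests use a shortened protocol (12 buffers, 2 s holds every 4 s) that
preserves the 3-contraction structure.

## Known limitations

- The reader supports the text export dialect only (one time/voltage
  pair per line after a 3-line header); native binary, `.mat` and `.csv`
  variants are out of scope, and the exact header content of real
  exports is not modelled (the writer emits a documented placeholder).
- The published response plot of the filter places the first stopband
  notch near 27 Hz; the printed design command mathematically puts it at
  30.9 Hz (confirmed by two independent implementations and the analytic
  zero locations). This package reports the computed value.
- DELAYED_ONSET is a weak proxy (period irregularity); true
  command-to-onset latency would need the command timestamps, which the
  recordings do not contain.
- Windowed offset detection assumes the cohort's expected offset range
  is configured sensibly; a grossly mis-set window turns into
  OFFSET_UNDETECTABLE rather than silent misdetection.
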