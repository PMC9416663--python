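# ankledyn

Signal processing for portable, custom-made ankle-torque dynamometry.

A strain-gauge pedal dynamometer converts ankle torque during maximal
voluntary isometric contractions (MVICs) into a voltage recorded by a
PC oscilloscope as folders of one-second text buffers. Before those
recordings can feed clinical statistics — for example in studies of
diabetic peripheral neuropathy (DPN) — each one must be filtered, its
relaxed-pedal baseline ("offset") found, its contractions measured, and
its quality judged. `ankledyn` implements that whole chain:

- **I/O** — read the multi-buffer text dialect (3-line header, local time
  axis restarting at zero per buffer), reconstruct the global time axis,
  and parse folder-name keywords (`Sub 01`, `LFT`/`RX`, `PFlex`/`Dorsi`,
  `+5,`/`0,`/`-5,`, session flags) into structured metadata.
- **Filtering** — a 5th-order Chebyshev type II low-pass designed as
  `cheby2(5, 50, 29.3935/(fs/2))`. The type II stopband ripple creates
  exact zeros; the design cut is chosen so the second, wider notch lands
  on the 50 Hz electric network frequency (ENF), so one filter both
  band-limits the pedal signal (−3 dB at ≈15 Hz) and rejects mains hum
  (≥78 dB across 49.5–50.5 Hz at fs = 6103.5469 Hz). Applied zero-phase
  via second-order sections.
- **Offset detection** — the mode of a quantum-aligned amplitude
  histogram, optionally *level-windowed* around the expected offset so a
  contraction plateau cannot masquerade as the baseline; plus per-segment
  drift tracking.
- **Features** — contraction segmentation, direction detection, MVIC
  amplitude `|peak − offset|` oriented by direction, linear Nm/V torque
  conversion, inter-MVIC variation and intra-MVIC steadiness.
- **Validation** — an error-taxonomy gate (wrong contraction count,
  keyword/direction mismatch, short holds, delayed onsets, offset
  instability, movement spikes, fatigue decrement, tremor, submaximal
  effort, technical faults) with DPN-aware routing: pathology-compatible
  patterns go to operator review instead of automatic rejection.
- **Synthetic data** — a seeded generator of realistic pedal recordings
  (3 plateaus ~10 s apart, 1–2 Vpp, few-hundred-mV offset, 50 Hz hum,
  noise, 8-bit ±2 V quantization) with injectable error modes, so the
  chain is fully testable without clinical data.

## Worked example

```python
import ankledyn as ad

# one synthetic measurement written in the oscilloscope folder dialect
rec, truth = ad.generate_measurement(ad.SynthParams(rng_seed=7))
folder = ad.write_folder(rec, "20210909-0001 Sub 01,LFT,+5,PFlex", "demo")

res = ad.process_measurement(folder)
print(res.key.subject_id, res.key.foot, res.key.direction_flag)
print(f"offset  {res.offset.offset_v * 1e3:.1f} mV")
print("MVICs  ", [f"{a:.3f}" for a in res.features.mvic_amplitudes_v], "V")
print(f"peak    {res.features.mvic_peak_v:.3f} V")
print(res.report.status, sorted(res.report.codes))
```

prints

```
01 left plantar
offset  500.0 mV
MVICs   ['1.204', '1.303', '1.254'] V
peak    1.303 V
valid []
```

The offset is the detected relaxed-pedal level; the three MVIC values are
the per-contraction excursions of the plateau peaks above it (the ground
truth here was 1.2, 1.3, 1.25 V before noise, hum and 8-bit
quantization), `peak` is the best contraction, and the empty validation
report means the measurement passes all quality gates. With a configured
pedal calibration (e.g. 32 Nm/V) the peak maps to torque in Nm.

Batch use from a shell:

```sh
ankledyn simulate --out cohort --subjects 3 --corrupt drop_contraction
ankledyn process cohort --out results
ankledyn plot "cohort/20210909-0000 Sub 01,LFT,0,PFlex"
ankledyn index cohort --biometrics subjects.csv
```

`process` writes `summary.csv` (canonical) and `summary.xlsx` with one
row per measurement: offset, per-contraction amplitudes, peak/mean MVIC,
torque if calibrated, steadiness metrics, validation status and codes.

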