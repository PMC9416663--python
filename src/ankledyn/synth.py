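"""Seeded synthetic pedal-press recordings and error injection.

No dynamometer recordings are publicly deposited, so the whole chain is
exercised on synthetic measurements that imitate the voltage signal's
statistics: a baseline offset of a few hundred millivolts, three
near-rectangular MVIC plateaus roughly 10 s apart giving a 1-2 V
peak-to-peak span, 50 Hz mains hum, wideband Gaussian noise, and 8-bit
quantization over a symmetric ±2 V full scale at 6103.5469 Hz — the
acquisition configuration of the oscilloscope the chain was built for.

Plateau edges are raised-cosine ramps (default 0.3 s): true square edges
are unphysiological and would ring unrealistically under IIR filtering.

:func:`inject_error` turns a clean measurement into one exhibiting a
named failure mode from the measurement-error taxonomy (missing or short
contractions, delayed onsets, baseline drift, fatigue decrement, tremor,
body-movement spikes, submaximal effort, flipped direction, technical
flatline/saturation).  Corruption is applied by regenerating the waveform
from the stored parameters, so the identity corruption reproduces the
original recording bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ParamOutOfRange, UnknownMode
from .io_picoscope import HEADER_LINES, Recording, parse_folder_name

#: error-mode tags understood by :func:`inject_error`
ERROR_MODES = (
    "drop_contraction", "short_hold", "delayed_onset", "baseline_drift",
    "plateau_decrement", "tremor", "movement_spike", "submaximal_dip",
    "direction_flip", "flatline", "saturation",
)


@dataclass(frozen=True)
class SynthParams:
    """Generator parameters; the defaults are the nominal study conditions."""

    fs_hz: float = 6103.5469
    n_buffers: int = 32
    buffer_s: float = 1.0
    offset_v: float = 0.5
    plateau_amplitudes_v: tuple[float, ...] = (1.2, 1.3, 1.25)
    period_s: float = 10.0
    hold_s: float = 5.0
    direction: str = "plantar"
    hum_amp_v: float = 0.05
    hum_freq_hz: float = 50.0
    noise_sd_v: float = 0.02
    drift_v_per_s: float = 0.0
    quantize: bool = True
    adc_bits: int = 8
    adc_range_v: float = 2.0
    rng_seed: int = 0
    ramp_s: float = 0.3
    first_onset_s: float = 2.5
    # corruption hooks (neutral by default); set via inject_error
    onset_delays_s: tuple[float, ...] = ()
    hold_overrides_s: tuple[float | None, ...] = ()
    tremor_hz: float = 8.0
    tremor_amp_v: float = 0.0
    spikes: tuple[tuple[float, float, float], ...] = ()  # (time_s, amp_v, width_s)
    flatline: bool = False
    allow_clipping: bool = False

    @property
    def quantum_v(self) -> float:
        return 2 * self.adc_range_v / 2 ** self.adc_bits


@dataclass
class GroundTruth:
    """Construction-time truth attached to every synthetic measurement."""

    offset_v: float
    plateau_amplitudes_v: tuple[float, ...]
    direction: str
    segments: list[tuple[float, float]]  # (onset, end of hold) per contraction
    injected_modes: list[str]
    params: SynthParams = field(repr=False, default=None)


def _raised_cosine_env(t: np.ndarray, onset: float, hold: float,
                       ramp: float) -> np.ndarray:
    """0->1->0 envelope: cosine ramp up at onset, hold, cosine ramp down."""
    env = np.zeros_like(t)
    up = (t >= onset - ramp) & (t < onset)
    env[up] = 0.5 * (1 + np.cos(np.pi * (onset - t[up]) / ramp))
    on = (t >= onset) & (t <= onset + hold)
    env[on] = 1.0
    down = (t > onset + hold) & (t <= onset + hold + ramp)
    env[down] = 0.5 * (1 + np.cos(np.pi * (t[down] - onset - hold) / ramp))
    return env


def generate_measurement(p: SynthParams = SynthParams()
                         ) -> tuple[Recording, GroundTruth]:
    """Generate one synthetic measurement with its ground truth.

    Fully reproducible from ``p.rng_seed``.  Raises
    :class:`ParamOutOfRange` when the deterministic signal levels would
    clip the ADC full scale (unless ``allow_clipping`` is set, the hook
    the saturation error mode uses).
    """
    n_per = int(round(p.fs_hz * p.buffer_s))
    n = n_per * p.n_buffers
    t = np.arange(n) / p.fs_hz
    sign = 1.0 if p.direction == "plantar" else -1.0

    baseline = p.offset_v + p.drift_v_per_s * t
    v = baseline.copy()
    truth_segments: list[tuple[float, float]] = []

    if not p.flatline:
        for k, amp in enumerate(p.plateau_amplitudes_v):
            delay = p.onset_delays_s[k] if k < len(p.onset_delays_s) else 0.0
            hold = p.hold_s
            if k < len(p.hold_overrides_s) and p.hold_overrides_s[k] is not None:
                hold = p.hold_overrides_s[k]
            onset = p.first_onset_s + k * p.period_s + delay
            env = _raised_cosine_env(t, onset, hold, p.ramp_s)
            v += sign * amp * env
            if p.tremor_amp_v:
                v += sign * p.tremor_amp_v * env * np.sin(2 * np.pi * p.tremor_hz * t)
            truth_segments.append((onset, onset + hold))

    for (ts, amp, width) in p.spikes:
        v += amp * np.exp(-0.5 * ((t - ts) / (width / 2)) ** 2)

    if not p.allow_clipping:
        lo, hi = v.min(), v.max()
        if hi > p.adc_range_v or lo < -p.adc_range_v:
            raise ParamOutOfRange(
                f"signal spans [{lo:.3f}, {hi:.3f}] V, outside ±{p.adc_range_v} V")

    rng = np.random.default_rng(p.rng_seed)
    phase = rng.uniform(0, 2 * np.pi)
    v = v + p.hum_amp_v * np.sin(2 * np.pi * p.hum_freq_hz * t + phase)
    v = v + rng.normal(0.0, p.noise_sd_v, size=n)

    if p.quantize:
        q = p.quantum_v
        half = 2 ** (p.adc_bits - 1)
        codes = np.clip(np.round(v / q), -half, half - 1)
        v = codes * q

    rec = Recording(times=t, voltages=v, fs=p.fs_hz, n_buffers=p.n_buffers,
                    source="synthetic")
    truth = GroundTruth(offset_v=p.offset_v,
                        plateau_amplitudes_v=tuple(p.plateau_amplitudes_v),
                        direction=p.direction, segments=truth_segments,
                        injected_modes=[], params=p)
    return rec, truth


def inject_error(rec: Recording, truth: GroundTruth, mode: str,
                 p: dict | None = None, seed: int | None = None
                 ) -> tuple[Recording, GroundTruth]:
    """Corrupt a synthetic measurement with one named error mode.

    ``p`` overrides the mode's default corruption parameters; ``seed``
    overrides the regeneration seed (default: keep the original, so a
    zero-strength corruption is the identity).  Raises
    :class:`UnknownMode` for an unrecognized tag.
    """
    if mode not in ERROR_MODES:
        raise UnknownMode(f"{mode!r}; known modes: {ERROR_MODES}")
    p = dict(p or {})
    sp = truth.params
    if seed is not None:
        sp = replace(sp, rng_seed=seed)

    amps = list(sp.plateau_amplitudes_v)
    if mode == "drop_contraction":
        k = p.get("index", len(amps) - 1)
        del amps[k]
        sp = replace(sp, plateau_amplitudes_v=tuple(amps))
    elif mode == "short_hold":
        k = p.get("index", 1)
        hold = p.get("hold_s", 0.5)
        overrides = [None] * len(amps)
        overrides[k] = hold
        sp = replace(sp, hold_overrides_s=tuple(overrides))
    elif mode == "delayed_onset":
        k = p.get("index", 1)
        delay = p.get("delay_s", 4.0)
        delays = [0.0] * len(amps)
        delays[k] = delay
        sp = replace(sp, onset_delays_s=tuple(delays))
    elif mode == "baseline_drift":
        sp = replace(sp, drift_v_per_s=p.get("drift_v_per_s", 0.006))
    elif mode == "plateau_decrement":
        frac = p.get("decrement_frac", 0.35)
        a0 = max(amps)
        sp = replace(sp, plateau_amplitudes_v=tuple(
            a0 * (1 - frac * k / (len(amps) - 1)) for k in range(len(amps))))
    elif mode == "tremor":
        sp = replace(sp, tremor_amp_v=p.get("amp_v", 0.1),
                     tremor_hz=p.get("freq_hz", 8.0))
    elif mode == "movement_spike":
        ts = p.get("time_s", sp.first_onset_s + sp.period_s - 1.5)  # mid-baseline
        sp = replace(sp, spikes=sp.spikes + (
            (ts, p.get("amp_v", 0.4), p.get("width_s", 0.15)),))
    elif mode == "submaximal_dip":
        k = p.get("index", 1)
        amps[k] *= p.get("factor", 0.55)
        sp = replace(sp, plateau_amplitudes_v=tuple(amps))
    elif mode == "direction_flip":
        sp = replace(sp, direction="dorsi" if sp.direction == "plantar" else "plantar")
    elif mode == "flatline":
        sp = replace(sp, flatline=True)
    elif mode == "saturation":
        k = p.get("index", 1)
        amps[k] = p.get("amplitude_v", sp.adc_range_v - sp.offset_v + 0.3)
        sp = replace(sp, plateau_amplitudes_v=tuple(amps), allow_clipping=True)

    new_rec, new_truth = generate_measurement(sp)
    new_truth.injected_modes = truth.injected_modes + [mode]
    return new_rec, new_truth


_HEADER = ("Time\tChannel A\n",
           "(s)\t(V)\n",
           "ankledyn synthetic buffer export\n")


def write_folder(rec: Recording, name: str, dest: str | Path = ".") -> Path:
    """Write a recording as a measurement folder in the text-buffer dialect.

    Emits one file per buffer, named ``<name><two-digit suffix>.txt`` with
    a 3-line header and the local time axis restarting at zero per buffer.
    The folder name must parse under the keyword grammar.  Values are
    printed at fixed precision (ns / µV), so a write-read-write cycle is
    byte-identical in the payload lines.
    """
    parse_folder_name(name)  # raises if the name is not a valid key
    folder = Path(dest) / name
    folder.mkdir(parents=True, exist_ok=True)
    n = len(rec.voltages)
    if n % rec.n_buffers:
        raise ValueError("sample count not divisible by n_buffers")
    n_per = n // rec.n_buffers
    assert HEADER_LINES == len(_HEADER)
    for k in range(rec.n_buffers):
        sl = slice(k * n_per, (k + 1) * n_per)
        t_local = rec.times[sl] - rec.times[sl.start]
        with open(folder / f"{name}{k + 1:02d}.txt", "w") as fh:
            fh.writelines(_HEADER)
            for t, v in zip(t_local, rec.voltages[sl]):
                fh.write(f"{t:.9f}\t{v:.6f}\n")
    return folder
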