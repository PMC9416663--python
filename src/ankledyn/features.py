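"""Contraction segmentation and MVIC feature extraction.

A valid recording holds (by protocol) three maximal voluntary isometric
contractions (MVICs): near-rectangular plateaus about 10 s apart, each held
for several seconds, riding on the relaxed-pedal offset.  Plantar flexion
deflects the pedal voltage above the offset, dorsiflexion below it, so the
MVIC amplitude is the oriented excursion of the plateau peak from the
offset, and torque follows by the linear pedal calibration (Nm/V).

Steadiness conventions: the per-contraction plateau statistics are taken
over the central 80% of each segment (10% trimmed per side) to keep
rise/fall transients out; intra-MVIC steadiness is the plateau SD relative
to the plateau's mean excursion about the offset, which makes the metric
invariant under reflecting the recording about its offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import IndeterminateDirection, MissingCalibration
from .io_picoscope import Recording
from .offset_detection import ADC_QUANTUM_V, OffsetEstimate

#: default fraction of the global oriented excursion above which a sample
#: counts as "in contraction"
DEFAULT_THRESHOLD_FRAC = 0.5

#: shortest pedal action considered a contraction (s)
DEFAULT_MIN_HOLD_S = 1.0

#: fraction trimmed from each side of a segment for plateau statistics
PLATEAU_TRIM_FRAC = 0.10


@dataclass(frozen=True)
class ContractionSegment:
    start_s: float
    end_s: float
    peak_v: float           # raw voltage at the oriented extremum
    plateau_mean_v: float   # raw mean over the trimmed plateau
    plateau_sd_v: float

    @property
    def hold_duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class Calibration:
    """Linear voltage-to-torque conversion of the pedal load cell."""

    gain_nm_per_v: float
    reference: str = ""

    def __post_init__(self):
        if not np.isfinite(self.gain_nm_per_v) or self.gain_nm_per_v == 0:
            raise ValueError("calibration gain must be finite and nonzero")


@dataclass(frozen=True)
class FeatureSet:
    """Per-recording MVIC features handed to the validator and exporter."""

    offset_v: float
    direction: str                       # "plantar" | "dorsi"
    mvic_amplitudes_v: np.ndarray        # oriented |peak - offset| per contraction
    mvic_peak_v: float                   # best amplitude across contractions
    mvic_mean_v: float                   # mean amplitude across contractions
    fallback_amplitude_v: float          # oriented global extremum - offset
    inter_mvic_variation: float          # (max-min)/mean of amplitudes
    inter_mvic_sd_v: float
    intra_mvic_steadiness: np.ndarray    # plateau SD / plateau mean excursion
    n_contractions: int
    segments: list[ContractionSegment] = field(default_factory=list)
    mvic_torque_nm: float | None = None


def detect_direction(rec: Recording, offset: OffsetEstimate,
                     quantum_v: float = ADC_QUANTUM_V) -> str:
    """Infer contraction direction from the larger excursion about the offset.

    Plantar flexion if (max - offset) exceeds (offset - min), dorsiflexion
    otherwise.  Raises :class:`IndeterminateDirection` when the two
    excursions differ by less than one ADC quantum (e.g. a flat signal).
    """
    off = getattr(offset, "offset_v", offset)
    up = float(rec.voltages.max() - off)
    down = float(off - rec.voltages.min())
    if abs(up - down) < quantum_v:
        raise IndeterminateDirection(
            f"excursions differ by {abs(up - down) * 1e3:.2f} mV (< one quantum)")
    return "plantar" if up > down else "dorsi"


def _oriented(voltages: np.ndarray, offset_v: float, direction: str) -> np.ndarray:
    """Excursion from the offset, positive in the contraction direction."""
    e = np.asarray(voltages, float) - offset_v
    return e if direction == "plantar" else -e


def segment_contractions(rec: Recording, offset: OffsetEstimate | float,
                         direction: str,
                         threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
                         min_hold_s: float = DEFAULT_MIN_HOLD_S,
                         ) -> list[ContractionSegment]:
    """Find maximal runs where the oriented excursion exceeds a fraction of
    the global excursion and lasts at least ``min_hold_s``.

    ``offset`` may be an :class:`OffsetEstimate` or a bare voltage.
    Zero segments is a legal outcome (handed to the validator).
    """
    e = _oriented(rec.voltages, getattr(offset, "offset_v", offset), direction)
    peak = e.max()
    if peak <= 0:
        return []
    above = e > threshold_frac * peak
    segments = []
    for i0, i1 in _runs(above):
        dur = rec.times[i1 - 1] - rec.times[i0] + 1.0 / rec.fs
        if dur < min_hold_s:
            continue
        seg_e = e[i0:i1]
        seg_v = rec.voltages[i0:i1]
        ipk = i0 + int(np.argmax(seg_e))
        trim = int(np.floor(len(seg_v) * PLATEAU_TRIM_FRAC))
        core = seg_v[trim:len(seg_v) - trim] if len(seg_v) > 2 * trim else seg_v
        segments.append(ContractionSegment(
            start_s=float(rec.times[i0]), end_s=float(rec.times[i1 - 1]),
            peak_v=float(rec.voltages[ipk]),
            plateau_mean_v=float(core.mean()),
            plateau_sd_v=float(core.std(ddof=0))))
    return segments


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of True runs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def baseline_intervals(rec: Recording, segments: list[ContractionSegment],
                       margin_s: float = 0.5) -> list[tuple[float, float]]:
    """Non-contraction time intervals, keeping ``margin_s`` clear of each
    contraction edge so rise/fall ramps do not contaminate the baseline."""
    t0, t1 = float(rec.times[0]), float(rec.times[-1])
    if not segments:
        return [(t0, t1)]
    out = []
    cursor = t0
    for seg in sorted(segments, key=lambda s: s.start_s):
        hi = seg.start_s - margin_s
        if hi - cursor > 0.2:
            out.append((cursor, hi))
        cursor = max(cursor, seg.end_s + margin_s)
    if t1 - cursor > 0.2:
        out.append((cursor, t1))
    return out


def extract_mvic(rec: Recording, offset: OffsetEstimate, direction: str,
                 segments: list[ContractionSegment],
                 cal: Calibration | None = None) -> FeatureSet:
    """Extract MVIC amplitudes and steadiness metrics from segments.

    Per-contraction amplitude is the oriented difference between the
    segment peak and the offset (max - offset for plantar flexion,
    offset - min for dorsiflexion).  With no segments the amplitudes are
    empty and only the global-extremum fallback amplitude is informative.
    """
    off = getattr(offset, "offset_v", offset)
    amps = np.array([_oriented(np.array([s.peak_v]), off, direction)[0]
                     for s in segments])
    e = _oriented(rec.voltages, off, direction)
    fallback = float(e.max())

    steadiness = np.array([
        s.plateau_sd_v / abs(s.plateau_mean_v - off)
        if abs(s.plateau_mean_v - off) > 0 else np.inf
        for s in segments])

    if len(amps):
        peak = float(amps.max())
        mean = float(amps.mean())
        variation = float((amps.max() - amps.min()) / mean) if mean else 0.0
        sd = float(amps.std(ddof=0))
    else:
        peak = mean = variation = sd = 0.0

    torque = None
    if cal is not None:
        torque = voltage_to_torque(peak, cal)

    return FeatureSet(offset_v=off, direction=direction,
                      mvic_amplitudes_v=amps, mvic_peak_v=peak,
                      mvic_mean_v=mean, fallback_amplitude_v=fallback,
                      inter_mvic_variation=variation, inter_mvic_sd_v=sd,
                      intra_mvic_steadiness=steadiness,
                      n_contractions=len(segments), segments=list(segments),
                      mvic_torque_nm=torque)


def voltage_to_torque(amplitude_v: float, cal: Calibration | None) -> float:
    """Linear, origin-preserving voltage-to-torque conversion (Nm)."""
    if cal is None:
        raise MissingCalibration("no Nm/V gain configured")
    return cal.gain_nm_per_v * amplitude_v
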