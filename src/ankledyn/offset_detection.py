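"""Histogram-mode pedal-offset detection with level windowing.

The relaxed-pedal baseline ("offset") occupies roughly half of a correct
recording and is the most stable level in it, so the mode of the amplitude
histogram is the most probable offset.  When the participant's baseline
wanders, the contraction plateau can out-count the baseline and the
full-range histogram mode lands on the plateau — a fake offset.  Windowing
the histogram to a voltage band around the expected offset removes the
plateau levels from contention and recovers those measurements.

Histogram bins default to one ADC quantum wide (15.625 mV for the 8-bit,
±2 V acquisition) and are aligned with the quantized code levels, so each
code level falls at a bin center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyWindow, NoBaselineSegments
from .io_picoscope import Recording

#: ADC quantum of the 8-bit, ±2 V acquisition: 4 V / 2**8
ADC_QUANTUM_V = 4.0 / 256

#: default expected offset and half-width of the detection window (V)
DEFAULT_EXPECTED_OFFSET_V = 0.5
DEFAULT_HALF_WIDTH_V = 0.3

#: default max-min drift across baseline segments tolerated before the
#: offset is flagged unstable (V)
DEFAULT_DRIFT_TOLERANCE_V = 0.1


@dataclass(frozen=True)
class AmplitudeHistogram:
    bin_edges: np.ndarray  # V, strictly increasing
    counts: np.ndarray     # samples per bin; sums to the samples considered


@dataclass(frozen=True)
class OffsetEstimate:
    """Most probable pedal offset: center of the maximal-count bin."""

    offset_v: float
    bin_index: int
    histogram: AmplitudeHistogram
    window_v: tuple[float, float] | None  # None = full range
    windowed: bool


@dataclass(frozen=True)
class OffsetStability:
    """Per-baseline-segment offset levels and their max-min drift."""

    drift_v: float
    segment_levels: np.ndarray
    unstable: bool


def _aligned_edges(lo: float, hi: float, bin_width: float) -> np.ndarray:
    """Bin edges of width ``bin_width`` whose centers sit on integer
    multiples of ``bin_width`` (the quantized ADC code levels)."""
    k_lo = int(np.floor(lo / bin_width + 0.5))
    k_hi = int(np.floor(hi / bin_width + 0.5))
    return (np.arange(k_lo, k_hi + 2) - 0.5) * bin_width


def amplitude_histogram(values: np.ndarray,
                        bin_width_v: float = ADC_QUANTUM_V) -> AmplitudeHistogram:
    """Quantum-aligned amplitude histogram of a voltage series."""
    values = np.asarray(values, float)
    edges = _aligned_edges(values.min(), values.max(), bin_width_v)
    counts, edges = np.histogram(values, bins=edges)
    return AmplitudeHistogram(bin_edges=edges, counts=counts)


def estimate_offset(rec: Recording | np.ndarray,
                    window: tuple[float, float] | None = None,
                    bin_width_v: float = ADC_QUANTUM_V) -> OffsetEstimate:
    """Detect the pedal offset as the maximum of the amplitude histogram.

    With ``window=(low, high)`` only samples inside the window are
    histogrammed (level windowing).  Ties between equal-count bins break
    toward the lower-voltage bin.  Raises :class:`EmptyWindow` when no
    sample falls inside the window — the case where automatic offset
    detection is impossible.
    """
    values = rec.voltages if isinstance(rec, Recording) else np.asarray(rec, float)
    if values.size == 0:
        raise EmptyWindow("recording holds no samples")
    if window is not None:
        lo, hi = window
        if not lo < hi:
            raise ValueError("window low must be < high")
        values = values[(values >= lo) & (values <= hi)]
        if values.size == 0:
            raise EmptyWindow(f"no samples inside offset window [{lo}, {hi}] V")
    hist = amplitude_histogram(values, bin_width_v)
    idx = int(np.argmax(hist.counts))  # argmax takes the first = lowest bin on ties
    center = 0.5 * (hist.bin_edges[idx] + hist.bin_edges[idx + 1])
    return OffsetEstimate(offset_v=float(center), bin_index=idx, histogram=hist,
                          window_v=window, windowed=window is not None)


def default_window(expected_v: float = DEFAULT_EXPECTED_OFFSET_V,
                   half_width_v: float = DEFAULT_HALF_WIDTH_V,
                   direction: str = "plantar") -> tuple[float, float]:
    """Detection window around the expected relaxed-pedal offset.

    The window is symmetric about ``expected_v``; for dorsiflexion-dominant
    polarity the caller passes the direction-appropriate expected offset.
    """
    return (expected_v - half_width_v, expected_v + half_width_v)


def offset_stability(rec: Recording,
                     offset: OffsetEstimate,
                     segments: list[tuple[float, float]],
                     bin_width_v: float = ADC_QUANTUM_V,
                     half_width_v: float = DEFAULT_HALF_WIDTH_V,
                     drift_tolerance_v: float = DEFAULT_DRIFT_TOLERANCE_V,
                     ) -> OffsetStability:
    """Quantify offset drift across baseline (non-contraction) intervals.

    For every interval the local offset level is re-detected as the
    windowed histogram maximum (window centered on the global estimate);
    drift is the max-min of those levels.  ``unstable`` is set when drift
    exceeds the tolerance — a candidate for rejection, or for operator
    review in pathology-context batches.
    """
    if not segments:
        raise NoBaselineSegments("no baseline intervals supplied")
    win = (offset.offset_v - half_width_v, offset.offset_v + half_width_v)
    levels = []
    for (t0, t1) in segments:
        mask = (rec.times >= t0) & (rec.times <= t1)
        seg = rec.voltages[mask]
        if seg.size == 0:
            continue
        inside = seg[(seg >= win[0]) & (seg <= win[1])]
        values = inside if inside.size else seg  # fall back to unwindowed
        est = estimate_offset(values, bin_width_v=bin_width_v)
        levels.append(est.offset_v)
    if not levels:
        raise NoBaselineSegments("baseline intervals contain no samples")
    levels = np.asarray(levels)
    drift = float(levels.max() - levels.min())
    return OffsetStability(drift_v=drift, segment_levels=levels,
                           unstable=drift > drift_tolerance_v)
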