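"""Measurement validation gate and error taxonomy.

Every measurement passes through a validation step before its features
reach the statistician.  Failures fall into non-human (instrumental /
technical) and human (participant or tester) classes; all of them are
report *codes*, never exceptions, so a batch always completes.

Some patterns that look like errors — unstable offset, progressive force
decrement, tremor — are expected signal behaviour in participants with
diabetic peripheral neuropathy (DPN).  In a DPN-context batch those codes
route the measurement to ``needs_review`` for operator judgement instead
of automatic rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .features import FeatureSet, segment_contractions
from .io_picoscope import MeasurementKey, Recording
from .offset_detection import ADC_QUANTUM_V, OffsetEstimate, OffsetStability

# validation codes
WRONG_CONTRACTION_COUNT = "WRONG_CONTRACTION_COUNT"
DIRECTION_KEYWORD_MISMATCH = "DIRECTION_KEYWORD_MISMATCH"
SHORT_HOLD = "SHORT_HOLD"
DELAYED_ONSET = "DELAYED_ONSET"
OFFSET_UNSTABLE = "OFFSET_UNSTABLE"
OFFSET_UNDETECTABLE = "OFFSET_UNDETECTABLE"
BODY_MOVEMENT_SPIKE = "BODY_MOVEMENT_SPIKE"
FATIGUE_DECREMENT = "FATIGUE_DECREMENT"
TREMOR_OSCILLATION = "TREMOR_OSCILLATION"
TECHNICAL_SIGNAL_FAULT = "TECHNICAL_SIGNAL_FAULT"
SUBMAXIMAL_EFFORT = "SUBMAXIMAL_EFFORT"

ALL_CODES = frozenset({
    WRONG_CONTRACTION_COUNT, DIRECTION_KEYWORD_MISMATCH, SHORT_HOLD,
    DELAYED_ONSET, OFFSET_UNSTABLE, OFFSET_UNDETECTABLE, BODY_MOVEMENT_SPIKE,
    FATIGUE_DECREMENT, TREMOR_OSCILLATION, TECHNICAL_SIGNAL_FAULT,
    SUBMAXIMAL_EFFORT,
})

#: codes compatible with DPN pathology, routed to operator review in a
#: DPN-context batch rather than auto-rejected
REVIEW_ELIGIBLE = frozenset({OFFSET_UNSTABLE, FATIGUE_DECREMENT,
                             TREMOR_OSCILLATION})

#: the code each synthetic error-injection mode is designed to raise at
#: default thresholds (every validator path is reachable on synthetic data)
EXPECTED_CODE_FOR_MODE = {
    "drop_contraction": WRONG_CONTRACTION_COUNT,
    "short_hold": SHORT_HOLD,
    "delayed_onset": DELAYED_ONSET,
    "baseline_drift": OFFSET_UNSTABLE,
    "plateau_decrement": FATIGUE_DECREMENT,
    "tremor": TREMOR_OSCILLATION,
    "movement_spike": BODY_MOVEMENT_SPIKE,
    "submaximal_dip": SUBMAXIMAL_EFFORT,
    "direction_flip": DIRECTION_KEYWORD_MISMATCH,
    "flatline": TECHNICAL_SIGNAL_FAULT,
    "saturation": TECHNICAL_SIGNAL_FAULT,
}


@dataclass(frozen=True)
class ValidationConfig:
    """Numeric triggers of the validation gate.

    The taxonomy names the failure situations; the thresholds here are this
    package's documented defaults, all overridable per cohort.
    """

    expected_contractions: int = 3
    min_hold_s: float = 1.0
    drift_tolerance_v: float = 0.1
    spike_z_threshold: float = 6.0
    fatigue_decrement_frac: float = 0.15
    tremor_band_hz: tuple[float, float] = (4.0, 12.0)
    tremor_power_frac: float = 1e-3
    submaximal_frac: float = 0.6
    period_cv_threshold: float = 0.5
    technical_min_excursion_v: float = 0.2
    saturation_frac: float = 0.01
    adc_range_v: float = 2.0
    short_hold_floor_s: float = 0.2
    edge_guard_s: float = 0.25  # keep filter edge transients out of spike scans
    review_eligible_codes: frozenset[str] = REVIEW_ELIGIBLE
    dpn_context: bool = False


@dataclass(frozen=True)
class ValidationReport:
    status: str                       # "valid" | "invalid" | "needs_review"
    codes: frozenset[str]
    notes: dict[str, str]
    dpn_context: bool
    source: str = ""


@dataclass(frozen=True)
class BatchSummary:
    n_valid: int
    n_invalid: int
    n_needs_review: int
    code_counts: dict[str, int]
    failing_sources: list[str]


def _robust_sigma(x: np.ndarray, floor: float) -> float:
    mad = np.median(np.abs(x - np.median(x)))
    return max(1.4826 * mad, floor)


def _detrended(t: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Residual after removing a linear trend (keeps spikes, drops drift)."""
    if len(v) < 3:
        return v - v.mean()
    coef = np.polyfit(t, v, 1)
    return v - np.polyval(coef, t)


def _spike_detected(rec: Recording, features: FeatureSet,
                    cfg: ValidationConfig) -> bool:
    """Any sample deviating from its (linearly detrended) segment level by
    more than ``spike_z_threshold`` robust SDs, scanning plateau cores and
    baseline intervals away from contraction edges."""
    from .features import baseline_intervals  # local import avoids cycle

    intervals: list[tuple[float, float]] = []
    for s in features.segments:
        trim = 0.15 * (s.end_s - s.start_s)
        intervals.append((s.start_s + trim, s.end_s - trim))
    intervals.extend(baseline_intervals(rec, features.segments, margin_s=0.6))

    # zero-phase filtering leaves a short phase-dependent transient at the
    # recording edges; keep it out of the scan
    lo_t = rec.times[0] + cfg.edge_guard_s
    hi_t = rec.times[-1] - cfg.edge_guard_s

    floor = ADC_QUANTUM_V / 2
    for (t0, t1) in intervals:
        t0, t1 = max(t0, lo_t), min(t1, hi_t)
        mask = (rec.times >= t0) & (rec.times <= t1)
        if mask.sum() < 10:
            continue
        resid = _detrended(rec.times[mask], rec.voltages[mask])
        sigma = _robust_sigma(resid, floor)
        if np.max(np.abs(resid)) > cfg.spike_z_threshold * sigma:
            return True
    return False


def _tremor_detected(rec: Recording, features: FeatureSet,
                     cfg: ValidationConfig) -> bool:
    """Plateau band power in the tremor band exceeding a fraction of the
    plateau's mean-square excursion about the offset."""
    lo, hi = cfg.tremor_band_hz
    for s in features.segments:
        trim = 0.1 * (s.end_s - s.start_s)
        mask = (rec.times >= s.start_s + trim) & (rec.times <= s.end_s - trim)
        v = rec.voltages[mask]
        if len(v) < 64:
            continue
        excursion_power = float(np.mean((v - features.offset_v) ** 2))
        if excursion_power == 0:
            continue
        f, p = sps.periodogram(v - v.mean(), fs=rec.fs)
        band = (f >= lo) & (f <= hi)
        band_var = float(np.trapezoid(p[band], f[band])) if band.sum() > 1 else 0.0
        if band_var / excursion_power > cfg.tremor_power_frac:
            return True
    return False


def validate(rec: Recording,
             key: MeasurementKey | None,
             features: FeatureSet | None,
             offset_stab: OffsetStability | None,
             cfg: ValidationConfig = ValidationConfig(),
             precomputed_codes: dict[str, str] | None = None,
             source: str = "") -> ValidationReport:
    """Run the validation gate on one processed measurement.

    Upstream-stage failures (e.g. an undetectable offset) are passed in via
    ``precomputed_codes`` (code -> note).  All checks emit codes, never
    exceptions, so cohort batches always complete.
    """
    codes: dict[str, str] = dict(precomputed_codes or {})

    # technical faults are assessed on the raw excursions
    span = float(rec.voltages.max() - rec.voltages.min())
    if span < cfg.technical_min_excursion_v:
        codes[TECHNICAL_SIGNAL_FAULT] = (
            f"peak-to-peak span {span * 1e3:.0f} mV below "
            f"{cfg.technical_min_excursion_v * 1e3:.0f} mV")
    rail = cfg.adc_range_v - 2 * ADC_QUANTUM_V
    sat = float(np.mean(rec.voltages >= rail) + np.mean(rec.voltages <= -rail))
    if sat > cfg.saturation_frac:
        codes[TECHNICAL_SIGNAL_FAULT] = (
            f"{sat:.1%} of samples pinned at the ADC full scale")

    if features is not None:
        n = features.n_contractions
        if n != cfg.expected_contractions:
            codes[WRONG_CONTRACTION_COUNT] = (
                f"{n} contractions detected, {cfg.expected_contractions} expected "
                "(participant or tester-command attribution is an operator judgement)")

        if key is not None and features.direction != key.direction_flag:
            codes[DIRECTION_KEYWORD_MISMATCH] = (
                f"signal is {features.direction} but folder keyword says "
                f"{key.direction_flag}")

        # re-scan with a low floor so sub-min-hold contraction attempts surface
        short_runs = segment_contractions(
            rec, features.offset_v, features.direction,
            min_hold_s=cfg.short_hold_floor_s)
        held = [s.hold_duration_s for s in short_runs]
        if any(h < cfg.min_hold_s for h in held):
            worst = min(h for h in held if h < cfg.min_hold_s)
            codes[SHORT_HOLD] = f"contraction held only {worst:.2f} s (< {cfg.min_hold_s} s)"

        if n >= 3:
            onsets = np.array([s.start_s for s in features.segments])
            periods = np.diff(np.sort(onsets))
            cv = periods.std(ddof=1) / periods.mean()
            if cv > cfg.period_cv_threshold:
                codes[DELAYED_ONSET] = (
                    f"inter-contraction period CV {cv:.2f} (weak proxy: command "
                    "timing is not recorded)")

        amps = features.mvic_amplitudes_v
        if len(amps) >= 2:
            if np.all(np.diff(amps) < 0):
                overall = (amps[0] - amps[-1]) / amps[0]
                if overall > cfg.fatigue_decrement_frac:
                    codes[FATIGUE_DECREMENT] = (
                        f"monotone amplitude decrement of {overall:.0%}")
            if amps.min() < cfg.submaximal_frac * amps.max():
                codes[SUBMAXIMAL_EFFORT] = (
                    f"weakest contraction is {amps.min() / amps.max():.0%} "
                    "of the best")

        if _spike_detected(rec, features, cfg):
            codes[BODY_MOVEMENT_SPIKE] = "sample(s) far outside segment level"
        if _tremor_detected(rec, features, cfg):
            lo, hi = cfg.tremor_band_hz
            codes[TREMOR_OSCILLATION] = f"plateau oscillation in {lo}-{hi} Hz band"

    if offset_stab is not None and offset_stab.unstable:
        codes[OFFSET_UNSTABLE] = (
            f"offset drift {offset_stab.drift_v * 1e3:.0f} mV across baseline "
            f"segments (> {cfg.drift_tolerance_v * 1e3:.0f} mV)")

    if not codes:
        status = "valid"
    elif cfg.dpn_context and set(codes) <= cfg.review_eligible_codes:
        status = "needs_review"
    else:
        status = "invalid"
    return ValidationReport(status=status, codes=frozenset(codes),
                            notes=codes, dpn_context=cfg.dpn_context,
                            source=source)


def summarize_batch(reports: list[ValidationReport]) -> BatchSummary:
    """Counts per status and per code over one processed cohort."""
    if not reports:
        raise ValueError("no reports to summarize")
    code_counts: dict[str, int] = {}
    failing = []
    n = {"valid": 0, "invalid": 0, "needs_review": 0}
    for r in reports:
        n[r.status] += 1
        if r.status != "valid":
            failing.append(r.source)
        for c in r.codes:
            code_counts[c] = code_counts.get(c, 0) + 1
    return BatchSummary(n_valid=n["valid"], n_invalid=n["invalid"],
                        n_needs_review=n["needs_review"],
                        code_counts=code_counts, failing_sources=failing)
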