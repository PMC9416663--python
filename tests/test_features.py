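"""Direction detection, contraction segmentation, MVIC extraction and
torque conversion, including the exact symmetry properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ankledyn as ad
from ankledyn.errors import IndeterminateDirection, MissingCalibration
from ankledyn.features import Calibration
from ankledyn.offset_detection import ADC_QUANTUM_V


def make_recording(voltages, fs=1000.0):
    v = np.asarray(voltages, float)
    return ad.Recording(times=np.arange(len(v)) / fs, voltages=v,
                        fs=fs, n_buffers=1)


def reflect(rec, offset_v):
    return rec.replace_voltages(2 * offset_v - rec.voltages)


@pytest.fixture(scope="module")
def noiseless():
    """Noise-free, unquantized plantar recording with known plateaus."""
    p = ad.SynthParams(rng_seed=0, noise_sd_v=0.0, hum_amp_v=0.0,
                       quantize=False)
    return ad.generate_measurement(p)


class TestDetectDirection:
    def test_plantar_by_construction(self, noiseless):
        rec, truth = noiseless
        assert ad.detect_direction(rec, truth.offset_v) == "plantar"

    def test_reflection_flips_direction(self, noiseless):
        rec, truth = noiseless
        assert ad.detect_direction(reflect(rec, truth.offset_v),
                                   truth.offset_v) == "dorsi"

    def test_constant_signal_indeterminate(self):
        rec = make_recording(np.full(1000, 0.5))
        with pytest.raises(IndeterminateDirection):
            ad.detect_direction(rec, 0.5)


class TestSegmentContractions:
    def test_three_plateaus_about_ten_seconds_apart(self, noiseless):
        rec, truth = noiseless
        segs = ad.segment_contractions(rec, truth.offset_v, "plantar")
        assert len(segs) == 3
        onsets = [s.start_s for s in segs]
        periods = np.diff(onsets)
        assert np.allclose(periods, 10.0, atol=0.5)
        for s in segs:
            assert s.hold_duration_s == pytest.approx(5.0, abs=0.7)

    def test_constant_signal_zero_segments(self):
        rec = make_recording(np.full(1000, 0.5))
        assert ad.segment_contractions(rec, 0.5, "plantar") == []

    def test_short_plateau_excluded_by_min_hold(self):
        """Thresholded run-length oracle: a 0.4 s plateau with 1 s
        min-hold must not count as a contraction."""
        fs = 1000.0
        v = np.full(5000, 0.5)
        v[1000:1400] = 1.7    # 0.4 s
        v[3000:4500] = 1.7    # 1.5 s
        rec = make_recording(v, fs)
        segs = ad.segment_contractions(rec, 0.5, "plantar", min_hold_s=1.0)
        assert len(segs) == 1
        assert segs[0].start_s == pytest.approx(3.0, abs=0.01)
        segs_all = ad.segment_contractions(rec, 0.5, "plantar", min_hold_s=0.2)
        assert len(segs_all) == 2


class TestExtractMvic:
    def test_amplitudes_are_peak_minus_offset(self):
        """Max-minus-offset oracle on constructed plateau peaks."""
        fs = 1000.0
        v = np.full(30000, 0.5)
        for k, pk in enumerate([1.7, 1.8, 1.75]):
            v[int((2 + 10 * k) * fs):int((7 + 10 * k) * fs)] = pk
        rec = make_recording(v, fs)
        segs = ad.segment_contractions(rec, 0.5, "plantar")
        fs_out = ad.extract_mvic(rec, 0.5, "plantar", segs)
        np.testing.assert_allclose(sorted(fs_out.mvic_amplitudes_v),
                                   [1.2, 1.25, 1.3], atol=1e-12)
        assert fs_out.mvic_peak_v == pytest.approx(1.3)
        assert fs_out.n_contractions == 3

    def test_constant_signal_zero_amplitudes(self):
        rec = make_recording(np.full(1000, 0.5))
        out = ad.extract_mvic(rec, 0.5, "plantar", [])
        assert out.mvic_peak_v == 0.0
        assert out.n_contractions == 0
        assert len(out.mvic_amplitudes_v) == 0

    def test_default_signal_spans_one_to_two_vpp(self, default_coeffs):
        """With default generator conditions the signal span stays in the
        1-2 V peak-to-peak regime."""
        for seed in range(5):
            rec, _ = ad.generate_measurement(ad.SynthParams(rng_seed=seed))
            vpp = rec.voltages.max() - rec.voltages.min()
            assert 1.0 <= vpp <= 2.0 + 0.2  # small headroom for noise tails

    def test_recovery_within_three_sigma(self, default_coeffs):
        """Parameter recovery: with additive noise sigma = 20 mV the
        filtered-chain amplitudes land within 3 sigma of ground truth."""
        sigma = 0.02
        for seed in range(12):
            p = ad.SynthParams(rng_seed=3000 + seed, noise_sd_v=sigma)
            rec, truth = ad.generate_measurement(p)
            filt = ad.apply_lowpass(rec, default_coeffs)
            off = ad.estimate_offset(filt, window=ad.default_window())
            segs = ad.segment_contractions(filt, off, truth.direction)
            out = ad.extract_mvic(filt, off, truth.direction, segs)
            assert len(out.mvic_amplitudes_v) == len(truth.plateau_amplitudes_v)
            err = np.abs(np.sort(out.mvic_amplitudes_v)
                         - np.sort(truth.plateau_amplitudes_v))
            assert np.all(err <= 3 * sigma)


class TestSymmetries:
    def test_reflection_preserves_amplitudes_and_steadiness(self):
        """Reflecting a recording about its offset flips direction and
        leaves every amplitude and steadiness metric unchanged."""
        p = ad.SynthParams(rng_seed=11, quantize=False)
        rec, truth = ad.generate_measurement(p)
        off = truth.offset_v
        segs = ad.segment_contractions(rec, off, "plantar")
        a = ad.extract_mvic(rec, off, "plantar", segs)
        mirrored = reflect(rec, off)
        segs_m = ad.segment_contractions(mirrored, off, "dorsi")
        b = ad.extract_mvic(mirrored, off, "dorsi", segs_m)
        assert b.direction == "dorsi"
        np.testing.assert_allclose(b.mvic_amplitudes_v, a.mvic_amplitudes_v,
                                   rtol=1e-9)
        np.testing.assert_allclose(b.intra_mvic_steadiness,
                                   a.intra_mvic_steadiness, rtol=1e-9)
        assert b.inter_mvic_variation == pytest.approx(a.inter_mvic_variation,
                                                       rel=1e-9)

    @given(c=st.floats(min_value=0.05, max_value=1.1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_scale_equivariance(self, c):
        """Scaling the excursion about the offset by c scales every MVIC
        amplitude by c (relative thresholds make segmentation scale-free)."""
        p = ad.SynthParams(rng_seed=13, quantize=False)
        rec, truth = ad.generate_measurement(p)
        off = truth.offset_v
        segs = ad.segment_contractions(rec, off, "plantar")
        a = ad.extract_mvic(rec, off, "plantar", segs)
        scaled = rec.replace_voltages(off + c * (rec.voltages - off))
        segs_s = ad.segment_contractions(scaled, off, "plantar")
        b = ad.extract_mvic(scaled, off, "plantar", segs_s)
        np.testing.assert_allclose(b.mvic_amplitudes_v,
                                   c * a.mvic_amplitudes_v, rtol=1e-9)


class TestTorque:
    def test_zero_amplitude_zero_torque(self):
        assert ad.voltage_to_torque(0.0, Calibration(32.0)) == 0.0

    def test_quantum_implied_gain(self):
        """A 0.5 Nm error per 15.625 mV quantum implies 32 Nm/V, so 1 V
        maps to 32 Nm."""
        gain = 0.5 / ADC_QUANTUM_V
        assert gain == pytest.approx(32.0)
        assert ad.voltage_to_torque(1.0, Calibration(gain)) == pytest.approx(32.0)

    @given(g=st.floats(min_value=0.1, max_value=100),
           amp=st.floats(min_value=0, max_value=2))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_linearity(self, g, amp):
        cal = Calibration(g)
        assert ad.voltage_to_torque(2 * amp, cal) == pytest.approx(
            2 * ad.voltage_to_torque(amp, cal), rel=1e-12)

    def test_missing_calibration(self):
        with pytest.raises(MissingCalibration):
            ad.voltage_to_torque(1.0, None)
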