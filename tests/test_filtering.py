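"""ENF-rejecting Chebyshev type II design: stopband notch placement,
cutoff, stability and zero-phase application."""

import numpy as np
import pytest
from scipy import signal as sps

import ankledyn as ad
from ankledyn.errors import FsMismatch, NarrowBandWarning
from ankledyn.filtering import DB_FLOOR, FilterCoefficients, FilterSpec


class TestDesign:
    def test_enf_band_attenuation(self, default_coeffs):
        """Minimal attenuation across 49.5-50.5 Hz is at least 78 dB
        (frozen computed value 78.683 dB, cross-checked against R
        signal::cheby2)."""
        att = ad.min_attenuation_db(default_coeffs, 49.5, 50.5)
        assert att >= 78.0
        assert att == pytest.approx(78.683, abs=0.01)

    def test_dc_gain_is_unity(self, default_coeffs):
        """Type II passband is flat with unit gain at DC."""
        db0 = ad.frequency_response(default_coeffs, np.array([0.0]))[0]
        assert db0 == pytest.approx(0.0, abs=1e-4)

    def test_second_notch_sits_on_enf(self, default_coeffs):
        """The design cut frequency is chosen so the second notch lands
        exactly on the 50 Hz network frequency."""
        notches = ad.notch_frequencies(default_coeffs)
        assert notches[1] == pytest.approx(50.0, abs=1e-3)

    def test_lowest_notch_from_root_oracle(self, default_coeffs):
        """Lowest numerator zero: root-finding on b must agree with a
        dense scan of the magnitude response (two independent routes)."""
        notch_roots = ad.notch_frequencies(default_coeffs)[0]
        grid = np.linspace(20, 45, 250001)
        db = ad.frequency_response(default_coeffs, grid)
        notch_scan = grid[np.argmin(db)]
        assert notch_roots == pytest.approx(notch_scan, abs=1e-3)
        assert notch_roots == pytest.approx(30.906, abs=1e-3)

    def test_cutoff_3db(self, default_coeffs):
        """Actual -3 dB cut-off is near 15 Hz and satisfies the >=12 Hz
        bandwidth condition for a 1 s shortest pedal action."""
        f3 = ad.cutoff_3db_hz(default_coeffs)
        assert f3 == pytest.approx(15.04, abs=0.05)
        assert f3 >= 12.0

    def test_poles_inside_unit_circle(self, default_coeffs):
        """Root-modulus oracle on the denominator polynomial."""
        assert np.max(np.abs(np.roots(default_coeffs.a))) < 1
        assert ad.check_stability(default_coeffs)

    @pytest.mark.parametrize("fs", [4000.0, 10000.0, 50000.0])
    def test_stable_across_sampling_frequencies(self, fs):
        coeffs = ad.design_cheby2(FilterSpec(fs_hz=fs))
        assert np.max(np.abs(np.roots(coeffs.a))) < 1

    def test_narrowband_warning_below_4khz(self):
        with pytest.warns(NarrowBandWarning):
            ad.design_cheby2(FilterSpec(fs_hz=3000.0))

    def test_sos_matches_ba_in_passband(self, default_coeffs):
        """The second-order-section realization used for filtering must
        match the printed b/a form over the passband (to 1e-4 dB; the b/a
        expansion itself carries ~1e-5 dB of coefficient rounding)."""
        grid = np.linspace(0.1, 14.0, 500)
        _, h = sps.freqz(default_coeffs.b, default_coeffs.a, worN=grid,
                         fs=default_coeffs.spec.fs_hz)
        _, h_sos = sps.sosfreqz(default_coeffs.sos, worN=grid,
                                fs=default_coeffs.spec.fs_hz)
        np.testing.assert_allclose(20 * np.log10(np.abs(h)),
                                   20 * np.log10(np.abs(h_sos)), atol=1e-4)

    def test_stopband_floor(self, default_coeffs):
        """Beyond the stopband edge the response never rises above
        -50 dB."""
        grid = np.linspace(default_coeffs.spec.design_cut_hz,
                           default_coeffs.spec.fs_hz / 2 - 1e-3, 20000)
        assert np.max(ad.frequency_response(default_coeffs, grid)) <= -50 + 1e-6


class TestFrequencyResponse:
    def test_identity_filter_is_flat(self, default_coeffs):
        ident = FilterCoefficients(b=np.array([1.0]), a=np.array([1.0]),
                                   spec=default_coeffs.spec)
        db = ad.frequency_response(ident, np.linspace(0, 3000, 100))
        np.testing.assert_allclose(db, 0.0, atol=1e-12)

    def test_exact_zeros_clipped_to_floor(self, default_coeffs):
        notch = ad.notch_frequencies(default_coeffs)[1]  # exactly 50 Hz
        db = ad.frequency_response(default_coeffs, np.array([notch]))[0]
        assert db >= DB_FLOOR


class TestApplyLowpass:
    def test_zero_in_zero_out(self, default_coeffs):
        rec = ad.Recording(times=np.arange(1000) / 6103.5469,
                           voltages=np.zeros(1000), fs=6103.5469, n_buffers=1)
        out = ad.apply_lowpass(rec, default_coeffs)
        np.testing.assert_allclose(out.voltages, 0.0)

    def test_step_settles_to_unity_dc_gain(self, default_coeffs):
        """Steady-state oracle via direct difference-equation recursion:
        a causal pass over a long step must settle at the step value."""
        n = 60000
        x = np.ones(n)
        b, a = default_coeffs.b, default_coeffs.a
        y = np.zeros(n)
        for i in range(n):  # direct recursion, independent of scipy filtering
            acc = 0.0
            for j in range(len(b)):
                if i - j >= 0:
                    acc += b[j] * x[i - j]
            for j in range(1, len(a)):
                if i - j >= 0:
                    acc -= a[j] * y[i - j]
            y[i] = acc
        assert y[-1] == pytest.approx(1.0, abs=1e-5)
        rec = ad.Recording(times=np.arange(n) / 6103.5469, voltages=x,
                           fs=6103.5469, n_buffers=1)
        out = ad.apply_lowpass(rec, default_coeffs, zero_phase=False)
        # sos realization settles at its own (cleaner) DC gain; the two
        # realizations agree to the b/a coefficient-rounding level
        assert out.voltages[-1] == pytest.approx(y[-1], abs=1e-5)

    def test_hum_attenuated(self, default_coeffs):
        """A 50 Hz hum component must come out at least 78 dB down."""
        fs = 6103.5469
        t = np.arange(int(fs * 8)) / fs
        hum = 0.05 * np.sin(2 * np.pi * 50 * t)
        rec = ad.Recording(times=t, voltages=hum, fs=fs, n_buffers=8)
        out = ad.apply_lowpass(rec, default_coeffs, zero_phase=False)
        core = out.voltages[len(out.voltages) // 2:]  # past the transient
        ratio = np.max(np.abs(core)) / 0.05
        assert 20 * np.log10(ratio) <= -78

    def test_fs_mismatch_raises(self, default_coeffs):
        rec = ad.Recording(times=np.arange(100) / 1000.0,
                           voltages=np.zeros(100), fs=1000.0, n_buffers=1)
        with pytest.raises(FsMismatch):
            ad.apply_lowpass(rec, default_coeffs)

    def test_zero_phase_preserves_peak_location(self, default_coeffs):
        """Forward-backward filtering must not delay the global extremum
        of a noise-free plateau signal."""
        p = ad.SynthParams(rng_seed=0, noise_sd_v=0.0, hum_amp_v=0.0,
                           quantize=False)
        rec, truth = ad.generate_measurement(p)
        out = ad.apply_lowpass(rec, default_coeffs)
        t_filt = out.times[np.argmax(out.voltages)]
        # the plateau top is flat: the extremum must stay on the hold
        # interval of the largest plateau, not be delayed off it
        k = int(np.argmax(truth.plateau_amplitudes_v))
        onset, end = truth.segments[k]
        assert onset <= t_filt <= end


class TestPeriodogram:
    def test_pure_tone_peaks_at_its_bin(self):
        """DFT oracle: the periodogram of a pure 50 Hz tone must peak in
        the same bin as a direct |FFT|^2 computation."""
        fs = 6103.5469
        t = np.arange(int(fs * 4)) / fs
        v = np.sin(2 * np.pi * 50 * t)
        rec = ad.Recording(times=t, voltages=v, fs=fs, n_buffers=4)
        spec = ad.periodogram_psd(rec)
        f_peak = spec.freqs[np.argmax(spec.power)]
        mags = np.abs(np.fft.rfft(v)) ** 2
        f_oracle = np.fft.rfftfreq(len(v), 1 / fs)[np.argmax(mags)]
        assert f_peak == pytest.approx(f_oracle, abs=1e-9)
        assert f_peak == pytest.approx(50.0, abs=0.5)

    def test_zero_signal_zero_power(self):
        rec = ad.Recording(times=np.arange(1000) / 6103.5469,
                           voltages=np.zeros(1000), fs=6103.5469, n_buffers=1)
        spec = ad.periodogram_psd(rec)
        assert np.all(spec.power == 0)

    def test_pedal_signal_energy_below_10hz(self, clean_measurement):
        """The press signal's dominant power must lie under 10 Hz."""
        rec, _ = clean_measurement
        spec = ad.periodogram_psd(rec)
        low = spec.freqs < 10
        assert spec.power[low].sum() > 0.95 * spec.power.sum()
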