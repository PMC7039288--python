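"""Spectral heart-rate estimation and the AC/DC -> R -> SpO2 chain."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vitalband import (
    UndefinedRatioError,
    estimate_heart_rate,
    extract_ac_dc,
    modulation_ratio,
    single_sided_spectrum,
    spo2_from_ratio,
    windowed_heart_rate,
)
from vitalband.synthetic import PPGSpec, generate_ppg
from vitalband.types import ACDCComponents, DualPPG, Spectrum


def _sinusoid_ppg(freq_hz, amp, offset, duration_s=10.0, fs_hz=50.0):
    t = np.arange(0.0, duration_s, 1.0 / fs_hz)
    s = offset + amp * np.sin(2 * np.pi * freq_hz * t)
    return DualPPG(t=t, red=s, ir=s, fs_hz=fs_hz)


class TestSingleSidedSpectrum:
    def test_pure_sinusoid_peak_at_1342_mhz(self):
        t = np.arange(0.0, 40.0, 1.0 / 50.0)
        x = np.sin(2 * np.pi * 1.342 * t)
        spec = single_sided_spectrum(x, 50.0, 0.002)
        assert spec.freq_hz[np.argmax(spec.amplitude)] == pytest.approx(
            1.342, abs=spec.resolution_hz
        )

    def test_constant_signal_yields_zero_spectrum(self):
        spec = single_sided_spectrum(np.full(100, 7.3), 50.0, 0.01)
        assert np.allclose(spec.amplitude, 0.0)

    def test_matches_direct_dft_oracle(self):
        # small series: compare against an explicit DFT evaluated on the
        # padded grid; the weaker 2 Hz line must stay a local (not global) max
        fs, n = 20.0, 100
        t = np.arange(n) / fs
        x = 1.0 * np.sin(2 * np.pi * 1.0 * t) + 0.4 * np.sin(2 * np.pi * 2.0 * t)
        spec = single_sided_spectrum(x, fs, 0.05)
        xm = x - x.mean()
        # explicit sum_n x_n exp(-2i pi f t_n), evaluated on the same grid
        grid = np.exp(-2j * np.pi * np.outer(spec.freq_hz, t))
        oracle = np.abs(grid @ xm) * 2.0 / n
        assert np.allclose(spec.amplitude[1:-1], oracle[1:-1], atol=1e-9)
        peak_1hz = spec.amplitude[np.abs(spec.freq_hz - 1.0) < 0.01].max()
        peak_2hz = spec.amplitude[np.abs(spec.freq_hz - 2.0) < 0.01].max()
        assert peak_1hz == spec.amplitude.max()
        assert peak_2hz > 0.3  # weaker line still resolved

    def test_resolution_at_most_requested(self):
        spec = single_sided_spectrum(np.random.default_rng(0).normal(size=64),
                                     50.0, 0.002)
        assert spec.resolution_hz <= 0.002

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            single_sided_spectrum(np.array([1.0]), 50.0, 0.01)


class TestEstimateHeartRate:
    def _spectrum_with_peak(self, peak_hz, res=0.002):
        freq = np.arange(0.0, 5.0 + res, res)
        amp = np.zeros_like(freq)
        amp[np.argmin(np.abs(freq - peak_hz))] = 1.0
        return Spectrum(freq_hz=freq, amplitude=amp, resolution_hz=res)

    @pytest.mark.parametrize(
        "peak_hz,bpm", [(1.342, 80.52), (1.0, 60.0), (0.5, 30.0), (3.5, 210.0)]
    )
    def test_bpm_is_sixty_times_peak_frequency(self, peak_hz, bpm):
        est = estimate_heart_rate(self._spectrum_with_peak(peak_hz))
        assert est.bpm == pytest.approx(bpm)

    def test_amplitude_tie_breaks_to_lower_frequency(self):
        res = 0.01
        freq = np.arange(0.0, 5.0, res)
        amp = np.zeros_like(freq)
        amp[np.argmin(np.abs(freq - 1.0))] = 1.0
        amp[np.argmin(np.abs(freq - 2.0))] = 1.0
        est = estimate_heart_rate(Spectrum(freq, amp, res))
        assert est.bpm == pytest.approx(60.0)

    def test_band_outside_grid_rejected(self):
        spec = self._spectrum_with_peak(1.0)
        with pytest.raises(ValueError):
            estimate_heart_rate(spec, band_hz=(0.5, 10.0))

    def test_estimates_stay_in_physiological_range(self, ppg_8052):
        spec = single_sided_spectrum(ppg_8052.ir, ppg_8052.fs_hz, 0.002)
        est = estimate_heart_rate(spec)
        assert 30.0 <= est.bpm <= 210.0


class TestWindowedHeartRate:
    def test_five_minutes_noiseless_recovers_truth(self):
        ppg = generate_ppg(
            PPGSpec(heart_rate_bpm=80.52, duration_s=300.0, noise_sd=0.0)
        )
        result = windowed_heart_rate(ppg, "ir")
        assert len(result.estimates) == 7
        assert result.mean_bpm == pytest.approx(80.52, abs=60 * 0.002)
        for est in result.estimates:
            assert abs(est.peak_freq_hz - 1.342) <= 0.002

    def test_single_window_input(self, ppg_8052):
        result = windowed_heart_rate(ppg_8052, "ir", window_s=40.0)
        assert len(result.estimates) == 1
        assert result.mean_bpm == result.estimates[0].bpm

    def test_trailing_partial_window_dropped(self):
        ppg = generate_ppg(PPGSpec(duration_s=299.0, noise_sd=0.0))
        result = windowed_heart_rate(ppg, "ir")
        assert len(result.estimates) == 7  # floor(299 / 40)

    def test_too_short_input_rejected(self):
        ppg = generate_ppg(PPGSpec(duration_s=20.0))
        with pytest.raises(ValueError):
            windowed_heart_rate(ppg, "ir", window_s=40.0)


class TestExtractACDC:
    def test_constant_signal_flagged(self):
        t = np.arange(0.0, 10.0, 0.02)
        flat = DualPPG(t=t, red=np.full(t.size, 3.0), ir=np.full(t.size, 3.0),
                       fs_hz=50.0)
        (c,) = extract_ac_dc(flat)
        assert c.dc_red == pytest.approx(3.0)
        assert not c.valid

    def test_sinusoid_closed_form(self):
        c = extract_ac_dc(_sinusoid_ppg(1.2, amp=2.0, offset=5.0))[0]
        assert c.dc_ir == pytest.approx(5.0, rel=0.02)
        assert c.ac_ir == pytest.approx(2.0, rel=0.02)

    def test_generator_round_trip_amplitudes(self):
        ppg = generate_ppg(
            PPGSpec(perfusion_ir=0.02, dc_ir=1000.0, duration_s=40.0, noise_sd=0.0)
        )
        comps = extract_ac_dc(ppg)
        assert len(comps) == 4
        for c in comps:
            assert c.dc_ir == pytest.approx(1000.0, rel=0.02)
            assert c.ac_ir == pytest.approx(20.0, rel=0.02)

    def test_interval_count_floors(self, ppg_8052):
        assert len(extract_ac_dc(ppg_8052, interval_s=15.0)) == 2


class TestModulationRatio:
    def test_symmetric_components_give_unity(self):
        assert modulation_ratio(ACDCComponents(20, 1000, 20, 1000)) == 1.0

    def test_half_red_perfusion_gives_half(self):
        assert modulation_ratio(ACDCComponents(10, 1000, 20, 1000)) == 0.5

    @given(
        ac_red=st.floats(0.1, 100), dc_red=st.floats(1, 1e4),
        ac_ir=st.floats(0.1, 100), dc_ir=st.floats(1, 1e4),
    )
    def test_matches_direct_formula(self, ac_red, dc_red, ac_ir, dc_ir):
        c = ACDCComponents(ac_red, dc_red, ac_ir, dc_ir)
        expected = (ac_red / dc_red) / (ac_ir / dc_ir)
        assert modulation_ratio(c) == pytest.approx(expected, rel=1e-12)

    @given(
        scale_red=st.floats(0.01, 100), scale_ir=st.floats(0.01, 100),
    )
    def test_invariant_under_per_wavelength_scaling(self, scale_red, scale_ir):
        base = ACDCComponents(12.0, 800.0, 20.0, 1100.0)
        scaled = ACDCComponents(
            12.0 * scale_red, 800.0 * scale_red,
            20.0 * scale_ir, 1100.0 * scale_ir,
        )
        assert modulation_ratio(scaled) == pytest.approx(
            modulation_ratio(base), rel=1e-9
        )

    def test_zero_ir_ac_signalled(self):
        with pytest.raises(UndefinedRatioError):
            modulation_ratio(ACDCComponents(10, 1000, 0.0, 1000))

    def test_flagged_interval_signalled(self):
        with pytest.raises(UndefinedRatioError):
            modulation_ratio(ACDCComponents(np.nan, 1000, 20, 1000))


class TestSpO2FromRatio:
    @pytest.mark.parametrize("ratio,expected", [(1.0, 85.0), (0.5, 97.5)])
    def test_operating_points(self, ratio, expected):
        assert spo2_from_ratio(ratio).spo2 == pytest.approx(expected)

    def test_zero_ratio_clamped_with_raw_kept(self):
        est = spo2_from_ratio(0.0)
        assert est.spo2_unclamped == pytest.approx(110.0)
        assert est.spo2 == pytest.approx(100.0)

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            spo2_from_ratio(-0.1)

    @given(st.floats(0.0, 4.0), st.floats(0.0, 4.0))
    def test_strictly_decreasing_in_ratio(self, r1, r2):
        if r1 == r2:
            return
        lo, hi = sorted((r1, r2))
        assert spo2_from_ratio(lo).spo2_unclamped > spo2_from_ratio(hi).spo2_unclamped


class TestEndToEndSpO2:
    def test_equal_perfusion_recovers_unity_ratio(self):
        ppg = generate_ppg(
            PPGSpec(perfusion_red=0.02, perfusion_ir=0.02, noise_sd=0.0)
        )
        ratios = [modulation_ratio(c) for c in extract_ac_dc(ppg) if c.valid]
        assert np.mean(ratios) == pytest.approx(1.0, abs=1e-6)
        assert spo2_from_ratio(float(np.mean(ratios))).spo2 == pytest.approx(85.0)

    def test_half_perfusion_recovers_commercial_point(self):
        ppg = generate_ppg(
            PPGSpec(perfusion_red=0.01, perfusion_ir=0.02, noise_sd=0.0)
        )
        ratios = [modulation_ratio(c) for c in extract_ac_dc(ppg) if c.valid]
        assert spo2_from_ratio(float(np.mean(ratios))).spo2 == pytest.approx(
            97.5, abs=0.05
        )
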