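"""Feature extractors: definitions, oracles, and scale behaviour."""

import math

import numpy as np
import pytest

from cogload.features import (
    BlinkEvent,
    RESP_BANDS,
    assemble_feature_vector,
    detect_blinks,
    eeg_feature_names,
    extract_eeg_features,
    extract_eog_features,
    extract_gsr_features,
    extract_hrv_features,
    extract_resp_features,
    extract_vehicular_features,
    feature_names,
    steering_entropy,
    steering_reversal_rate,
    welch_band_power,
)
from cogload.preprocessing import IBISeries, ScenarioWindow
from cogload.synthetic import blink_waveform, scr_waveform


def _sine(freq, fs, dur, amp=1.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(int(dur * fs)) / fs)


# --------------------------------------------------------------------------
# spectral


class TestWelchBandPower:
    def test_zero_signal_has_zero_power_everywhere(self):
        for band in [(0.5, 4), (8, 12), (31, 50)]:
            assert welch_band_power(np.zeros(256 * 50), 256.0, band) == 0.0

    def test_sinusoid_power_lands_in_its_band(self):
        x = _sine(10.0, 256.0, 50.0)
        alpha = welch_band_power(x, 256.0, (8.0, 12.0))
        beta = welch_band_power(x, 256.0, (12.0, 30.0))
        assert alpha > 50 * beta
        # independent oracle: raw periodogram of the same signal
        f = np.fft.rfftfreq(x.size, 1 / 256.0)
        p = np.abs(np.fft.rfft(x)) ** 2 / (256.0 * x.size)
        mask = (f >= 8) & (f < 12)
        assert p[mask].sum() > 50 * p[(f >= 12) & (f < 30)].sum()

    def test_white_noise_band_power_proportional_to_bandwidth(self):
        """Flat spectrum: power([12,30)) / power([8,12)) -> 18/4."""
        ratios = []
        for seed in range(50):
            x = np.random.default_rng(seed).standard_normal(256 * 50)
            ratios.append(
                welch_band_power(x, 256.0, (12.0, 30.0))
                / welch_band_power(x, 256.0, (8.0, 12.0))
            )
        assert np.mean(ratios) == pytest.approx(18 / 4, rel=0.15)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            welch_band_power(np.zeros(3200), 32.0, (10.0, 20.0))

    def test_amplitude_scaling_is_quadratic(self):
        x = _sine(10.0, 256.0, 50.0)
        p1 = welch_band_power(x, 256.0, (8.0, 12.0))
        p3 = welch_band_power(3 * x, 256.0, (8.0, 12.0))
        assert p3 == pytest.approx(9 * p1, rel=1e-9)


class TestEegFeatures:
    def test_exactly_270_values_with_consistent_ratios(self, small_windows):
        out = extract_eeg_features(small_windows[0])
        assert len(out) == 270
        for ch in ("Fp1", "Cz", "POz"):
            th = out[f"EEG_{ch}_theta"]
            al = out[f"EEG_{ch}_alpha"]
            be = out[f"EEG_{ch}_beta"]
            assert out[f"EEG_{ch}_ratio_t_b"] == pytest.approx(th / be, rel=1e-9)
            assert out[f"EEG_{ch}_ratio_a_b"] == pytest.approx(al / be, rel=1e-9)
            assert out[f"EEG_{ch}_ratio_ta_b"] == pytest.approx((th + al) / be, rel=1e-9)
            assert out[f"EEG_{ch}_ratio_ta_ab"] == pytest.approx(
                (th + al) / (al + be), rel=1e-9
            )

    def test_missing_channel_is_an_error(self, small_windows):
        w = small_windows[0]
        broken = ScenarioWindow(
            start_s=w.start_s,
            scenario=w.scenario,
            task=w.task,
            channels={k: v for k, v in w.channels.items() if "EEG" not in k},
            rates=w.rates,
        )
        with pytest.raises(ValueError, match="EEG"):
            extract_eeg_features(broken)

    def test_alpha_boosted_channel_raises_alpha_beta_ratio(self):
        """Injected alpha component is recovered in >= 19/20 seeds."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            base = rng.standard_normal(256 * 50)
            boosted = base + _sine(10.0, 256.0, 50.0, amp=0.5)
            w = {"fs": 256.0}
            r_base = welch_band_power(base, 256.0, (8, 12)) / welch_band_power(
                base, 256.0, (12, 30)
            )
            r_boost = welch_band_power(boosted, 256.0, (8, 12)) / welch_band_power(
                boosted, 256.0, (12, 30)
            )
            hits += r_boost > r_base
        assert hits >= 19

    def test_scaling_leaves_ratios_unchanged(self, small_windows):
        w = small_windows[0]
        scaled = ScenarioWindow(
            start_s=w.start_s,
            scenario=w.scenario,
            task=w.task,
            channels={
                k: (3.0 * v if k.startswith("EEG") else v)
                for k, v in w.channels.items()
            },
            rates=w.rates,
        )
        a = extract_eeg_features(w)
        b = extract_eeg_features(scaled)
        assert b["EEG_Cz_alpha"] == pytest.approx(9 * a["EEG_Cz_alpha"], rel=1e-9)
        assert b["EEG_Cz_ratio_a_b"] == pytest.approx(a["EEG_Cz_ratio_a_b"], rel=1e-9)


# --------------------------------------------------------------------------
# blinks / EOG


class TestBlinks:
    def test_flat_signal_gives_no_events(self):
        assert detect_blinks(np.zeros(256 * 10), 256.0) == []

    def test_injected_templates_recovered_with_timing(self):
        fs = 256.0
        x = np.random.default_rng(0).standard_normal(int(fs * 50)) * 10.0
        tmpl = blink_waveform(fs, amplitude=300.0)
        apex = int(np.argmax(tmpl))
        truth = np.arange(2.0, 50.0, 4.0)  # 12 blinks
        for bt in truth:
            i = int(bt * fs) - apex
            x[i : i + tmpl.size] += tmpl
        events = detect_blinks(x, fs)
        assert len(events) == 12
        errs = [min(abs(e.peak_s - truth)) for e in events]
        assert max(errs) < 0.020

    def test_subthreshold_template_not_detected(self):
        fs = 256.0
        x = np.zeros(int(fs * 20))
        tmpl = blink_waveform(fs, amplitude=50.0)
        x[1000 : 1000 + tmpl.size] += tmpl
        assert detect_blinks(x, fs, threshold=100.0) == []

    def test_events_ordered_and_invariants_hold(self, small_windows):
        w = small_windows[0]
        events = detect_blinks(w.channels["EOG V"], w.rates["EOG V"])
        for e in events:
            assert e.start_s < e.peak_s < e.end_s
            assert e.amplitude > 0
        peaks = [e.peak_s for e in events]
        assert peaks == sorted(peaks)


class TestEogSummary:
    def _blink(self, start, dur, peak_frac=0.4):
        return BlinkEvent(
            start_s=start,
            peak_s=start + peak_frac * dur,
            end_s=start + dur,
            amplitude=100.0,
            closure_speed=1000.0,
            peak_closing_velocity=2000.0,
            reopen_delay_s=(1 - peak_frac) * dur,
            duration80_s=0.1,
        )

    def test_rate_is_per_minute(self):
        blinks = [self._blink(1.0 + 4 * i, 0.3) for i in range(12)]
        out = extract_eog_features(blinks, 50.0)
        assert out["EOG_blink_rate"] == pytest.approx(14.4)
        assert out["EOG_blink_count"] == 12

    def test_no_blinks_gives_zero_counts_and_flagged_means(self):
        out = extract_eog_features([], 50.0)
        assert out["EOG_blink_count"] == 0
        assert out["EOG_perclos"] == 0.0
        assert math.isnan(out["EOG_blink_duration"])

    def test_mean_duration_over_events(self):
        blinks = [self._blink(1.0, 0.2), self._blink(5.0, 0.4)]
        out = extract_eog_features(blinks, 50.0)
        assert out["EOG_blink_duration"] == pytest.approx(0.3)


# --------------------------------------------------------------------------
# HRV


class TestHrvFeatures:
    def _series(self, intervals_ms):
        t = np.concatenate([[0.0], np.cumsum(np.asarray(intervals_ms) / 1000)])
        return IBISeries(beat_times=t, intervals=np.asarray(intervals_ms, float))

    def test_constant_ibi(self):
        out = extract_hrv_features(self._series(np.full(40, 800.0)))
        assert out["ECG_meanHR"] == pytest.approx(75.0)
        assert out["ECG_SDNN"] == 0.0
        assert out["ECG_RMSSD"] == 0.0
        assert out["ECG_NN50"] == 0 and out["ECG_pNN50"] == 0.0

    def test_nn50_hand_count(self):
        # successive differences 60, 40, 55, 10 ms -> two exceed 50 ms
        ibi = self._series([800, 860, 820, 875, 885])
        out = extract_hrv_features(ibi)
        assert out["ECG_NN50"] == 2
        assert out["ECG_pNN50"] == pytest.approx(50.0)

    def test_short_series_spectral_members_flagged(self):
        out = extract_hrv_features(self._series(np.full(10, 800.0)))
        assert math.isnan(out["ECG_LF"]) and math.isnan(out["ECG_SampEn"])
        assert out["ECG_meanHR"] == pytest.approx(75.0)

    def test_lf_hf_ratio_consistent_with_members(self, small_windows):
        from cogload.features import hrv_from_window

        out = extract_hrv_features(hrv_from_window(small_windows[0]))
        assert out["ECG_LF_HF"] == pytest.approx(out["ECG_LF"] / out["ECG_HF"], rel=1e-9)
        assert out["ECG_LF"] >= 0 and out["ECG_HF"] >= 0
        assert 0 <= out["ECG_pNN50"] <= 100


# --------------------------------------------------------------------------
# GSR


class TestGsrFeatures:
    def test_flat_signal(self):
        out = extract_gsr_features(np.full(32 * 50, 2.0), 32.0)
        assert out["GSR_n_peaks"] == 0
        assert out["GSR_mean"] == pytest.approx(2.0)
        assert out["GSR_sd"] == 0.0

    def test_injected_scr_bumps_recovered(self):
        fs = 32.0
        x = np.zeros(int(fs * 50)) + 2.0
        for t0 in (5.0, 14.0, 23.0, 32.0, 41.0):
            w = scr_waveform(fs, amplitude=1.0, rise_s=1.5)
            i = int(t0 * fs)
            x[i : i + w.size] += w[: x.size - i]
        out = extract_gsr_features(x, fs)
        assert out["GSR_n_peaks"] == 5
        assert out["GSR_peak_amplitude"] == pytest.approx(1.0, rel=0.10)
        assert out["GSR_rise_time"] == pytest.approx(1.5, abs=0.2)

    def test_quartiles_use_linear_interpolation(self):
        x = np.array([1, 2, 3, 4, 5, 6, 7, 8], dtype=float)
        out = extract_gsr_features(np.tile(x, 20), 2.0)
        assert out["GSR_q1"] == pytest.approx(2.75)
        assert out["GSR_q3"] == pytest.approx(6.25)


# --------------------------------------------------------------------------
# respiration


class TestRespFeatures:
    def test_constant_signal(self):
        out = extract_resp_features(np.full(32 * 50, 1.0), 32.0)
        assert out["RR_sd"] == 0.0
        assert all(out[f"RR_power_{lo:.1f}_{hi:.1f}"] == 0.0 for lo, hi in RESP_BANDS)

    def test_quarter_hz_sinusoid_dominates_its_band(self):
        x = _sine(0.25, 32.0, 50.0)
        out = extract_resp_features(x, 32.0)
        target = out["RR_power_0.2_0.3"]
        others = [
            out[f"RR_power_{lo:.1f}_{hi:.1f}"]
            for lo, hi in RESP_BANDS
            if (lo, hi) != (0.2, 0.3)
        ]
        assert all(target > 10 * p for p in others)

    def test_kurtosis_uses_non_excess_convention(self):
        vals = []
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal(20000)
            vals.append(extract_resp_features(x, 32.0)["RR_kurtosis"])
        assert 2.7 < np.mean(vals) < 3.3


# --------------------------------------------------------------------------
# vehicular


def _veh_window(swa=None, latpos=None, landep=None, n=500, fs=10.0):
    zeros = np.zeros(n)
    chans = {
        "VEH latpos_m": zeros if latpos is None else latpos,
        "VEH latspeed_mps": zeros.copy(),
        "VEH swa_deg": zeros if swa is None else swa,
        "VEH yaw_deg": zeros.copy(),
        "VEH yawrate_dps": zeros.copy(),
        "VEH landep_flag": zeros if landep is None else landep,
    }
    rates = {k: fs for k in chans}
    return ScenarioWindow(start_s=0.0, scenario="CR", task="baseline",
                          channels=chans, rates=rates)


class TestVehicularFeatures:
    def test_constant_wheel_on_lane_centre(self):
        out = extract_vehicular_features(_veh_window())
        assert out["VEH_steering_entropy"] == 0.0
        assert out["VEH_swrr"] == 0.0
        assert out["VEH_swa_zero_crossings"] == 0.0
        assert out["VEH_lanex"] == 0.0

    def test_triangle_wave_reversal_count(self):
        # 6 linear segments alternating slope, 5 interior direction
        # changes, each with a 10-degree swing
        seg = np.linspace(0, 10, 100)
        swa = np.concatenate([seg if i % 2 == 0 else seg[::-1] for i in range(6)])
        out = extract_vehicular_features(_veh_window(swa=swa, n=swa.size))
        assert out["VEH_swrr"] == 5.0

    def test_small_swings_below_gap_threshold_not_counted(self):
        seg = np.linspace(0, 0.5, 100)  # swings of 0.5 degrees < 1 degree gap
        swa = np.concatenate([seg if i % 2 == 0 else seg[::-1] for i in range(6)])
        assert steering_reversal_rate(swa) == 0.0

    def test_lanex_is_flag_fraction(self):
        landep = np.zeros(500)
        landep[:10] = 1.0
        out = extract_vehicular_features(_veh_window(landep=landep))
        assert out["VEH_lanex"] == pytest.approx(0.02)

    def test_missing_channel_is_an_error(self, small_windows):
        w = small_windows[0]
        broken = ScenarioWindow(
            start_s=0.0, scenario="CR", task="baseline",
            channels={k: v for k, v in w.channels.items() if k != "VEH swa_deg"},
            rates=w.rates,
        )
        with pytest.raises(ValueError, match="swa"):
            extract_vehicular_features(broken)

    def test_steering_entropy_increases_with_unpredictability(self):
        rng = np.random.default_rng(0)
        smooth = np.cumsum(np.full(500, 0.01))
        jerky = np.cumsum(rng.standard_normal(500))
        assert steering_entropy(jerky) > steering_entropy(smooth)


# --------------------------------------------------------------------------
# assembly


class TestAssembly:
    def test_vector_has_exactly_323_named_features(self, small_windows):
        row = assemble_feature_vector(small_windows[0])
        feats = [n for n in row.index if n not in ("task", "scenario", "participant")]
        assert len(feats) == 323
        assert feats == feature_names()

    def test_block_sizes(self):
        names = feature_names()
        assert len(names) == 323
        assert len(eeg_feature_names()) == 270
        assert sum(n.startswith("EOG_") for n in names) == 9
        assert sum(n.startswith("ECG_") for n in names) == 14
        assert sum(n.startswith("GSR_") for n in names) == 10
        assert sum(n.startswith("RR_") for n in names) == 9
        assert sum(n.startswith("VEH_") for n in names) == 11
        assert len(set(names)) == 323  # globally unique

    def test_identical_windows_give_identical_vectors(self, small_windows):
        a = assemble_feature_vector(small_windows[0])
        b = assemble_feature_vector(small_windows[0])
        assert a.equals(b)

    def test_labels_copied_from_window(self, small_windows):
        w = small_windows[3]
        row = assemble_feature_vector(w)
        assert row["task"] == w.task and row["scenario"] == w.scenario
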