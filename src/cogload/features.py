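"""The 323-feature vector extracted from one 50-s analysis window.

Per modality: 9 spectral features per EEG channel (5 band powers and 4
slow/fast-wave ratios) × 30 channels = 270; 9 blink-waveform features
from the vertical EOG; 14 heart-rate-variability features (time,
frequency and nonlinear domains) from the IBI series; 10 skin-
conductance features; 9 respiration features; 11 vehicular features.
270 + 9 + 14 + 10 + 9 + 11 = 323.

Spectral estimates use Welch's method with a Blackman window and 50%
overlap throughout. Band limits are half-open [lo, hi): delta [0.5, 4),
theta [4, 7), alpha [8, 12), beta [12, 30), gamma [31, 50) Hz. Welch
segment lengths are 5 s for EEG, 10 s for skin conductance, 25 s for
respiration — the 0.1-Hz-wide respiration bands need fine resolution
and low Blackman main-lobe leakage, and 32 s on the 4-Hz-resampled IBI series.

Per-event quantities (blink duration, SCR rise time, ...) are
summarized over the window by their mean; windows with no events carry
NaN for those members (later imputed with the training-column median
by the modelling stage) and zero for counts and rates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats
from scipy.interpolate import CubicSpline

from . import entropy as ent
from .preprocessing import IBISeries, ScenarioWindow, clean_ibi, detect_r_peaks, ibi_from_beats

__all__ = [
    "EEG_BANDS",
    "RESP_BANDS",
    "BlinkEvent",
    "welch_band_power",
    "extract_eeg_features",
    "detect_blinks",
    "extract_eog_features",
    "extract_hrv_features",
    "extract_gsr_features",
    "extract_resp_features",
    "extract_vehicular_features",
    "assemble_feature_vector",
    "extract_feature_table",
    "feature_names",
    "eeg_feature_names",
]

EEG_BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (31.0, 50.0),
}
EEG_RATIOS = ("ratio_ta_b", "ratio_a_b", "ratio_ta_ab", "ratio_t_b")

RESP_BANDS = [(0.0, 0.1), (0.1, 0.2), (0.2, 0.3), (0.3, 0.4), (0.4, 0.7), (0.7, 1.0)]

EOG_FEATURES = (
    "start_pos", "blink_duration", "closure_speed", "pcv",
    "reopen_delay", "duration80", "perclos", "blink_rate", "blink_count",
)
ECG_FEATURES = (
    "meanHR", "sdHR", "SDNN", "RMSSD", "NN50", "pNN50",
    "LF", "HF", "total_power", "LF_HF",
    "dfaAlpha", "SampEn", "ApEn", "PeEn",
)
GSR_FEATURES = (
    "n_peaks", "peak_amplitude", "rise_time", "peak_index",
    "mean", "sd", "q1", "q3", "slope", "power_sub1hz",
)
RR_FEATURE_NAMES = (
    "mean", "sd", "kurtosis",
    "power_0.0_0.1", "power_0.1_0.2", "power_0.2_0.3",
    "power_0.3_0.4", "power_0.4_0.7", "power_0.7_1.0",
)
VEH_FEATURES = (
    "sd_latpos", "mse_latpos", "sd_swa", "steering_entropy", "swrr",
    "swa_highfreq", "swa_zero_crossings", "lanex",
    "sd_latspeed", "sd_yaw", "sd_yawrate",
)


def eeg_feature_names(channels: list[str] | None = None) -> list[str]:
    from .synthetic import EEG_CHANNELS

    chans = channels if channels is not None else EEG_CHANNELS
    names = []
    for ch in chans:
        for band in EEG_BANDS:
            names.append(f"EEG_{ch}_{band}")
        for ratio in EEG_RATIOS:
            names.append(f"EEG_{ch}_{ratio}")
    return names


def feature_names() -> list[str]:
    """The canonical ordered 323 feature names."""
    names = eeg_feature_names()
    names += [f"EOG_{n}" for n in EOG_FEATURES]
    names += [f"ECG_{n}" for n in ECG_FEATURES]
    names += [f"GSR_{n}" for n in GSR_FEATURES]
    names += [f"RR_{n}" for n in RR_FEATURE_NAMES]
    names += [f"VEH_{n}" for n in VEH_FEATURES]
    return names


# --------------------------------------------------------------------------
# spectral workhorse


def _welch(x: np.ndarray, fs: float, seg_s: float = 5.0):
    x = np.asarray(x, dtype=float)
    nperseg = min(x.size, int(round(seg_s * fs)))
    if nperseg < 8:
        raise ValueError("signal too short for Welch estimation")
    return sps.welch(
        x, fs=fs, window="blackman", nperseg=nperseg, noverlap=nperseg // 2
    )


def welch_band_power(x, fs: float, band: tuple[float, float], seg_s: float = 5.0) -> float:
    """PSD integrated over the half-open band [lo, hi) Hz.

    Welch with a Blackman window and 50% overlap; ``seg_s`` sets the
    segment length (hence frequency resolution 1/seg_s).
    """
    lo, hi = band
    if hi > fs / 2 + 1e-9:
        raise ValueError(f"band {band} extends above Nyquist ({fs / 2} Hz)")
    if lo >= hi:
        raise ValueError(f"band must satisfy lo < hi, got {band}")
    f, psd = _welch(x, fs, seg_s)
    df = f[1] - f[0]
    mask = (f >= lo) & (f < hi)
    return float(np.sum(psd[mask]) * df)


# --------------------------------------------------------------------------
# EEG


def extract_eeg_features(window: ScenarioWindow, seg_s: float = 5.0) -> dict[str, float]:
    """Five band powers and four slow/fast ratios per EEG channel."""
    labels = [c for c in window.channels if c.startswith("EEG ")]
    if not labels:
        raise ValueError("no EEG channels in window")
    out: dict[str, float] = {}
    for label in labels:
        ch = label.split(" ", 1)[1]
        fs = window.rates[label]
        f, psd = _welch(window.channels[label], fs, seg_s)
        df = f[1] - f[0]
        powers = {}
        for band, (lo, hi) in EEG_BANDS.items():
            powers[band] = float(np.sum(psd[(f >= lo) & (f < hi)]) * df)
            out[f"EEG_{ch}_{band}"] = powers[band]
        th, al, be = powers["theta"], powers["alpha"], powers["beta"]
        out[f"EEG_{ch}_ratio_ta_b"] = (th + al) / be if be > 0 else math.nan
        out[f"EEG_{ch}_ratio_a_b"] = al / be if be > 0 else math.nan
        out[f"EEG_{ch}_ratio_ta_ab"] = (th + al) / (al + be) if al + be > 0 else math.nan
        out[f"EEG_{ch}_ratio_t_b"] = th / be if be > 0 else math.nan
    return out


# --------------------------------------------------------------------------
# EOG / blinks


@dataclass
class BlinkEvent:
    """One detected lid closure on the vertical EOG."""

    start_s: float
    peak_s: float
    end_s: float
    amplitude: float
    closure_speed: float  # amplitude / closing time
    peak_closing_velocity: float
    reopen_delay_s: float  # peak to end
    duration80_s: float  # time spent above 80% of the blink amplitude

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def detect_blinks(
    veog, fs: float, threshold: float | None = None, min_separation_s: float = 0.3
) -> list[BlinkEvent]:
    """Derivative-and-threshold blink detector on the vertical EOG.

    The signal is low-pass smoothed (10 Hz), the amplitude threshold
    defaults to median + 4 robust SDs (MAD-based); candidate peaks above
    threshold are walked outward along the velocity profile to find
    blink start and end. Events whose peak fails the threshold are not
    reported. Returns time-ordered, non-overlapping events.
    """
    if fs < 50:
        raise ValueError(f"fs must be >= 50 Hz for blink detection, got {fs}")
    x = np.asarray(veog, dtype=float)
    if x.size < int(fs):
        return []
    if np.ptp(x) == 0:
        return []
    sos = sps.butter(4, min(10.0, 0.45 * fs), btype="lowpass", fs=fs, output="sos")
    sm = sps.sosfiltfilt(sos, x)
    med = float(np.median(sm))
    if threshold is None:
        mad = float(np.median(np.abs(sm - med))) * 1.4826
        threshold = 4.0 * max(mad, 1e-12)
    peaks, _ = sps.find_peaks(
        sm - med, height=threshold, distance=max(1, int(min_separation_s * fs))
    )
    vel = np.gradient(sm) * fs
    events: list[BlinkEvent] = []
    last_end = -1
    for p in peaks:
        amp = sm[p] - med
        lvl10 = med + 0.1 * amp
        i = p
        while i > last_end + 1 and sm[i - 1] > lvl10:
            i -= 1
        j = p
        while j < sm.size - 1 and sm[j + 1] > lvl10:
            j += 1
        if j <= i or i <= last_end:
            continue
        if (i == 0 and sm[0] > lvl10) or (j == sm.size - 1 and sm[-1] > lvl10):
            continue  # template truncated at the window edge
        closing_t = (p - i) / fs
        lvl80 = med + 0.8 * amp
        above80 = np.count_nonzero(sm[i : j + 1] > lvl80) / fs
        events.append(
            BlinkEvent(
                start_s=i / fs,
                peak_s=p / fs,
                end_s=j / fs,
                amplitude=float(amp),
                closure_speed=float(amp / closing_t) if closing_t > 0 else math.nan,
                peak_closing_velocity=float(np.max(vel[i : p + 1])) if p > i else math.nan,
                reopen_delay_s=(j - p) / fs,
                duration80_s=float(above80),
            )
        )
        last_end = j
    return events


def extract_eog_features(
    blinks: list[BlinkEvent], window_duration: float
) -> dict[str, float]:
    """Window summary of blink events (means over events; rate per min)."""
    if window_duration <= 0:
        raise ValueError("window_duration must be > 0")
    n = len(blinks)
    out = {
        "EOG_blink_count": float(n),
        "EOG_blink_rate": n * 60.0 / window_duration,
        "EOG_perclos": (
            sum(b.duration80_s for b in blinks) / window_duration if n else 0.0
        ),
    }
    if n:
        out["EOG_start_pos"] = float(np.mean([b.start_s for b in blinks]))
        out["EOG_blink_duration"] = float(np.mean([b.duration_s for b in blinks]))
        out["EOG_closure_speed"] = float(np.nanmean([b.closure_speed for b in blinks]))
        out["EOG_pcv"] = float(np.nanmean([b.peak_closing_velocity for b in blinks]))
        out["EOG_reopen_delay"] = float(np.mean([b.reopen_delay_s for b in blinks]))
        out["EOG_duration80"] = float(np.mean([b.duration80_s for b in blinks]))
    else:
        for name in ("start_pos", "blink_duration", "closure_speed", "pcv",
                     "reopen_delay", "duration80"):
            out[f"EOG_{name}"] = math.nan
    return out


# --------------------------------------------------------------------------
# HRV


def extract_hrv_features(
    ibi: IBISeries,
    resample_hz: float = 4.0,
    min_intervals_spectral: int = 30,
) -> dict[str, float]:
    """Time, frequency and nonlinear HRV members from an IBI series.

    Time-domain members need >= 2 intervals; the spectral and nonlinear
    members need ``min_intervals_spectral`` and are NaN below that. The
    IBI series is resampled to an even ``resample_hz`` grid by cubic
    interpolation before Welch; LF is [0.04, 0.15) Hz, HF [0.15, 0.40)
    Hz, total power the integral over [0, 0.40) Hz.
    """
    x = np.asarray(ibi.intervals, dtype=float)  # ms
    out = {f"ECG_{n}": math.nan for n in ECG_FEATURES}
    if x.size < 2:
        return out
    inst_hr = 60000.0 / x
    out["ECG_meanHR"] = float(np.mean(inst_hr))
    out["ECG_sdHR"] = float(np.std(inst_hr, ddof=1))
    out["ECG_SDNN"] = float(np.std(x, ddof=1))
    d = np.diff(x)
    out["ECG_RMSSD"] = float(np.sqrt(np.mean(d**2))) if d.size else math.nan
    nn50 = int(np.count_nonzero(np.abs(d) > 50.0))
    out["ECG_NN50"] = float(nn50)
    out["ECG_pNN50"] = 100.0 * nn50 / d.size if d.size else math.nan

    if x.size < min_intervals_spectral:
        return out

    # frequency domain on an evenly resampled tachogram
    t = np.asarray(ibi.beat_times, dtype=float)[1 : x.size + 1]
    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    tach = CubicSpline(t, x)(grid)
    tach = tach - np.mean(tach)
    seg = min(tach.size, int(32 * resample_hz))
    f, psd = sps.welch(
        tach, fs=resample_hz, window="blackman", nperseg=seg, noverlap=seg // 2
    )
    df = f[1] - f[0]

    def bp(lo, hi):
        return float(np.sum(psd[(f >= lo) & (f < hi)]) * df)

    lf, hf = bp(0.04, 0.15), bp(0.15, 0.40)
    out["ECG_LF"] = lf
    out["ECG_HF"] = hf
    out["ECG_total_power"] = bp(0.0, 0.40)
    out["ECG_LF_HF"] = lf / hf if hf > 0 else math.nan

    out["ECG_dfaAlpha"] = ent.dfa_alpha(x)
    out["ECG_SampEn"] = ent.sample_entropy(x, m=2)
    out["ECG_ApEn"] = ent.approximate_entropy(x, m=2)
    out["ECG_PeEn"] = ent.permutation_entropy(x, order=3, delay=1)
    return out


def hrv_from_window(window: ScenarioWindow) -> IBISeries:
    """Window ECG slice -> R peaks -> cleaned IBI series."""
    fs = window.rates["ECG"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        beats = detect_r_peaks(window.channels["ECG"], fs)
    ibi = ibi_from_beats(beats)
    if ibi.intervals.size >= 3:
        try:
            ibi = clean_ibi(ibi)
        except ValueError:
            pass
    return ibi


# --------------------------------------------------------------------------
# GSR


def extract_gsr_features(
    gsr, fs: float, min_prominence: float = 0.05, seg_s: float = 10.0
) -> dict[str, float]:
    """Phasic-peak and distribution features of the skin conductance.

    The signal is low-pass smoothed at 1 Hz before peak picking (the
    phasic skin-conductance response is far slower than that). Peaks
    are local maxima with prominence >= ``min_prominence`` (conductance
    units); each peak's valley is the minimum over the preceding 5 s,
    giving amplitude (maximum - minimum), rise time and peak-to-valley
    slope. ``peak_index`` is the mean peak sample index
    normalized by the window length (a peak-timing centroid). Quartiles
    use linear interpolation between order statistics.
    """
    if fs < 2:
        raise ValueError(f"fs must be >= 2 Hz for GSR features, got {fs}")
    x = np.asarray(gsr, dtype=float)
    out = {f"GSR_{n}": math.nan for n in GSR_FEATURES}
    out["GSR_mean"] = float(np.mean(x))
    out["GSR_sd"] = float(np.std(x, ddof=0))
    out["GSR_q1"] = float(np.quantile(x, 0.25))
    out["GSR_q3"] = float(np.quantile(x, 0.75))
    if x.size >= int(4 * fs):
        out["GSR_power_sub1hz"] = welch_band_power(
            x - x.mean(), fs, (0.0, min(1.0, fs / 2)), seg_s=seg_s
        )
    if fs > 2.5 and x.size > 12:
        sos = sps.butter(2, 1.0, btype="lowpass", fs=fs, output="sos")
        sm = sps.sosfiltfilt(sos, x)
    else:
        sm = x
    peaks, _ = sps.find_peaks(sm, prominence=min_prominence, distance=max(1, int(fs)))
    out["GSR_n_peaks"] = float(peaks.size)
    if peaks.size:
        amps, rises, slopes = [], [], []
        back = int(5 * fs)
        for p in peaks:
            lo = max(0, p - back)
            v = lo + int(np.argmin(sm[lo : p + 1]))
            amps.append(sm[p] - sm[v])
            rt = (p - v) / fs
            rises.append(rt)
            slopes.append((sm[p] - sm[v]) / rt if rt > 0 else math.nan)
        out["GSR_peak_amplitude"] = float(np.mean(amps))
        out["GSR_rise_time"] = float(np.mean(rises))
        out["GSR_slope"] = float(np.nanmean(slopes))
        out["GSR_peak_index"] = float(np.mean(peaks) / x.size)
    return out


# --------------------------------------------------------------------------
# respiration


def extract_resp_features(resp, fs: float, seg_s: float = 25.0) -> dict[str, float]:
    """Mean, SD, (Pearson, non-excess) kurtosis and six band powers."""
    if fs < 2:
        raise ValueError(f"fs must be >= 2 Hz for respiration features, got {fs}")
    x = np.asarray(resp, dtype=float)
    out: dict[str, float] = {
        "RR_mean": float(np.mean(x)),
        "RR_sd": float(np.std(x, ddof=0)),
        "RR_kurtosis": (
            float(spstats.kurtosis(x, fisher=False)) if np.std(x) > 0 else math.nan
        ),
    }
    centred = x - x.mean()
    for lo, hi in RESP_BANDS:
        key = f"RR_power_{lo:.1f}_{hi:.1f}"
        out[key] = welch_band_power(centred, fs, (lo, hi), seg_s=seg_s)
    return out


# --------------------------------------------------------------------------
# vehicular


def lowess_smooth(x: np.ndarray, points: int = 110) -> np.ndarray:
    """Lowess smoothing with a locally linear model over ``points`` samples."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    x = np.asarray(x, dtype=float)
    frac = min(1.0, points / x.size)
    t = np.arange(x.size, dtype=float)
    return lowess(x, t, frac=frac, it=0, return_sorted=False)


def steering_reversal_rate(
    swa, gap_deg: float = 1.0, smooth_points: int = 110
) -> float:
    """Count of steering direction reversals with angular gap >= ``gap_deg``.

    The raw angle is Lowess-smoothed (locally linear, ``smooth_points``
    samples), reduced to its sequence of stationary extremes, and a
    reversal is counted whenever the angle swing between consecutive
    extremes reaches the gap threshold.
    """
    x = np.asarray(swa, dtype=float)
    if x.size < 3 or np.ptp(x) == 0:
        return 0.0
    sm = lowess_smooth(x, smooth_points)
    d = np.diff(sm)
    sign = np.sign(d)
    sign[sign == 0] = 1.0
    turn = np.flatnonzero(sign[1:] != sign[:-1]) + 1
    idx = np.concatenate([[0], turn, [sm.size - 1]])
    extremes = sm[idx]
    count = 0
    anchor = extremes[0]
    direction = 0.0
    for v in extremes[1:]:
        step = v - anchor
        if direction == 0.0:
            if abs(step) >= gap_deg:
                direction = np.sign(step)
                anchor = v
        elif np.sign(step) == -direction and abs(step) >= gap_deg:
            count += 1
            direction = -direction
            anchor = v
        elif np.sign(step) == direction:
            anchor = v
    return float(count)


def steering_entropy(
    swa, baseline_errors: np.ndarray | None = None
) -> float:
    """Boer-style steering entropy in bits.

    Each sample is predicted by a second-order Taylor extrapolation of
    the three previous samples; the prediction errors are binned into 9
    bins with edges at ±0.5α, ±α, ±2.5α, ±5α where α is the 90th
    percentile of the absolute baseline errors (the window's own errors
    when no baseline is supplied), and the Shannon entropy of the bin
    distribution is returned (log base 2). A constant wheel gives 0.
    """
    x = np.asarray(swa, dtype=float)
    if x.size < 4:
        return 0.0
    pred = x[2:-1] + (x[2:-1] - x[1:-2]) + 0.5 * ((x[2:-1] - x[1:-2]) - (x[1:-2] - x[0:-3]))
    err = x[3:] - pred
    ref = err if baseline_errors is None else np.asarray(baseline_errors, dtype=float)
    alpha = float(np.percentile(np.abs(ref), 90))
    if alpha <= 0:
        return 0.0
    edges = np.array([-5, -2.5, -1, -0.5, 0.5, 1, 2.5, 5]) * alpha
    counts = np.histogram(err, bins=np.concatenate([[-np.inf], edges, [np.inf]]))[0]
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def extract_vehicular_features(window: ScenarioWindow) -> dict[str, float]:
    """Lateral control, steering and lane-keeping summaries."""
    needed = [
        "VEH latpos_m", "VEH latspeed_mps", "VEH swa_deg",
        "VEH yaw_deg", "VEH yawrate_dps", "VEH landep_flag",
    ]
    for name in needed:
        if name not in window.channels:
            raise ValueError(f"missing vehicular channel {name!r}")
    fs = window.rates["VEH swa_deg"]
    latpos = window.channels["VEH latpos_m"]
    swa = window.channels["VEH swa_deg"]
    out = {
        "VEH_sd_latpos": float(np.std(latpos, ddof=0)),
        "VEH_mse_latpos": float(np.mean(latpos**2)),  # lane centre at 0
        "VEH_sd_swa": float(np.std(swa, ddof=0)),
        "VEH_steering_entropy": steering_entropy(swa),
        "VEH_swrr": steering_reversal_rate(swa),
        "VEH_swa_highfreq": (
            welch_band_power(swa - swa.mean(), fs, (0.3, fs / 2), seg_s=20.0)
            if np.ptp(swa) > 0
            else 0.0
        ),
        "VEH_swa_zero_crossings": float(np.count_nonzero(swa[:-1] * swa[1:] < 0)),
        "VEH_lanex": float(np.mean(window.channels["VEH landep_flag"] > 0)),
        "VEH_sd_latspeed": float(np.std(window.channels["VEH latspeed_mps"], ddof=0)),
        "VEH_sd_yaw": float(np.std(window.channels["VEH yaw_deg"], ddof=0)),
        "VEH_sd_yawrate": float(np.std(window.channels["VEH yawrate_dps"], ddof=0)),
    }
    return out


# --------------------------------------------------------------------------
# assembly


def assemble_feature_vector(window: ScenarioWindow) -> pd.Series:
    """All 323 named features of one window plus its labels.

    The order is fixed (see :func:`feature_names`); labels ``task``,
    ``scenario`` and ``participant`` are appended after the features.
    """
    values: dict[str, float] = {}
    values.update(extract_eeg_features(window))
    fs_eog = window.rates["EOG V"]
    blinks = detect_blinks(window.channels["EOG V"], fs_eog)
    values.update(extract_eog_features(blinks, window.duration_s))
    values.update(extract_hrv_features(hrv_from_window(window)))
    values.update(extract_gsr_features(window.channels["GSR"], window.rates["GSR"]))
    values.update(extract_resp_features(window.channels["RESP"], window.rates["RESP"]))
    values.update(extract_vehicular_features(window))

    names = feature_names()
    missing = [n for n in names if n not in values]
    if missing:
        raise RuntimeError(f"feature assembly incomplete: {missing[:5]} ...")
    row = pd.Series({n: values[n] for n in names})
    row["task"] = window.task
    row["scenario"] = window.scenario
    row["participant"] = window.participant_id
    return row


def extract_feature_table(windows: list[ScenarioWindow]) -> pd.DataFrame:
    """Feature vectors for many windows, one row per window."""
    return pd.DataFrame([assemble_feature_vector(w) for w in windows]).reset_index(
        drop=True
    )
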