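"""Raw-channel cleaning, QRS → inter-beat intervals, window segmentation.

The analysis unit is a 50-s window: each scripted driving event lasts
60 s and the first 10 s are discarded while the driver settles into the
task, so the window is the half-open interval [start+10, start+60).

EEG is band-pass filtered 0.5–60 Hz (8th-order Butterworth) with a
4th-order Butterworth band-stop at 48–52 Hz for mains interference;
filters run forward–backward so no feature is phase-shifted. Vehicular,
respiration and skin-conductance channels get a median filter against
spiky noise. The ECG channel is reduced to an inter-beat-interval (IBI)
series by a derivative/adaptive-threshold QRS detector, then cleaned by
a deterministic threshold rule (see :func:`clean_ibi`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

log = logging.getLogger(__name__)

__all__ = [
    "MultimodalRecording",
    "ScenarioWindow",
    "IBISeries",
    "SCENARIOS",
    "TASKS",
    "filter_eeg",
    "notch_mains",
    "median_denoise",
    "detect_r_peaks",
    "ibi_from_beats",
    "clean_ibi",
    "segment_windows",
]

SCENARIOS = ("CR", "HE", "SW")  # crossing, hidden exit, side wind
TASKS = ("baseline", "1-back", "2-back")

DISCARD_S = 10.0
WINDOW_S = 50.0


@dataclass
class MultimodalRecording:
    """Synchronized raw channels with per-channel sampling rates.

    All channels start at session time 0; ``channels[name]`` has
    ``rates[name] * duration_s`` samples (within one sample).
    """

    channels: dict[str, np.ndarray]
    rates: dict[str, float]
    participant_id: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        name = next(iter(self.channels))
        return len(self.channels[name]) / self.rates[name]

    def eeg_labels(self) -> list[str]:
        return [c for c in self.channels if c.startswith("EEG ")]


@dataclass
class ScenarioWindow:
    """One labelled 50-s analysis segment, channels sliced consistently."""

    start_s: float
    scenario: str
    task: str
    channels: dict[str, np.ndarray]
    rates: dict[str, float]
    participant_id: str = ""
    duration_s: float = WINDOW_S

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")


@dataclass
class IBISeries:
    """Beat times (s) and the intervals between them (ms)."""

    beat_times: np.ndarray  # seconds, strictly increasing, len n+1
    intervals: np.ndarray  # ms, len n
    cleaned: np.ndarray | None = None  # bool per interval: was replaced

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.size and (self.intervals <= 0).any():
            raise ValueError("all inter-beat intervals must be > 0")
        if self.cleaned is None:
            self.cleaned = np.zeros(self.intervals.size, dtype=bool)


def filter_eeg(channel, fs: float) -> np.ndarray:
    """Zero-phase 0.5–60 Hz band-pass plus 48–52 Hz mains band-stop.

    Requires fs > 120 Hz so the 60-Hz band edge sits below Nyquist.
    """
    if fs <= 120:
        raise ValueError(f"fs must exceed 120 Hz for the 60-Hz band edge, got {fs}")
    x = np.asarray(channel, dtype=float)
    band = sps.butter(8, [0.5, 60.0], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(band, x)
    return notch_mains(y, fs)


def notch_mains(channel, fs: float) -> np.ndarray:
    """4th-order Butterworth band-stop over 48–52 Hz, zero-phase."""
    stop = sps.butter(4, [48.0, 52.0], btype="bandstop", fs=fs, output="sos")
    return sps.sosfiltfilt(stop, np.asarray(channel, dtype=float))


def median_denoise(signal, kernel: int = 5) -> np.ndarray:
    """Median filter; removes isolated spikes while keeping edges."""
    if kernel % 2 == 0 or kernel < 3:
        raise ValueError(f"kernel must be odd and >= 3, got {kernel}")
    return sps.medfilt(np.asarray(signal, dtype=float), kernel_size=kernel)


def detect_r_peaks(ecg, fs: float, refractory_s: float = 0.2) -> np.ndarray:
    """R-peak times via a derivative + adaptive-threshold QRS detector.

    Pan–Tompkins-family pipeline: 5–15 Hz band-pass, differentiate,
    square, moving-window integrate (150 ms), threshold at a running
    mixture of recent peak and noise levels, enforce a >= 200 ms
    refractory period, then snap each detection to the local maximum of
    the band-passed signal.

    Returns an empty array (with a warning) on flat or sub-threshold input.
    """
    if fs < 100:
        raise ValueError(f"fs must be >= 100 Hz for QRS detection, got {fs}")
    x = np.asarray(ecg, dtype=float)
    if x.size < int(10 * fs):
        raise ValueError("need at least 10 s of ECG")
    if np.ptp(x) == 0:
        warnings.warn("flat ECG signal: no beats detected")
        return np.array([])

    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    deriv = np.gradient(bp)
    sq = deriv**2
    win = max(1, int(round(0.150 * fs)))
    integ = np.convolve(sq, np.ones(win) / win, mode="same")

    refr = int(round(refractory_s * fs))
    # seed thresholds from the first 2 s
    spki = float(np.max(integ[: int(2 * fs)])) * 0.6
    npki = float(np.mean(integ[: int(2 * fs)])) * 0.5
    thr = npki + 0.25 * (spki - npki)

    cand, _ = sps.find_peaks(integ, distance=refr)
    beats = []
    for i in cand:
        if integ[i] > thr:
            spki = 0.125 * integ[i] + 0.875 * spki
            beats.append(i)
        else:
            npki = 0.125 * integ[i] + 0.875 * npki
        thr = npki + 0.25 * (spki - npki)

    if not beats:
        warnings.warn("no QRS complexes found above threshold")
        return np.array([])

    # snap to the local band-passed maximum within ±80 ms
    half = int(round(0.08 * fs))
    times = []
    for i in beats:
        lo, hi = max(0, i - half), min(x.size, i + half + 1)
        times.append((lo + int(np.argmax(bp[lo:hi]))) / fs)
    times = np.array(sorted(set(times)))
    # refractory on the snapped times
    keep = [0]
    for j in range(1, times.size):
        if times[j] - times[keep[-1]] >= refractory_s:
            keep.append(j)
    return times[keep]


def ibi_from_beats(beat_times) -> IBISeries:
    """Build an IBI series (ms) from strictly increasing beat times (s)."""
    t = np.asarray(beat_times, dtype=float)
    if t.size and (np.diff(t) <= 0).any():
        raise ValueError("beat times must be strictly increasing")
    return IBISeries(beat_times=t, intervals=np.diff(t) * 1000.0)


def clean_ibi(
    ibi: IBISeries,
    lo_ms: float = 300.0,
    hi_ms: float = 2000.0,
    max_rel_dev: float = 0.30,
    local_window: int = 5,
) -> IBISeries:
    """Flag artifact intervals and replace them by the local median.

    An interval is flagged when it lies outside [lo_ms, hi_ms] or
    deviates more than ``max_rel_dev`` from the median of the
    ``local_window`` surrounding *unflagged-candidate* values (computed
    on the raw series). Flagged values are replaced by that local
    median, which makes the operation idempotent. Beat times are left
    untouched; ``cleaned`` marks the replaced intervals.
    """
    x = np.asarray(ibi.intervals, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 intervals to clean")
    half = local_window // 2
    med = np.empty_like(x)
    for i in range(x.size):
        lo = max(0, i - half)
        med[i] = np.median(x[lo : i + half + 1])
    bad = (x < lo_ms) | (x > hi_ms) | (np.abs(x - med) > max_rel_dev * med)
    if bad.all():
        raise ValueError("all intervals flagged as artifacts in this window")
    out = x.copy()
    if bad.any():
        # local median of neighbouring good intervals
        good_idx = np.flatnonzero(~bad)
        for i in np.flatnonzero(bad):
            order = good_idx[np.argsort(np.abs(good_idx - i), kind="stable")][
                :local_window
            ]
            out[i] = np.median(x[order])
    return IBISeries(
        beat_times=ibi.beat_times.copy(),
        intervals=out,
        cleaned=bad | np.asarray(ibi.cleaned, dtype=bool),
    )


def segment_windows(
    recording: MultimodalRecording,
    events: list[tuple[float, str, str]],
    discard_s: float = DISCARD_S,
    window_s: float = WINDOW_S,
) -> list[ScenarioWindow]:
    """Cut one labelled window per scripted event.

    ``events`` holds (event_start_s, scenario, task); the window spans
    [event_start + discard, event_start + discard + window) half-open.
    Events that extend past the end of the recording are skipped with a
    warning and do not produce a window.
    """
    total = recording.duration_s
    out = []
    skipped = 0
    for start, scenario, task in events:
        w0 = start + discard_s
        w1 = w0 + window_s
        if w1 > total + 1e-9:
            skipped += 1
            warnings.warn(
                f"event at t={start:.1f}s needs data to {w1:.1f}s but the "
                f"recording ends at {total:.1f}s; skipped"
            )
            continue
        sliced = {}
        for name, data in recording.channels.items():
            fs = recording.rates[name]
            i0 = int(round(w0 * fs))
            i1 = i0 + int(round(window_s * fs))
            sliced[name] = data[i0:i1]
        out.append(
            ScenarioWindow(
                start_s=w0,
                scenario=scenario,
                task=task,
                channels=sliced,
                rates=dict(recording.rates),
                participant_id=recording.participant_id,
                duration_s=window_s,
            )
        )
    if skipped:
        log.info("segment_windows: skipped %d event(s) outside the recording", skipped)
    return out
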