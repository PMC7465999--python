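"""Synthetic multimodal driving sessions with controllable load effects.

A simulated session is a sequence of scripted 60-s driving events, each
a (scenario, task) pair: scenarios CR (crossing traffic), HE (hidden
exit) and SW (side wind), tasks baseline / 1-back / 2-back. The n-back
working-memory task raises cognitive load, and every generated modality
moves the way the physiology literature reports for load:

* EEG alpha- and theta-band power increase,
* eye-blink rate increases,
* mean heart rate increases while SDNN-scale heart-rate variability
  drops and the LF/HF spectral balance shifts to LF,
* skin-conductance (GSR) phasic peaks become more frequent and larger,
* respiration accelerates,
* lateral-position variability and steering reversal activity grow.

Effect magnitudes are expressed as per-task multipliers relative to the
baseline task (all 1 by construction); scenario gains let one scenario
express the effect more strongly (the side-wind scenario, which demands
continuous lateral control, is given the largest gain by default).
Everything is driven by one integer seed: identical configuration and
seed give bit-identical output.

The module also provides a fast tabular generator
(:func:`generate_feature_table`) that skips signal synthesis and plants
class-mean shifts directly into a named 323-column feature table, for
exercising the selection and classification stages at scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import zlib

import numpy as np
import pandas as pd

from .preprocessing import SCENARIOS, TASKS, MultimodalRecording

__all__ = [
    "EEG_CHANNELS",
    "EFFECT_FIELDS",
    "LoadEffectProfile",
    "SimulationConfig",
    "EventTruth",
    "GroundTruth",
    "simulate_session",
    "simulate_cohort",
    "generate_feature_table",
    "scr_waveform",
    "blink_waveform",
    "default_profile",
]

# 30-channel 10-20 montage (includes the frontal row the selection stage
# tends to pick up: Fp1/Fpz/Fp2/F7/F4/FC2/FC5)
EEG_CHANNELS = [
    "Fp1", "Fpz", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2", "POz",
]

EFFECT_FIELDS = (
    "alpha_power",
    "theta_power",
    "blink_rate",
    "mean_hr",
    "sdnn_scale",
    "lf_hf_ratio",
    "gsr_peak_rate",
    "gsr_peak_amplitude",
    "resp_rate",
    "latpos_sd",
    "swrr_rate",
)

# Task multipliers are deliberately modest: single-modality information
# should be partial, with reliable separation only when modalities are
# combined. Calibrated once against the default cohort, then frozen.
_DEFAULT_MULTIPLIERS = {
    "baseline": {f: 1.0 for f in EFFECT_FIELDS},
    "1-back": {
        "alpha_power": 1.12,
        "theta_power": 1.10,
        "blink_rate": 1.25,
        "mean_hr": 1.05,
        "sdnn_scale": 0.87,
        "lf_hf_ratio": 1.15,
        "gsr_peak_rate": 1.30,
        "gsr_peak_amplitude": 1.12,
        "resp_rate": 1.10,
        "latpos_sd": 1.15,
        "swrr_rate": 1.20,
    },
    "2-back": {
        "alpha_power": 1.25,
        "theta_power": 1.20,
        "blink_rate": 1.50,
        "mean_hr": 1.10,
        "sdnn_scale": 0.75,
        "lf_hf_ratio": 1.35,
        "gsr_peak_rate": 1.60,
        "gsr_peak_amplitude": 1.25,
        "resp_rate": 1.20,
        "latpos_sd": 1.30,
        "swrr_rate": 1.40,
    },
}

_DEFAULT_NOISE_SD = {
    "eeg": 1.0,   # pink-background amplitude, arbitrary µV-like units
    "eog": 15.0,
    "ecg": 0.02,
    "gsr": 0.02,
    "resp": 0.10,
    "veh": 0.05,
}

# the side-wind scenario demands continuous lateral control, so load
# expresses more strongly there (multipliers are raised to this power)
_DEFAULT_SCENARIO_GAIN = {"CR": 1.0, "HE": 1.0, "SW": 1.5}


@dataclass(frozen=True)
class LoadEffectProfile:
    """Per-task effect multipliers plus per-modality noise levels."""

    task_multipliers: dict = field(
        default_factory=lambda: {t: dict(m) for t, m in _DEFAULT_MULTIPLIERS.items()}
    )
    noise_sd: dict = field(default_factory=lambda: dict(_DEFAULT_NOISE_SD))
    scenario_gain: dict = field(default_factory=lambda: dict(_DEFAULT_SCENARIO_GAIN))

    def __post_init__(self) -> None:
        for task, mults in self.task_multipliers.items():
            for name, v in mults.items():
                if name not in EFFECT_FIELDS:
                    raise ValueError(f"unknown effect field {name!r}")
                if v <= 0:
                    raise ValueError(f"multiplier {name!r} for {task!r} must be > 0")
        base = self.task_multipliers.get("baseline", {})
        if any(base.get(f, 1.0) != 1.0 for f in EFFECT_FIELDS):
            raise ValueError("baseline task must have all multipliers equal to 1")

    def multiplier(self, task: str, name: str, scenario: str | None = None) -> float:
        m = self.task_multipliers[task].get(name, 1.0)
        if scenario is not None:
            m **= self.scenario_gain.get(scenario, 1.0)
        return m


def default_profile() -> LoadEffectProfile:
    return LoadEffectProfile()


def _default_schedule() -> list[tuple[str, str]]:
    # 12 events: every (scenario, task) pair once, plus one extra
    # baseline pass per scenario -> 6/3/3 baseline/1-back/2-back,
    # mirroring the baseline-heavy imbalance of n-back driving studies
    sched = []
    for sc in SCENARIOS:
        sched.append((sc, "baseline"))
        sched.append((sc, "1-back"))
        sched.append((sc, "baseline"))
        sched.append((sc, "2-back"))
    return sched


@dataclass(frozen=True)
class SimulationConfig:
    """Everything that determines a generated session except the participant."""

    n_participants: int = 16
    scenario_schedule: list = field(default_factory=_default_schedule)
    event_duration: float = 60.0
    sampling_rates: dict = field(
        default_factory=lambda: {"eeg": 256.0, "eog": 256.0, "ecg": 256.0,
                                 "gsr": 32.0, "resp": 32.0, "veh": 10.0}
    )
    effect_profile: LoadEffectProfile = field(default_factory=LoadEffectProfile)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.event_duration <= 0:
            raise ValueError("event_duration must be > 0 seconds")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for name, fs in self.sampling_rates.items():
            if fs <= 0:
                raise ValueError(f"sampling_rates[{name!r}] must be > 0, got {fs}")
        for sc, task in self.scenario_schedule:
            if sc not in SCENARIOS:
                raise ValueError(f"scenario_schedule: unknown scenario {sc!r}")
            if task not in TASKS:
                raise ValueError(f"scenario_schedule: unknown task {task!r}")


@dataclass
class EventTruth:
    """Injected event times (session-absolute seconds) for one event."""

    start_s: float
    scenario: str
    task: str
    blink_times: np.ndarray
    r_peak_times: np.ndarray
    gsr_peak_times: np.ndarray
    swa_reversal_times: np.ndarray


@dataclass
class GroundTruth:
    participant_id: str
    events: list[EventTruth]

    def event_list(self) -> list[tuple[float, str, str]]:
        """(start_s, scenario, task) triples for window segmentation."""
        return [(e.start_s, e.scenario, e.task) for e in self.events]


# --------------------------------------------------------------------------
# waveform building blocks


def blink_waveform(fs: float, amplitude: float = 1.0,
                   close_s: float = 0.12, reopen_s: float = 0.18) -> np.ndarray:
    """Asymmetric lid-closure bump: fast half-cosine up, slower down."""
    up = int(round(close_s * fs))
    down = int(round(reopen_s * fs))
    rise = (1 - np.cos(np.pi * np.arange(up) / up)) / 2
    fall = (1 + np.cos(np.pi * np.arange(down + 1) / down)) / 2
    return amplitude * np.concatenate([rise, fall])


def scr_waveform(fs: float, amplitude: float = 1.0,
                 rise_s: float = 1.5, decay_s: float = 4.0) -> np.ndarray:
    """Skin-conductance response: smooth rise to peak, exponential decay."""
    up = int(round(rise_s * fs))
    rise = amplitude * (1 - np.cos(np.pi * np.arange(up + 1) / up)) / 2
    t = np.arange(1, int(round(5 * decay_s * fs))) / fs
    fall = amplitude * np.exp(-t / decay_s)
    return np.concatenate([rise, fall])


def _qrs_waveform(fs: float) -> tuple[np.ndarray, int]:
    """One PQRST complex; returns (template, index of the R apex)."""
    t = np.arange(-0.30 * fs, 0.45 * fs) / fs

    def g(amp, mu, sigma):
        return amp * np.exp(-0.5 * ((t - mu) / sigma) ** 2)

    w = (
        g(0.15, -0.18, 0.025)   # P
        - g(0.15, -0.025, 0.010)  # Q
        + g(1.00, 0.0, 0.008)     # R
        - g(0.20, 0.025, 0.010)   # S
        + g(0.30, 0.25, 0.060)    # T
    )
    return w, int(np.argmin(np.abs(t)))


def _poisson_times(rng: np.random.Generator, rate_per_s: float, duration: float,
                   min_gap: float, t0: float = 0.0) -> np.ndarray:
    """Poisson event times on [t0, duration - t0) with a hard minimum gap."""
    if rate_per_s <= 0:
        return np.array([])
    times = []
    t = t0 + rng.exponential(1.0 / rate_per_s)
    while t < duration - t0:
        times.append(t)
        t += min_gap + rng.exponential(1.0 / rate_per_s)
    return np.array(times)


def _add_templates(signal: np.ndarray, fs: float, times: np.ndarray,
                   template: np.ndarray, apex: int = 0) -> None:
    """Add a template at each time (time marks the apex sample), in place."""
    for tt in times:
        i0 = int(round(tt * fs)) - apex
        j0, j1 = max(0, -i0), min(template.size, signal.size - i0)
        if j1 > j0:
            signal[i0 + j0 : i0 + j1] += template[j0:j1]


def _band_shaped_noise(rng: np.random.Generator, n: int, fs: float,
                       pink_sd: float, band_gains: dict) -> np.ndarray:
    """Pink background plus band-limited components, via spectral shaping."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    gain = pink_sd / np.sqrt(np.maximum(freqs, 0.5))
    for (lo, hi), g in band_gains.items():
        gain[(freqs >= lo) & (freqs < hi)] += g
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white) * gain
    return np.fft.irfft(spec, n)


def _ou_process(rng: np.random.Generator, n: int, dt: float,
                theta: float, stationary_sd: float) -> np.ndarray:
    """Mean-reverting (Ornstein–Uhlenbeck) path with the given stationary SD."""
    x = np.empty(n)
    x[0] = rng.normal(0.0, stationary_sd)
    sigma = stationary_sd * np.sqrt(2.0 * theta)
    w = rng.standard_normal(n - 1) * sigma * np.sqrt(dt)
    for i in range(1, n):
        x[i] = x[i - 1] - theta * x[i - 1] * dt + w[i - 1]
    return x


# --------------------------------------------------------------------------
# per-event channel synthesis


def _draw_subject(rng: np.random.Generator) -> dict:
    """Per-participant trait baselines (between-subject heterogeneity)."""
    return {
        "hr_bpm": float(rng.normal(70.0, 6.0)),
        "sdnn_s": 0.040 * float(rng.lognormal(0.0, 0.20)),
        "alpha_gain": float(rng.lognormal(0.0, 0.25)),
        "theta_gain": float(rng.lognormal(0.0, 0.25)),
        "blink_per_s": max(float(rng.normal(15.0, 4.0)), 6.0) / 60.0,
        "scr_per_s": max(float(rng.normal(6.0, 1.5)), 2.0) / 60.0,
        "scr_amp": 0.30 * float(rng.lognormal(0.0, 0.25)),
        "resp_hz": float(rng.normal(0.25, 0.02)),
        "latpos_sd_m": 0.25 * float(rng.lognormal(0.0, 0.15)),
        "swrev_per_s": 0.25 * float(rng.lognormal(0.0, 0.20)),
    }


def _gen_event(rng: np.random.Generator, cfg: SimulationConfig,
               scenario: str, task: str, subj: dict) -> tuple[dict, dict]:
    prof = cfg.effect_profile
    dur = cfg.event_duration
    rates = cfg.sampling_rates

    def mult(name: str) -> float:
        return prof.multiplier(task, name, scenario)

    chans: dict[str, np.ndarray] = {}
    truth: dict[str, np.ndarray] = {}

    # --- EEG: pink background + band-limited components -------------------
    fs = rates["eeg"]
    n = int(round(dur * fs))
    a_gain = subj["alpha_gain"] * np.sqrt(mult("alpha_power"))
    t_gain = 0.8 * subj["theta_gain"] * np.sqrt(mult("theta_power"))
    bands = {
        (0.5, 4.0): 0.9,          # delta
        (4.0, 7.0): t_gain,       # theta
        (8.0, 12.0): a_gain,      # alpha
        (12.0, 30.0): 0.45,       # beta
        (31.0, 50.0): 0.20,       # gamma
    }
    for ch in EEG_CHANNELS:
        chans[f"EEG {ch}"] = _band_shaped_noise(
            rng, n, fs, prof.noise_sd["eeg"], bands
        )

    # --- EOG: blink templates on a slow-drift background ------------------
    fs = rates["eog"]
    n = int(round(dur * fs))
    blink_times = _poisson_times(
        rng, subj["blink_per_s"] * mult("blink_rate"), dur, min_gap=0.5, t0=0.5
    )
    veog = rng.standard_normal(n) * prof.noise_sd["eog"]
    # slow drift
    drift = np.cumsum(rng.standard_normal(n)) * prof.noise_sd["eog"] / np.sqrt(n) * 0.5
    veog += drift - drift.mean()
    tmpl = blink_waveform(fs, amplitude=1.0)
    apex = int(np.argmax(tmpl))
    for bt in blink_times:
        amp = 300.0 * rng.normal(1.0, 0.08)
        _add_templates(veog, fs, np.array([bt]), tmpl * amp, apex)
    chans["EOG V"] = veog
    chans["EOG H"] = rng.standard_normal(n) * prof.noise_sd["eog"]
    truth["blink_times"] = blink_times

    # --- ECG: IBI point process convolved with a PQRST template -----------
    fs = rates["ecg"]
    n = int(round(dur * fs))
    mean_ibi = 60.0 / (subj["hr_bpm"] * mult("mean_hr"))  # seconds per beat
    sdnn = subj["sdnn_s"] * mult("sdnn_scale")  # seconds
    lfhf = mult("lf_hf_ratio")
    lf_amp = 0.030 * np.sqrt(lfhf)
    hf_amp = 0.030 / np.sqrt(lfhf)
    resp_f = subj["resp_hz"] * mult("resp_rate")
    phi = 0.6  # AR(1) beat-to-beat correlation keeps DFA/entropy non-degenerate
    beats = []
    t = rng.uniform(0.0, mean_ibi)
    e = rng.normal(0.0, sdnn)
    ph_lf, ph_hf = rng.uniform(0, 2 * np.pi, 2)
    while t < dur:
        beats.append(t)
        osc = lf_amp * np.sin(2 * np.pi * 0.1 * t + ph_lf) + hf_amp * np.sin(
            2 * np.pi * resp_f * t + ph_hf
        )
        ibi = mean_ibi * (1.0 + osc) + e
        e = phi * e + rng.normal(0.0, sdnn * np.sqrt(1 - phi**2))
        t += max(ibi, 0.3)
    r_times = np.array(beats)
    ecg = rng.standard_normal(n) * prof.noise_sd["ecg"]
    qrs, r_apex = _qrs_waveform(fs)
    _add_templates(ecg, fs, r_times, qrs, r_apex)
    chans["ECG"] = ecg
    truth["r_peak_times"] = r_times

    # --- GSR: tonic drift + phasic SCR bumps ------------------------------
    fs = rates["gsr"]
    n = int(round(dur * fs))
    scr_times = _poisson_times(
        rng, subj["scr_per_s"] * mult("gsr_peak_rate"), dur, min_gap=3.0, t0=2.0
    )
    tonic = 2.0 + np.cumsum(rng.standard_normal(n)) * 0.002
    gsr = tonic - (tonic - tonic[0]).mean() + rng.standard_normal(n) * prof.noise_sd["gsr"]
    rise_s = 1.5
    for st in scr_times:
        amp = subj["scr_amp"] * mult("gsr_peak_amplitude") * rng.lognormal(0.0, 0.25)
        w = scr_waveform(fs, amplitude=amp, rise_s=rise_s)
        _add_templates(gsr, fs, np.array([st]), w, apex=0)
    chans["GSR"] = gsr
    # the detectable peak sits one rise time after SCR onset
    truth["gsr_peak_times"] = scr_times + rise_s

    # --- respiration: task-scaled sinusoid --------------------------------
    fs = rates["resp"]
    n = int(round(dur * fs))
    tt = np.arange(n) / fs
    f = subj["resp_hz"] * mult("resp_rate") * rng.normal(1.0, 0.03)
    chans["RESP"] = np.sin(2 * np.pi * f * tt + rng.uniform(0, 2 * np.pi)) + (
        rng.standard_normal(n) * prof.noise_sd["resp"]
    )

    # --- vehicular channels at 10 Hz --------------------------------------
    fs = rates["veh"]
    n = int(round(dur * fs))
    dt = 1.0 / fs
    latpos = _ou_process(rng, n, dt, theta=0.3,
                         stationary_sd=subj["latpos_sd_m"] * mult("latpos_sd"))
    latspeed = np.gradient(latpos) * fs + rng.standard_normal(n) * 0.01
    # steering: smooth correction component + telegraph zigzag whose
    # reversal rate scales with load
    from scipy import signal as sps

    smooth = sps.sosfiltfilt(
        sps.butter(2, 0.08, btype="lowpass", fs=fs, output="sos"),
        rng.standard_normal(n),
    )
    sd = float(np.std(smooth))
    smooth = smooth / sd * 1.5 if sd > 0 else smooth
    rev_times = _poisson_times(rng, subj["swrev_per_s"] * mult("swrr_rate"), dur, min_gap=0.8)
    slope = np.full(n, 1.2)  # deg/s
    sign = 1.0
    prev = 0
    for rt in rev_times:
        i = int(round(rt * fs))
        slope[prev:i] *= sign
        sign = -sign
        prev = i
    slope[prev:] *= sign
    zig = np.cumsum(slope) * dt
    zig -= zig.mean()
    swa = smooth + zig + rng.standard_normal(n) * prof.noise_sd["veh"]
    yaw = sps.sosfiltfilt(
        sps.butter(2, 0.15, btype="lowpass", fs=fs, output="sos"),
        rng.standard_normal(n),
    )
    yawrate = np.gradient(yaw) * fs
    landep = (np.abs(latpos) > 0.9).astype(float)
    chans["VEH latpos_m"] = latpos
    chans["VEH latspeed_mps"] = latspeed
    chans["VEH swa_deg"] = swa
    chans["VEH yaw_deg"] = yaw
    chans["VEH yawrate_dps"] = yawrate
    chans["VEH landep_flag"] = landep
    truth["swa_reversal_times"] = rev_times

    return chans, truth


def _participant_key(participant_id: str) -> int:
    return zlib.crc32(str(participant_id).encode())


def simulate_session(
    config: SimulationConfig, participant_id: str
) -> tuple[MultimodalRecording, GroundTruth]:
    """Generate one participant's full session plus its ground truth.

    Deterministic: the RNG stream is keyed by (config.seed,
    participant_id), so the same call is bit-identical and different
    participants are independent.
    """
    rng = np.random.default_rng([config.seed, _participant_key(participant_id)])
    subj = _draw_subject(rng)
    all_chans: dict[str, list[np.ndarray]] = {}
    events: list[EventTruth] = []
    t0 = 0.0
    for scenario, task in config.scenario_schedule:
        chans, truth = _gen_event(rng, config, scenario, task, subj)
        for name, data in chans.items():
            all_chans.setdefault(name, []).append(data)
        events.append(
            EventTruth(
                start_s=t0,
                scenario=scenario,
                task=task,
                blink_times=truth["blink_times"] + t0,
                r_peak_times=truth["r_peak_times"] + t0,
                gsr_peak_times=truth["gsr_peak_times"] + t0,
                swa_reversal_times=truth["swa_reversal_times"] + t0,
            )
        )
        t0 += config.event_duration

    rates = {}
    for name in all_chans:
        if name.startswith("EEG "):
            rates[name] = config.sampling_rates["eeg"]
        elif name.startswith("EOG"):
            rates[name] = config.sampling_rates["eog"]
        elif name == "ECG":
            rates[name] = config.sampling_rates["ecg"]
        elif name == "GSR":
            rates[name] = config.sampling_rates["gsr"]
        elif name == "RESP":
            rates[name] = config.sampling_rates["resp"]
        else:
            rates[name] = config.sampling_rates["veh"]

    rec = MultimodalRecording(
        channels={k: np.concatenate(v) for k, v in all_chans.items()},
        rates=rates,
        participant_id=str(participant_id),
        meta={"seed": config.seed, "n_events": len(events)},
    )
    return rec, GroundTruth(participant_id=str(participant_id), events=events)


def simulate_cohort(
    config: SimulationConfig,
) -> list[tuple[MultimodalRecording, GroundTruth]]:
    """Simulate ``config.n_participants`` sessions (ids P01, P02, ...)."""
    return [
        simulate_session(config, f"P{i + 1:02d}")
        for i in range(config.n_participants)
    ]


# --------------------------------------------------------------------------
# fast tabular fixture


def generate_feature_table(
    n_per_class: tuple[int, int, int] = (306, 237, 178),
    n_informative: int = 42,
    effect_size: float = 1.0,
    seed: int = 0,
    scenario_gain: dict | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """A 323-column named feature table with planted class-mean shifts.

    ``n_per_class`` gives the row counts for (baseline, 1-back, 2-back).
    Exactly ``n_informative`` randomly chosen feature columns carry a
    standardized mean shift: 0 for baseline, ``effect_size/2`` for
    1-back and ``effect_size`` for 2-back (sign alternating across the
    informative columns); every other column is pure N(0, 1) noise.
    ``scenario_gain`` optionally scales the shift per scenario label.

    Returns the table (feature columns + ``task``, ``scenario``,
    ``participant``) and the list of informative column names.
    """
    from .features import feature_names

    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    names = feature_names()
    if n_informative > len(names):
        raise ValueError(f"n_informative must be <= {len(names)}")
    rng = np.random.default_rng(seed)
    informative = sorted(
        rng.choice(len(names), size=n_informative, replace=False).tolist()
    )
    info_names = [names[i] for i in informative]

    rows_total = sum(n_per_class)
    x = rng.standard_normal((rows_total, len(names)))
    tasks = np.repeat(list(TASKS), n_per_class)
    scenarios = np.array([SCENARIOS[i % 3] for i in range(rows_total)])
    gains = np.array([(scenario_gain or {}).get(sc, 1.0) for sc in scenarios])
    level = np.where(tasks == "1-back", 0.5, np.where(tasks == "2-back", 1.0, 0.0))
    shift = effect_size * level * gains
    for j, col in enumerate(informative):
        sign = 1.0 if j % 2 == 0 else -1.0
        x[:, col] += sign * shift
    df = pd.DataFrame(x, columns=names)
    df["task"] = tasks
    df["scenario"] = scenarios
    df["participant"] = [f"P{(i % 20) + 1:02d}" for i in range(rows_total)]
    # shuffle rows so folds are not task-sorted
    order = rng.permutation(rows_total)
    df = df.iloc[order].reset_index(drop=True)
    return df, info_names
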