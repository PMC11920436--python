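"""Synthetic sleep EEG, hypnograms, cue sounds and motor-task behavior.

Everything downstream of this module (closed-loop stimulation, event
detection, ERP/TFR, behavioral statistics) is tested against recordings
generated here, where the ground truth -- every planted slow oscillation
(SO), every spindle, every per-condition consolidation gain -- is known
exactly.

Conventions
-----------
* Amplitudes are microvolts (µV) throughout; times are seconds.
* SOs are one biphasic cycle: a raised-cosine negative half-wave (the
  down-state trough) followed by a raised-cosine positive half-wave (the
  up-state peak), with independently scalable trough and peak amplitudes.
* Spindles are Hann-windowed sinusoids in the sigma band.
* Background activity is Gaussian noise with a 1/f power spectrum.
* All generators are driven by an explicit integer seed and are
  bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

STAGES = ("W", "N1", "N2", "N3", "REM")
NREM_STAGES = ("N2", "N3")

#: default montage; Fpz is the online-detection channel
DEFAULT_CHANNELS = ("Fpz", "Fz", "C3", "Cz", "C4", "Pz", "Oz")

#: per-channel gain applied to planted events (fronto-central dominance)
_CHANNEL_GAIN = {
    "Fpz": 1.0, "Fz": 1.0, "Cz": 0.95, "C3": 0.9, "C4": 0.9,
    "Pz": 0.85, "Oz": 0.75,
}

EPOCH_S = 30.0


@dataclass
class EEGRecording:
    """Multichannel EEG with sampling rate, channel labels and hypnogram.

    ``signal`` has shape (n_channels, n_samples) in µV. ``hypnogram`` holds
    one stage label per 30-s epoch and must cover the whole recording.
    """

    signal: np.ndarray
    fs: float
    channels: tuple[str, ...]
    hypnogram: tuple[str, ...]
    start_time: float = 0.0

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.channels = tuple(self.channels)
        if len(self.channels) != self.signal.shape[0]:
            raise ValueError("channel list does not match signal rows")
        self.hypnogram = tuple(self.hypnogram)
        for st in self.hypnogram:
            if st not in STAGES:
                raise ValueError(f"unknown sleep stage label: {st!r}")
        n_epochs = math.ceil(self.duration_s / EPOCH_S)
        if len(self.hypnogram) != n_epochs:
            raise ValueError(
                f"hypnogram has {len(self.hypnogram)} epochs, "
                f"recording needs {n_epochs}"
            )

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.signal.shape[1] / self.fs

    def get_channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(f"channel {name!r} not in montage {self.channels}")
        return self.signal[self.channels.index(name)]

    def stage_at(self, t: float) -> str:
        idx = int((t - self.start_time) // EPOCH_S)
        idx = min(max(idx, 0), len(self.hypnogram) - 1)
        return self.hypnogram[idx]

    def nrem_mask(self) -> np.ndarray:
        """Boolean per-sample mask of N2/N3 sleep."""
        mask = np.zeros(self.n_samples, dtype=bool)
        spe = int(round(EPOCH_S * self.fs))
        for i, st in enumerate(self.hypnogram):
            if st in NREM_STAGES:
                mask[i * spe:(i + 1) * spe] = True
        return mask


@dataclass
class PlantedSO:
    trough_time: float      # s, trough of the negative half-wave
    trough_amp: float       # µV, negative
    ptp: float              # µV, trough-to-peak
    freq: float             # Hz, 1/period of the biphasic cycle

    def __post_init__(self):
        if self.trough_amp >= 0:
            raise ValueError("SO trough amplitude must be negative")
        if self.ptp <= 0 or self.freq <= 0:
            raise ValueError("SO PTP and frequency must be positive")


@dataclass
class PlantedSpindle:
    onset: float            # s
    duration: float         # s
    freq: float             # Hz
    amp: float              # µV, peak envelope amplitude

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("spindle duration must be positive")


@dataclass
class GroundTruth:
    """Planted events and noise parameters of a synthetic recording."""

    so_events: list[PlantedSO] = field(default_factory=list)
    spindle_events: list[PlantedSpindle] = field(default_factory=list)
    noise_exponent: float = 1.6     # power ~ 1/f**exponent above the knee
    noise_sd: float = 15.0          # broadband SD, µV


def _one_over_f_noise(n, fs, sd, exponent, rng, knee=1.0):
    """Gaussian noise with power ~ 1/f**exponent above a ~1 Hz knee.

    The plateau below the knee mirrors the low-frequency flattening of
    the aperiodic EEG spectrum (and avoids the DC singularity).
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    f = np.maximum(freqs, knee)
    spec *= f ** (-exponent / 2.0)
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def so_waveform(fs, trough_amp, ptp, freq):
    """One biphasic SO cycle sampled at ``fs``.

    Raised-cosine negative half-wave of amplitude ``trough_amp`` (< 0)
    followed by a raised-cosine positive half-wave of amplitude
    ``ptp + trough_amp``; each half lasts half a period of ``freq``.
    Returns (waveform, trough_offset_samples).
    """
    half = max(int(round(fs / (2.0 * freq))), 2)
    lobe = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(half) / half))
    peak_amp = ptp + trough_amp
    wave = np.concatenate([trough_amp * lobe, peak_amp * lobe])
    return wave, int(np.argmax(lobe))


def spindle_waveform(fs, duration, freq, amp):
    n = max(int(round(duration * fs)), 2)
    t = np.arange(n) / fs
    return amp * np.hanning(n) * np.sin(2.0 * np.pi * freq * t)


def generate_hypnogram(duration_s, plan):
    """Expand a stage plan into one label per 30-s epoch.

    ``plan`` is a sequence of ``(stage, duration_s)`` pairs covering at
    least ``duration_s`` seconds; stage durations are rounded to whole
    epochs.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n_epochs = math.ceil(duration_s / EPOCH_S)
    labels: list[str] = []
    for stage, dur in plan:
        if stage not in STAGES:
            raise ValueError(f"unknown sleep stage label: {stage!r}")
        labels.extend([stage] * int(round(dur / EPOCH_S)))
    if len(labels) < n_epochs:
        raise ValueError("plan does not cover the full duration")
    return tuple(labels[:n_epochs])


def sleep_efficiency(hypnogram) -> float:
    """Fraction of epochs spent asleep (N1/N2/N3/REM), in percent."""
    asleep = sum(1 for st in hypnogram if st != "W")
    return 100.0 * asleep / len(hypnogram)


def generate_sleep_eeg(
    duration_s,
    fs=1000.0,
    channels=DEFAULT_CHANNELS,
    hypnogram=None,
    so_rate=4.0,
    spindle_rate=2.0,
    so_trough_amp=(-110.0, -80.0),
    so_ptp=(150.0, 200.0),
    so_freq=(0.8, 1.3),
    spindle_freq=(11.0, 16.0),
    spindle_duration=(0.8, 2.0),
    spindle_amp=(25.0, 40.0),
    noise_sd=15.0,
    noise_exponent=1.6,
    min_separation=3.0,
    so_train_length=1,
    placement="poisson",
    seed=0,
):
    """Synthesize a multichannel NREM sleep EEG with planted events.

    Parameters
    ----------
    duration_s : float
        Recording length in seconds. The study's nights average 7.5 h;
        desk-scale analyses use much shorter recordings.
    so_rate, spindle_rate : float
        Planted events per minute (events are planted only within N2/N3
        epochs of the hypnogram).
    so_trough_amp, so_ptp, so_freq : tuple
        Uniform ranges for the planted SO parameters. The defaults keep
        every planted SO well inside the offline detector's acceptance
        windows (trough magnitude 40-200 µV, PTP 75-500 µV) with margin
        for background noise: at 0.8-1.3 Hz each half-wave lasts
        0.38-0.63 s, safely inside the 0.3-1.5 s (negative) and
        0.1-1 s (positive) duration windows even when slow noise
        perturbs the zero crossings.
    noise_sd : float
        Broadband SD of the 1/f background, µV. The source study does not
        report background levels; 15 µV gives an event-amplitude-to-noise
        ratio >= 5 at the default SO amplitudes.
    hypnogram : sequence of str, optional
        Per-30-s-epoch stages; defaults to all-N3.

    Returns
    -------
    (EEGRecording, GroundTruth)
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if so_rate < 0 or spindle_rate < 0:
        raise ValueError("event rates must be non-negative")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    channels = tuple(channels)
    if hypnogram is None:
        hypnogram = generate_hypnogram(duration_s, [("N3", duration_s + EPOCH_S)])
    nch = len(channels)

    sig = np.empty((nch, n))
    for c in range(nch):
        sig[c] = _one_over_f_noise(n, fs, noise_sd, noise_exponent, rng)

    # candidate event times restricted to NREM epochs, away from edges
    rec_stub = EEGRecording(np.zeros((1, n)), fs, ("Fpz",),
                            tuple(hypnogram))
    nrem = rec_stub.nrem_mask()
    nrem_minutes = nrem.sum() / fs / 60.0

    def _draw_times(rate, margin):
        if rate <= 0:
            return []
        if placement == "regular":
            # quasi-periodic recurrence (jittered grid), emulating the
            # rhythmic reoccurrence of SOs in deep NREM
            period = 60.0 / rate
            grid = np.arange(margin, duration_s - margin, period)
            times = grid + rng.uniform(-0.1 * period, 0.1 * period,
                                       grid.size)
            return sorted(t for t in times
                          if margin <= t <= duration_s - margin
                          and nrem[int(t * fs)])
        count = rng.poisson(rate * nrem_minutes)
        times: list[float] = []
        attempts = 0
        while len(times) < count and attempts < 50 * max(count, 1):
            attempts += 1
            t = rng.uniform(margin, duration_s - margin)
            i = int(t * fs)
            if not nrem[i]:
                continue
            if any(abs(t - u) < min_separation for u in times):
                continue
            times.append(t)
        return sorted(times)

    truth = GroundTruth(noise_exponent=noise_exponent, noise_sd=noise_sd)

    burst = max(int(so_train_length), 1)
    for t in _draw_times(so_rate / burst, 3.0 + burst):
        amp = rng.uniform(*so_trough_amp)
        ptp = rng.uniform(*so_ptp)
        freq = rng.uniform(*so_freq)
        wave, trough_off = so_waveform(fs, amp, ptp, freq)
        # SOs occur in trains of `so_train_length` back-to-back cycles
        start0 = int(round(t * fs)) - trough_off
        if start0 < 0 or start0 + burst * wave.size > n:
            continue
        for k in range(burst):
            start = start0 + k * wave.size
            for c, ch in enumerate(channels):
                g = _CHANNEL_GAIN.get(ch, 0.8)
                sig[c, start:start + wave.size] += g * wave
            truth.so_events.append(
                PlantedSO(trough_time=(start + trough_off) / fs,
                          trough_amp=amp, ptp=ptp, freq=freq))

    for t in _draw_times(spindle_rate, 3.0):
        dur = rng.uniform(*spindle_duration)
        freq = rng.uniform(*spindle_freq)
        amp = rng.uniform(*spindle_amp)
        wave = spindle_waveform(fs, dur, freq, amp)
        start = int(round(t * fs))
        if start + wave.size > n:
            continue
        for c, ch in enumerate(channels):
            g = _CHANNEL_GAIN.get(ch, 0.8)
            sig[c, start:start + wave.size] += g * wave
        truth.spindle_events.append(
            PlantedSpindle(onset=t, duration=dur, freq=freq, amp=amp))

    rec = EEGRecording(sig, fs, channels, tuple(hypnogram))
    return rec, truth


# ---------------------------------------------------------------------------
# auditory cues
# ---------------------------------------------------------------------------

CUE_DURATION_S = 0.100
CUE_RAMP_S = 0.010
N_HARMONICS = 11          # harmonics added on top of the fundamental


def _harmonic_complex(fs, f0, amps):
    n = int(round(CUE_DURATION_S * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    for k, a in enumerate(amps, start=1):
        x += a * np.sin(2.0 * np.pi * k * f0 * t)
    return x


def _apply_ramps(x, fs):
    nr = int(round(CUE_RAMP_S * fs))
    ramp = np.linspace(0.0, 1.0, nr)
    x = x.copy()
    x[:nr] *= ramp
    x[-nr:] *= ramp[::-1]
    return x


def synthesize_cue_sounds(fs_audio=44100.0):
    """The three 100-ms auditory cues used in the stimulation protocol.

    Returns a dict with keys ``low_tone`` (harmonic complex, fundamental
    543 Hz, 12 components with amplitudes linearly decreasing 1 -> 0.1),
    ``noise`` (white noise band-passed 100-1000 Hz) and ``high_tone``
    (fundamental 1480 Hz, amplitudes increasing 0.1 -> 1). Each sound is
    peak-normalized with 10-ms linear onset/offset ramps.
    """
    ncomp = N_HARMONICS + 1
    for f0 in (543.0, 1480.0):
        if ncomp * f0 >= fs_audio / 2.0:
            raise ValueError(
                f"fs_audio={fs_audio} aliases the {ncomp * f0:.0f} Hz harmonic")
    low = _harmonic_complex(fs_audio, 543.0, np.linspace(1.0, 0.1, ncomp))
    high = _harmonic_complex(fs_audio, 1480.0, np.linspace(0.1, 1.0, ncomp))
    rng = np.random.default_rng(543)
    n = int(round(CUE_DURATION_S * fs_audio))
    white = rng.standard_normal(n + 2000)
    sos = sps.butter(4, [100.0, 1000.0], btype="bandpass", fs=fs_audio,
                     output="sos")
    noise = sps.sosfiltfilt(sos, white)[1000:1000 + n]
    out = {}
    for name, x in (("low_tone", low), ("noise", noise), ("high_tone", high)):
        x = x / np.max(np.abs(x))
        out[name] = _apply_ramps(x, fs_audio)
    return out


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

@dataclass
class BehaviorSimParams:
    """Ground-truth parameters of the simulated SRTT behavior.

    ``gain_means`` are the planted per-condition overnight gains in
    percent speed change (positive = faster after sleep); ``gain_sd`` is
    the between-subject SD of each gain. ``rt_noise_sd_ms`` is the
    within-block keypress jitter. Learning within a session follows an
    exponential approach from ``initial_rt_ms`` to ``asymptote_rt_ms``.
    """

    n_subjects: int = 28
    gain_means: dict = field(
        default_factory=lambda: {"up": 8.0, "down": 2.0, "not": 7.0})
    gain_sd: float = 2.0                # %, per condition, between subjects
    subject_sd: float = 5.0             # %, shared subject intercept on gains
    rt_noise_sd_ms: float = 30.0
    initial_rt_ms: float = 420.0
    asymptote_rt_ms: float = 300.0
    learning_rate: float = 0.25         # per block, exponential decay
    error_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        for v in (self.gain_sd, self.subject_sd, self.rt_noise_sd_ms):
            if v < 0:
                raise ValueError("SD parameters must be non-negative")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


def generate_behavior(schedule, params: BehaviorSimParams):
    """Simulate per-keypress SRTT tables with planted consolidation gains.

    ``schedule`` is a :class:`clsleep.behavior.SessionSchedule`. Returns a
    pandas DataFrame with one row per keypress (subject, session, block,
    condition, press_index, key_expected, key_pressed, rt_ms, correct)
    such that the per-condition offline gains recoverable by
    :func:`clsleep.behavior.offline_change` equal ``gain_means`` up to
    sampling noise.
    """
    import pandas as pd

    rng = np.random.default_rng(params.seed)
    blocks = schedule.blocks
    frames = []
    n_rows_block = blocks["n_presses"].to_numpy()
    for s in range(params.n_subjects):
        subj_icpt = rng.normal(0.0, params.subject_sd)
        gains = {c: m + subj_icpt + rng.normal(0.0, params.gain_sd)
                 for c, m in params.gain_means.items()}
        # per-condition plateau RT at end of pre-night session
        plateau = {c: params.asymptote_rt_ms + rng.normal(0.0, 5.0)
                   for c in params.gain_means}
        plateau["random"] = params.initial_rt_ms

        rows_rt = []
        rows_correct = []
        within_block_idx = blocks.groupby(
            ["session", "condition"]).cumcount().to_numpy()
        for (_, blk), k in zip(blocks.iterrows(), within_block_idx):
            cond = blk["condition"]
            base = plateau.get(cond, params.asymptote_rt_ms)
            if blk["session"] == "pre_training":
                mean_rt = base + (params.initial_rt_ms - base) * math.exp(
                    -params.learning_rate * k)
            elif blk["session"] == "pre_test":
                mean_rt = base
            elif blk["session"] == "post_training":
                g = gains.get(cond, 0.0)
                mean_rt = base * (1.0 - g / 100.0)
                # mild continued learning after the first blocks
                mean_rt *= 1.0 - 0.01 * (1.0 - math.exp(-0.1 * k))
            else:  # random_pre / random_post
                mean_rt = params.initial_rt_ms
            npress = int(blk["n_presses"])
            rts = mean_rt + rng.normal(0.0, params.rt_noise_sd_ms, npress)
            rows_rt.append(np.maximum(rts, 80.0))
            rows_correct.append(rng.random(npress) >= params.error_rate)

        rep = np.repeat(np.arange(len(blocks)), n_rows_block)
        press_idx = np.concatenate([np.arange(k) for k in n_rows_block])
        expected = np.concatenate([
            np.resize(schedule.sequences.get(blk["sequence"], (0,)),
                      int(blk["n_presses"]))
            for _, blk in blocks.iterrows()
        ])
        correct = np.concatenate(rows_correct)
        pressed = expected.copy()
        wrong = ~correct
        pressed[wrong] = 1 + (expected[wrong] + rng.integers(
            1, 8, wrong.sum()) - 1) % 8
        frames.append(pd.DataFrame({
            "subject": s,
            "session": blocks["session"].to_numpy()[rep],
            "block": blocks["block"].to_numpy()[rep],
            "condition": blocks["condition"].to_numpy()[rep],
            "press_index": press_idx,
            "key_expected": expected,
            "key_pressed": pressed,
            "rt_ms": np.concatenate(rows_rt),
            "correct": correct,
        }))
    return pd.concat(frames, ignore_index=True)
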