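"""Cue- and trough-locked epochs, ERPs and Hann-taper time-frequency power.

Analyses run on 0.1-30 Hz band-passed data down-sampled to 100 Hz.
Trough-locked epochs span [-2, 2] s and cue-locked epochs [-2.5, 2] s
around the lock sample. Time-frequency power uses an adaptive sliding
window of five cycles per frequency (Hann taper, FFT) on a 5-30 Hz grid
with 20-ms steps, averaged over epochs after per-epoch power computation
(induced + evoked). Power is baseline-normalized as relative change
(P - B)/B, with B the mean power over a pre-cue window (cue lock) or the
whole epoch (trough lock).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from clsleep.synth import EEGRecording

ANALYSIS_FS = 100.0
WINDOWS = {"cue": (-2.5, 2.0), "trough": (-2.0, 2.0)}


@dataclass
class Epochs:
    """Epoch stack: ``data`` has shape (n_epochs, n_channels, n_times)."""

    data: np.ndarray
    times: np.ndarray           # s, relative to lock; t=0 at the lock sample
    fs: float
    channels: tuple[str, ...]
    lock: str                   # "cue" | "trough"
    condition: str = ""
    n_dropped: int = 0

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]


@dataclass
class TFRArray:
    """Channel x frequency x time power array (epoch average)."""

    power: np.ndarray
    freqs: np.ndarray           # Hz
    times: np.ndarray           # s relative to lock
    channels: tuple[str, ...]
    baseline_mode: str = "none"
    condition: str = ""


def _preprocess(recording: EEGRecording, target_fs=ANALYSIS_FS,
                band=(0.1, 30.0)):
    """Zero-phase 0.1-30 Hz band-pass, then polyphase resample."""
    fs = recording.fs
    taps = sps.firwin(int(fs) | 1, band, pass_zero=False, fs=fs)
    y = sps.filtfilt(taps, 1.0, recording.signal, axis=1)
    if fs != target_fs:
        up, down = (np.array([target_fs, fs]) /
                    np.gcd(int(target_fs), int(fs))).astype(int)
        y = sps.resample_poly(y, up, down, axis=1)
    return y


def make_epochs(recording: EEGRecording, lock_times, lock="trough",
                condition="", mask=None, window=None,
                target_fs=ANALYSIS_FS):
    """Cut band-passed, down-sampled epochs around ``lock_times``.

    ``mask``, if given, is a boolean per-sample array at the *recording*
    rate marking clean data; epochs overlapping rejected (False) samples
    are dropped, as are epochs extending past the recording edges. The
    number of dropped epochs is reported on the result.
    """
    if lock not in WINDOWS:
        raise ValueError(f"unknown lock kind {lock!r}")
    if window is None:
        window = WINDOWS[lock]
    y = _preprocess(recording, target_fs)
    n = y.shape[1]
    pre = int(round(-window[0] * target_fs))
    post = int(round(window[1] * target_fs))
    times = np.arange(-pre, post + 1) / target_fs
    data = []
    dropped = 0
    for t in np.asarray(lock_times, dtype=float):
        c = int(round(t * target_fs))
        if c - pre < 0 or c + post >= n:
            dropped += 1
            continue
        if mask is not None:
            lo = int(round((t + window[0]) * recording.fs))
            hi = int(round((t + window[1]) * recording.fs))
            if not np.all(mask[max(lo, 0):hi + 1]):
                dropped += 1
                continue
        data.append(y[:, c - pre:c + post + 1])
    if not data:
        raise ValueError("zero surviving epochs")
    return Epochs(np.asarray(data), times, target_fs, recording.channels,
                  lock, condition, dropped)


def average_erp(epochs: Epochs):
    """Pointwise mean and standard error over epochs (channel x time)."""
    if epochs.n_epochs < 2:
        raise ValueError("need at least 2 epochs for mean + SE")
    mean = epochs.data.mean(axis=0)
    se = epochs.data.std(axis=0, ddof=1) / np.sqrt(epochs.n_epochs)
    return mean, se


def compute_tfr(epochs: Epochs, freqs=None, step_s=0.02, n_cycles=5.0):
    """Hann-taper FFT power with an adaptive five-cycle window.

    For each frequency f the window length is ``n_cycles / f`` seconds;
    power is estimated every ``step_s`` at the window center, per epoch,
    then averaged over epochs. Power is scaled as one-sided spectral
    density (µV²/Hz) so that integrating over the frequency grid
    approximates band power.
    """
    if freqs is None:
        freqs = np.arange(5.0, 30.5, 1.0)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.min() < 5.0 or freqs.max() > 30.0:
        raise ValueError("frequency grid must lie within [5, 30] Hz")
    fs = epochs.fs
    data = epochs.data
    n_ep, n_ch, n_t = data.shape
    wlen_max = int(round(n_cycles / freqs.min() * fs))
    if n_t < wlen_max:
        raise ValueError("epochs too short for the lowest frequency window")
    step = max(int(round(step_s * fs)), 1)
    # common time grid: centers valid for the longest window
    half_max = wlen_max // 2
    centers = np.arange(half_max, n_t - half_max, step)
    times = epochs.times[centers]
    power = np.empty((n_ch, freqs.size, centers.size))
    flat = data.reshape(n_ep * n_ch, n_t)
    for fi, f in enumerate(freqs):
        wlen = int(round(n_cycles / f * fs))
        half = wlen // 2
        taper = np.hanning(wlen)
        kern = taper * np.exp(-2j * np.pi * f * np.arange(wlen) / fs)
        u = np.sum(taper ** 2)
        starts = centers - half
        segs = np.lib.stride_tricks.sliding_window_view(flat, wlen, axis=1)
        segs = segs[:, starts, :]
        amp = segs @ kern
        p = 2.0 * np.abs(amp) ** 2 / (fs * u)     # one-sided PSD, µV²/Hz
        power[:, fi, :] = p.reshape(n_ep, n_ch, centers.size).mean(axis=0)
    return TFRArray(power, freqs, times, epochs.channels,
                    condition=epochs.condition)


def baseline_normalize(tfr: TFRArray, mode="trough", baseline_window=None):
    """Convert power to relative change (P - B)/B per channel x frequency.

    ``mode="cue"`` uses the pre-cue window (default [-2.5, -2] s);
    ``mode="trough"`` uses the entire epoch as baseline.
    """
    if mode == "cue":
        if baseline_window is None:
            baseline_window = (-2.5, -2.0)
        sel = (tfr.times >= baseline_window[0]) & (tfr.times <= baseline_window[1])
        if not sel.any():
            raise ValueError("baseline window outside the epoch")
    elif mode == "trough":
        sel = np.ones_like(tfr.times, dtype=bool)
    else:
        raise ValueError(f"unknown baseline mode {mode!r}")
    b = tfr.power[:, :, sel].mean(axis=2, keepdims=True)
    if np.any(b == 0):
        raise ValueError("zero baseline power")
    return TFRArray((tfr.power - b) / b, tfr.freqs, tfr.times, tfr.channels,
                    baseline_mode=mode, condition=tfr.condition)
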