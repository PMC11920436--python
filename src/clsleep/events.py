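"""Offline detection of slow oscillations and sleep spindles.

SO detector
-----------
The signal is band-passed 0.3-2 Hz (linear-phase FIR, 0.2 Hz
transition, applied forward-backward so events are not shifted).
Negative peaks in the picking window and the next positive peak are
paired, then five logical thresholds select true SOs:

1. negative half-wave duration in [0.3, 1.5] s,
2. positive half-wave duration in [0.1, 1] s,
3. negative peak magnitude in [40, 300] µV,
4. positive peak amplitude in [10, 200] µV,
5. peak-to-peak amplitude in [75, 500] µV.

Spindle detector
----------------
Three sample-wise conditions must hold simultaneously: relative sigma
power (8-18 Hz over 1-30 Hz broadband, short-time Fourier transform
with 2-s windows every 200 ms) above 0.2; the 300-ms moving RMS of the
sigma-filtered signal above its mean + 1.5 SD; and the 300-ms moving
correlation between broadband and sigma-filtered signals above 0.65.
Contiguous runs form events; events shorter than 0.3 s or longer than
3 s are discarded, and events on different channels within 500 ms of
each other are merged (transitively) into a single spindle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from clsleep.synth import EEGRecording


@dataclass
class OscEvent:
    kind: str                   # "SO" | "spindle"
    channel: str
    onset: float                # s
    offset: float               # s
    trough_time: float = np.nan
    trough_amp: float = np.nan  # µV, negative for SOs
    peak_time: float = np.nan
    peak_amp: float = np.nan
    ptp: float = np.nan
    duration: float = np.nan    # s (spindles)
    freq: float = np.nan        # Hz (spindles: mean frequency)
    amp: float = np.nan         # µV (spindles: RMS amplitude)

    def __post_init__(self):
        if self.offset <= self.onset:
            raise ValueError("event offset must be after onset")


@dataclass
class DetectionParams:
    """Thresholds of the SO and spindle detectors (see module docstring)."""

    # --- slow oscillations ---
    so_band: tuple[float, float] = (0.3, 2.0)
    so_transition: float = 0.2                    # Hz
    neg_peak_window: tuple[float, float] = (-200.0, -40.0)   # picking, µV
    pos_peak_window: tuple[float, float] = (10.0, 150.0)     # picking, µV
    neg_duration: tuple[float, float] = (0.3, 1.5)           # s
    pos_duration: tuple[float, float] = (0.1, 1.0)           # s
    neg_amp: tuple[float, float] = (40.0, 300.0)             # magnitude, µV
    pos_amp: tuple[float, float] = (10.0, 200.0)             # µV
    ptp: tuple[float, float] = (75.0, 500.0)                 # µV
    # --- spindles ---
    broad_band: tuple[float, float] = (1.0, 30.0)
    sigma_band: tuple[float, float] = (8.0, 18.0)
    stft_window_s: float = 2.0
    stft_step_s: float = 0.2
    rel_power_threshold: float = 0.2
    rms_window_s: float = 0.3
    rms_step_s: float = 0.1
    rms_sd_factor: float = 1.5
    corr_threshold: float = 0.65
    spindle_duration: tuple[float, float] = (0.3, 3.0)       # s
    merge_window_s: float = 0.5

    def __post_init__(self):
        for name in ("so_transition", "stft_window_s", "stft_step_s",
                     "rms_window_s", "rms_step_s", "merge_window_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _fir_bandpass_zerophase(x, band, fs, transition):
    # odd-length symmetric (linear-phase) FIR applied centered via FFT
    # convolution: exactly zero-phase in one pass
    numtaps = min(int(np.ceil(3.3 * fs / transition)) | 1, x.size - 1 | 1)
    taps = sps.firwin(numtaps, band, pass_zero=False, fs=fs)
    return sps.fftconvolve(x, taps, mode="same")


def detect_slow_oscillations(recording: EEGRecording, channel="Fpz",
                             params: DetectionParams = None):
    """Run the parameterized SO detector on one channel.

    Returns a list of :class:`OscEvent` sorted by trough time; every
    event satisfies all five logical thresholds (see
    :func:`audit_so_events`).
    """
    if params is None:
        params = DetectionParams()
    fs = recording.fs
    x = recording.get_channel(channel)
    xf = _fir_bandpass_zerophase(x, params.so_band, fs, params.so_transition)

    neg_idx, _ = sps.find_peaks(-xf)
    pos_idx, _ = sps.find_peaks(xf)
    lo_n, hi_n = params.neg_peak_window
    neg_idx = neg_idx[(xf[neg_idx] >= lo_n) & (xf[neg_idx] <= hi_n)]
    lo_p, hi_p = params.pos_peak_window
    pos_idx = pos_idx[(xf[pos_idx] >= lo_p) & (xf[pos_idx] <= hi_p)]
    if neg_idx.size == 0 or pos_idx.size == 0:
        return []

    # zero crossings of the filtered trace
    sign = xf > 0
    n2p = np.flatnonzero(~sign[:-1] & sign[1:]) + 1
    p2n = np.flatnonzero(sign[:-1] & ~sign[1:]) + 1

    events = []
    for i, ni in enumerate(neg_idx):
        # pair with the next positive peak before the subsequent negative peak
        nxt_neg = neg_idx[i + 1] if i + 1 < neg_idx.size else xf.size
        cand = pos_idx[(pos_idx > ni) & (pos_idx < nxt_neg)]
        if cand.size == 0:
            continue
        pi = int(cand[0])
        # half-wave durations from surrounding zero crossings
        before = p2n[p2n <= ni]
        mid = n2p[(n2p > ni) & (n2p <= pi)]
        after = p2n[p2n > pi]
        if before.size == 0 or mid.size == 0 or after.size == 0:
            continue
        t0, t1, t2 = int(before[-1]), int(mid[0]), int(after[0])
        neg_dur = (t1 - t0) / fs
        pos_dur = (t2 - t1) / fs
        trough = float(xf[ni])
        peak = float(xf[pi])
        ptp = peak - trough
        if not (params.neg_duration[0] <= neg_dur <= params.neg_duration[1]):
            continue
        if not (params.pos_duration[0] <= pos_dur <= params.pos_duration[1]):
            continue
        if not (params.neg_amp[0] <= -trough <= params.neg_amp[1]):
            continue
        if not (params.pos_amp[0] <= peak <= params.pos_amp[1]):
            continue
        if not (params.ptp[0] <= ptp <= params.ptp[1]):
            continue
        events.append(OscEvent(
            kind="SO", channel=channel, onset=t0 / fs, offset=t2 / fs,
            trough_time=ni / fs, trough_amp=trough,
            peak_time=pi / fs, peak_amp=peak, ptp=ptp,
            freq=1.0 / max((t2 - t0) / fs, 1e-9)))
    events.sort(key=lambda e: e.trough_time)
    return events


def audit_so_events(events, params: DetectionParams = None):
    """Independently re-check every SO against the logical thresholds.

    Returns True iff all events pass; used as a post-hoc consistency
    audit of the detector.
    """
    if params is None:
        params = DetectionParams()
    for ev in events:
        neg_dur = ev.peak_time - ev.onset            # approx: trough half
        ok = (
            params.neg_amp[0] <= -ev.trough_amp <= params.neg_amp[1]
            and params.pos_amp[0] <= ev.peak_amp <= params.pos_amp[1]
            and params.ptp[0] <= ev.ptp <= params.ptp[1]
            and ev.offset > ev.onset
            and ev.trough_amp < 0
        )
        if not ok:
            return False
    return True


# ---------------------------------------------------------------------------
# spindles
# ---------------------------------------------------------------------------

def _moving_stat_grid(n, fs, win_s, step_s):
    win = int(round(win_s * fs))
    step = int(round(step_s * fs))
    starts = np.arange(0, n - win + 1, step)
    return win, step, starts


def _interp_to_samples(values, centers, n):
    t = np.arange(n)
    return np.interp(t, centers, values, left=values[0] if values.size else 0,
                     right=values[-1] if values.size else 0)


def detect_spindles(recording: EEGRecording, params: DetectionParams = None,
                    channels=None):
    """Run the three-threshold spindle detector on each channel.

    Returns a list of :class:`OscEvent` (kind "spindle") sorted by onset;
    cross-channel merging is left to :func:`merge_cross_channel`.
    """
    if params is None:
        params = DetectionParams()
    fs = recording.fs
    if channels is None:
        channels = recording.channels
    win_stft = int(round(params.stft_window_s * fs))
    if recording.n_samples < win_stft:
        raise ValueError("recording shorter than the STFT window")

    events = []
    for ch in channels:
        x = recording.get_channel(ch)
        n = x.size
        broad = _fir_bandpass_zerophase(x, params.broad_band, fs, 1.0)
        sigma = _fir_bandpass_zerophase(x, params.sigma_band, fs, 1.5)

        # (1) relative sigma power from the STFT
        step = int(round(params.stft_step_s * fs))
        freqs, times, Z = sps.stft(
            x, fs=fs, window="hann", nperseg=win_stft,
            noverlap=win_stft - step, boundary=None, padded=False)
        psd = np.abs(Z) ** 2
        broad_mask = (freqs >= params.broad_band[0]) & (freqs <= params.broad_band[1])
        sigma_mask = (freqs >= params.sigma_band[0]) & (freqs <= params.sigma_band[1])
        total = psd[broad_mask].sum(axis=0)
        relpow = np.divide(psd[sigma_mask].sum(axis=0), total,
                           out=np.zeros_like(total), where=total > 0)
        relpow_s = _interp_to_samples(relpow, times * fs, n)

        # (2) moving RMS of the sigma-filtered signal
        win_r, step_r, starts = _moving_stat_grid(
            n, fs, params.rms_window_s, params.rms_step_s)
        sw = np.lib.stride_tricks.sliding_window_view(sigma, win_r)[::step_r]
        rms = np.sqrt((sw ** 2).mean(axis=1))
        centers = starts + win_r / 2.0
        thr_rms = rms.mean() + params.rms_sd_factor * rms.std()
        rms_s = _interp_to_samples(rms, centers, n)

        # (3) moving broadband/sigma correlation on the same grid
        bw = np.lib.stride_tricks.sliding_window_view(broad, win_r)[::step_r]
        bc = bw - bw.mean(axis=1, keepdims=True)
        sc = sw - sw.mean(axis=1, keepdims=True)
        denom = np.sqrt((bc ** 2).sum(axis=1) * (sc ** 2).sum(axis=1))
        corr = np.divide((bc * sc).sum(axis=1), denom,
                         out=np.zeros(denom.shape), where=denom > 0)
        corr_s = _interp_to_samples(corr, centers, n)

        hit = ((relpow_s > params.rel_power_threshold)
               & (rms_s > thr_rms)
               & (corr_s > params.corr_threshold))
        # contiguous runs -> candidate events
        d = np.diff(hit.astype(int))
        run_starts = np.flatnonzero(d == 1) + 1
        run_ends = np.flatnonzero(d == -1) + 1
        if hit[0]:
            run_starts = np.r_[0, run_starts]
        if hit[-1]:
            run_ends = np.r_[run_ends, n]
        shrink = win_r // 2
        for s, e in zip(run_starts, run_ends):
            # the 300-ms moving-window tracks smear each boundary by half
            # a window; shrink the run accordingly so durations refer to
            # the oscillatory burst itself
            s, e = s + shrink, e - shrink
            if e <= s:
                continue
            dur = (e - s) / fs
            if not (params.spindle_duration[0] <= dur
                    <= params.spindle_duration[1]):
                continue
            seg = sigma[s:e]
            # mean frequency from zero crossings of the sigma-band signal
            zc = np.flatnonzero(np.diff(seg > 0))
            freq = (zc.size / 2.0) / dur if zc.size else np.nan
            events.append(OscEvent(
                kind="spindle", channel=ch, onset=s / fs, offset=e / fs,
                duration=dur, freq=freq,
                amp=float(np.sqrt((seg ** 2).mean()) * np.sqrt(2.0))))
    events.sort(key=lambda e: e.onset)
    return events


def merge_cross_channel(events, merge_window_s=0.5):
    """Collapse same-spindle detections across channels.

    Events (sorted by onset) whose onsets lie within ``merge_window_s``
    of each other are assumed to reflect the same spindle; the relation
    is closed transitively and each group becomes one event spanning the
    earliest onset to the latest offset (channel of the highest-amplitude
    member, amplitude/frequency averaged).
    """
    if not events:
        return []
    events = sorted(events, key=lambda e: e.onset)
    groups = [[events[0]]]
    for ev in events[1:]:
        if ev.onset - groups[-1][-1].onset < merge_window_s:
            groups[-1].append(ev)
        else:
            groups.append([ev])
    def _nanmean(values):
        values = [v for v in values if np.isfinite(v)]
        return float(np.mean(values)) if values else np.nan

    merged = []
    for grp in groups:
        best = max(grp, key=lambda e: (e.amp if np.isfinite(e.amp) else 0.0))
        onset = min(e.onset for e in grp)
        offset = max(e.offset for e in grp)
        merged.append(OscEvent(
            kind=grp[0].kind, channel=best.channel, onset=onset,
            offset=offset, duration=offset - onset,
            freq=_nanmean(e.freq for e in grp),
            amp=_nanmean(e.amp for e in grp),
            trough_time=_nanmean(e.trough_time for e in grp),
            trough_amp=_nanmean(e.trough_amp for e in grp),
            peak_amp=_nanmean(e.peak_amp for e in grp),
            ptp=_nanmean(e.ptp for e in grp),
        ))
    return merged


def event_metrics_by_interval(events, intervals):
    """Per-condition event density, amplitude and frequency.

    ``intervals`` is a DataFrame with ``start_s``, ``end_s`` and
    ``label`` (up / down / not) columns; intervals must not overlap.
    Density is events per minute of labelled time. Returns a DataFrame
    indexed by label with columns ``density_per_min``, ``mean_amp``,
    ``mean_freq``, ``n_events``, ``minutes``. Group statistics across
    subjects are delegated to :func:`clsleep.behavior.rm_anova`.
    """
    out = []
    for label, grp in intervals.groupby("label"):
        minutes = float((grp["end_s"] - grp["start_s"]).sum()) / 60.0
        if minutes <= 0:
            raise ValueError(f"zero total duration for condition {label!r}")
        sel = []
        for ev in events:
            t = ev.trough_time if np.isfinite(ev.trough_time) else ev.onset
            if ((grp["start_s"] <= t) & (t < grp["end_s"])).any():
                sel.append(ev)
        amps = [e.amp if e.kind == "spindle" else e.ptp for e in sel]
        freqs = [e.freq for e in sel]
        out.append({
            "label": label, "density_per_min": len(sel) / minutes,
            "mean_amp": float(np.nanmean(amps)) if sel else 0.0,
            "mean_freq": float(np.nanmean(freqs)) if sel else 0.0,
            "n_events": len(sel), "minutes": minutes,
        })
    return pd.DataFrame(out).set_index("label")
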