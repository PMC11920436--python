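"""Real-time slow-oscillation phase-targeted stimulation simulator.

Reproduces, in software, the behavior of a closed-loop auditory
stimulation device: a causal moving-average prefilter and sex-specific
amplitude thresholds arm the detector on SO down-states, the
endpoint-corrected Hilbert transform (ecHT) provides a causal
instantaneous-phase estimate, and cues are fired when the phase crosses
the condition's target (90° = SO peak for "up" intervals, 270° = trough
for "down" intervals). Stimulation alternates between 3-min up- and
down-intervals separated by 1-min rest, runs only during N2/N3 sleep,
locks out after each cue until the next positive-to-negative zero
crossing, validates every cue online against a causal 0.1-4.5 Hz FIR
trace, and silences a down interval whenever validated down cues
outnumber validated up cues.

Phase convention: 0° at the negative-to-positive zero crossing, 90° at
the peak, 270° at the trough.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal as sps

from clsleep.synth import EEGRecording, NREM_STAGES, EPOCH_S

TWO_PI = 2.0 * np.pi


@dataclass
class StimulationConfig:
    """Parameters of the online detection/stimulation algorithm.

    Thresholds are sex-specific (``sex`` selects which pair applies):
    the down-state is detected when the moving-average-filtered signal
    drops below ``down_threshold_*`` and the up-state additionally
    requires the running peak-to-peak amplitude to reach
    ``ptp_threshold_*``. Online validation uses the fixed
    ``online_valid_trough`` / ``online_valid_ptp`` criteria on a
    0.1-4.5 Hz FIR-filtered trace.
    """

    band: tuple[float, float] = (0.1, 4.5)
    ma_window: int = 50
    down_threshold_f: float = -41.0
    down_threshold_m: float = -39.5
    ptp_threshold_f: float = 77.0
    ptp_threshold_m: float = 74.0
    stim_interval_s: float = 180.0
    rest_min_s: float = 60.0
    online_valid_trough: float = -40.0
    online_valid_ptp: float = 75.0
    fir_order: int = 500
    target_phase_up: float = 90.0
    target_phase_down: float = 270.0
    session_limit_s: float = 3.0 * 3600.0
    sex: str = "F"
    detection_channel: str = "Fpz"
    loop_fs: float = 500.0
    echt_buffer_s: float = 2.0
    echt_filter_order: int = 2
    first_interval: str = "up"
    validation_window_s: float = 2.0
    max_chase_s: float = 2.0            # give up phase chase after this long

    def __post_init__(self):
        if self.sex not in ("F", "M"):
            raise ValueError(f"unknown sex code {self.sex!r}")
        if not self.band[0] < self.band[1]:
            raise ValueError("pass-band low must be < high")
        if self.stim_interval_s <= 0 or self.rest_min_s <= 0:
            raise ValueError("interval durations must be positive")
        for thr in (self.down_threshold_f, self.down_threshold_m,
                    self.online_valid_trough):
            if thr >= 0:
                raise ValueError("trough thresholds must be negative")

    @property
    def down_threshold(self) -> float:
        return self.down_threshold_f if self.sex == "F" else self.down_threshold_m

    @property
    def ptp_threshold(self) -> float:
        return self.ptp_threshold_f if self.sex == "F" else self.ptp_threshold_m


@dataclass
class CueLog:
    """Result of a closed-loop run: delivered cues and interval layout."""

    cues: pd.DataFrame          # onset_s, condition, phase_deg, amp, online_valid, interval_id
    intervals: pd.DataFrame     # interval_id, start_s, end_s, kind, silenced
    header: dict = field(default_factory=dict)
    status: str = "ok"

    @property
    def n_up(self) -> int:
        return int((self.cues["condition"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.cues["condition"] == "down").sum())


def _empty_cues() -> pd.DataFrame:
    return pd.DataFrame({
        "onset_s": pd.Series(dtype=float),
        "condition": pd.Series(dtype=object),
        "phase_deg": pd.Series(dtype=float),
        "amp": pd.Series(dtype=float),
        "online_valid": pd.Series(dtype=bool),
        "interval_id": pd.Series(dtype=int),
    })


# ---------------------------------------------------------------------------
# endpoint-corrected Hilbert transform
# ---------------------------------------------------------------------------

_ECHT_RESP_CACHE: dict = {}


def _echt_filter(band, fs, order):
    key = ("ba", band, fs, order)
    ba = _ECHT_RESP_CACHE.get(key)
    if ba is None:
        ba = sps.butter(order, band, btype="bandpass", fs=fs)
        _ECHT_RESP_CACHE[key] = ba
    return ba


def _echt_response(n, band, fs, order):
    """Frequency response of the causal band-pass at the FFT bin frequencies."""
    key = (n, band, fs, order)
    resp = _ECHT_RESP_CACHE.get(key)
    if resp is None:
        b, a = _echt_filter(band, fs, order)
        freqs = np.fft.fftfreq(n, d=1.0 / fs)
        _, resp = sps.freqz(b, a, worN=TWO_PI * freqs / fs)
        _ECHT_RESP_CACHE[key] = resp
    return resp


def echt_phase(window, band, fs, filter_order=2):
    """Causal instantaneous phase/amplitude at the last sample of ``window``.

    The endpoint-corrected Hilbert transform computes the analytic signal
    of the buffer via the one-sided FFT spectrum and applies a *causal*
    band-pass filter in the frequency domain; because the filter is
    causal its edge distortion (the Gibbs overshoot of the plain Hilbert
    transform) is pushed to the *start* of the buffer, leaving the
    endpoint estimate clean.

    Returns ``(phase_deg, amplitude)`` with 0° at the rising zero
    crossing, 90° at the peak and 270° at the trough.
    """
    x = np.asarray(window, dtype=float)
    if x.ndim != 1 or x.size < 64:
        raise ValueError("window must be 1-D with at least 64 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("window contains NaNs or infs")
    n = x.size
    spec = np.fft.fft(x)
    # one-sided (analytic) spectrum
    h = np.zeros(n)
    h[0] = 1.0
    if n % 2 == 0:
        h[n // 2] = 1.0
        h[1:n // 2] = 2.0
    else:
        h[1:(n + 1) // 2] = 2.0
    spec *= h
    resp = _echt_response(n, tuple(band), float(fs), int(filter_order))
    analytic = np.fft.ifft(spec * resp)
    end = analytic[-1]
    raw_phase = np.angle(end)
    # Compensate the causal filter's steady-state phase response at the
    # endpoint's instantaneous frequency (median phase increment over the
    # last ~100 ms, robust to in-band noise). The compensation is scaled
    # by a convergence weight -- the analytic amplitude one period ago
    # relative to now -- because during an oscillation's onset transient
    # the filter has not yet built up its steady-state lag and the raw
    # endpoint phase is already accurate.
    tail = analytic[-min(int(0.1 * fs) + 1, n):]
    dphi = float(np.median(np.angle(tail[1:] * np.conj(tail[:-1]))))
    f_inst = float(np.clip(dphi * fs / TWO_PI, band[0], band[1]))
    b, a = _echt_filter(tuple(band), float(fs), int(filter_order))
    _, h_inst = sps.freqz(b, a, worN=np.array([TWO_PI * f_inst / fs]))
    lag = int(np.clip(fs / f_inst, 1, n - 1))
    a_now = np.abs(end)
    weight = float(np.clip(np.abs(analytic[-1 - lag]) / a_now, 0.0, 1.0)) \
        if a_now > 0 else 1.0
    phase = (np.degrees(raw_phase - weight * np.angle(h_inst[0])) + 90.0) % 360.0
    return phase, float(a_now)


def oracle_phase(x, band, fs):
    """Non-causal reference phase (deg) of a full trace.

    Zero-phase band-pass + analytic signal; same phase convention as
    :func:`echt_phase`. Used as the offline oracle against which the
    causal estimator is scored.
    """
    taps = sps.firwin(501, band, pass_zero=False, fs=fs)
    xf = sps.filtfilt(taps, 1.0, x)
    analytic = sps.hilbert(xf)
    return (np.degrees(np.angle(analytic)) + 90.0) % 360.0


# ---------------------------------------------------------------------------
# streaming SO candidate detector
# ---------------------------------------------------------------------------

class SOCandidateDetector:
    """Per-sample state machine for online SO down/up detection.

    Feed moving-average-filtered samples through :meth:`update`; it
    returns ``None``, ``"down_detected"`` (first sample below the
    sex-specific trough threshold) or ``"up_detected"`` (the first
    up-state sample -- signal back above zero -- at which the running
    peak-to-peak amplitude since the qualifying trough has reached the
    sex-specific threshold; requiring a positive excursion keeps
    monophasic negative deflections from counting their return to
    baseline as an up-state). ``reset`` arms the detector for the next
    SO (the caller applies the zero-crossing lockout).
    """

    def __init__(self, config: StimulationConfig):
        self.cfg = config
        self.reset()

    def reset(self):
        self._below = False
        self._trough = np.inf
        self._up_fired = False
        self._down_fired = False

    def update(self, sample: float):
        cfg = self.cfg
        event = None
        if not self._below:
            if sample < cfg.down_threshold:
                self._below = True
                self._trough = sample
                if not self._down_fired:
                    self._down_fired = True
                    event = "down_detected"
        else:
            self._trough = min(self._trough, sample)
            if (not self._up_fired and sample > 0.0
                    and sample - self._trough >= cfg.ptp_threshold):
                self._up_fired = True
                event = "up_detected"
        return event


# ---------------------------------------------------------------------------
# online validation
# ---------------------------------------------------------------------------

def causal_fir_trace(x, config: StimulationConfig, fs):
    """0.1-4.5 Hz linear-phase FIR (causal), delay-compensated.

    Returns the filtered trace aligned with ``x``; the trailing
    ``fir_order/2`` samples are NaN because the causal filter has not yet
    produced them (cues that fall in that edge region are flagged
    indeterminate).
    """
    order = config.fir_order
    taps = sps.firwin(order + 1, config.band, pass_zero=False, fs=fs)
    y = sps.lfilter(taps, 1.0, x)
    delay = order // 2
    out = np.full_like(x, np.nan, dtype=float)
    out[:x.size - delay] = y[delay:]
    out[:delay] = np.nan          # start-up transient
    return out


def _cycle_bounds(xf, idx):
    """Bounds of the SO cycle containing sample ``idx``.

    A cycle runs between consecutive positive-to-negative zero crossings
    (trough first, then peak). Returns (start, end) sample indices or
    None when the cycle is not fully contained in the finite part of
    ``xf``.
    """
    sign = xf > 0
    p2n = np.flatnonzero(sign[:-1] & ~sign[1:]) + 1   # first sample <= 0
    if p2n.size == 0:
        return None
    starts = p2n[p2n <= idx]
    ends = p2n[p2n > idx]
    if starts.size == 0 or ends.size == 0:
        return None
    return int(starts[-1]), int(ends[-1])


def online_validate(cue_time, filtered, fs, config: StimulationConfig):
    """Does the cue fall within an SO meeting the online validity criteria?

    ``filtered`` is the delay-compensated causal FIR trace of the
    detection channel. The SO cycle containing the cue (bounded by
    positive-to-negative zero crossings) is searched within
    ``validation_window_s`` around the cue for a trough <=
    ``online_valid_trough`` followed by a peak giving PTP >=
    ``online_valid_ptp``. Cues whose cycle extends into the filter's
    edge-transient (NaN) region are indeterminate and counted invalid.
    """
    idx = int(round(cue_time * fs))
    if idx < 0 or idx >= filtered.size:
        raise ValueError("cue outside recording bounds")
    half = int(round(config.validation_window_s * fs))
    lo, hi = max(idx - half, 0), min(idx + half + 1, filtered.size)
    seg = filtered[lo:hi]
    if not np.all(np.isfinite(seg)):
        return False          # indeterminate: edge transient
    bounds = _cycle_bounds(seg, idx - lo)
    if bounds is None:
        return False
    s, e = bounds
    cyc = seg[s:e + 1]
    tr = int(np.argmin(cyc))
    trough = cyc[tr]
    if trough > config.online_valid_trough:
        return False
    peak = cyc[tr:].max()
    return bool(peak - trough >= config.online_valid_ptp)


def balance_conditions(counters, upcoming_kind):
    """Decide whether the upcoming interval runs or is silenced.

    ``counters`` maps condition -> running count of online-validated
    cues. A *down* interval is silenced iff validated down cues
    outnumber validated up cues at decision time; up intervals always
    run.
    """
    if upcoming_kind == "down" and counters.get("down", 0) > counters.get("up", 0):
        return "silence"
    return "run"


def cue_rate_in_band(cue_log, band=(0.1, 4.5), n_boot=1000, seed=0):
    """Fraction of cues whose instantaneous rate lies in the SO band.

    The instantaneous rate of cue *i* (i >= 1) is ``1 / (t_i -
    t_{i-1})``; band edges are inclusive. Returns ``(fraction, (lo, hi))``
    with a bootstrap 95% CI over the inter-cue intervals.
    """
    times = cue_log.cues["onset_s"].to_numpy() if isinstance(cue_log, CueLog) \
        else np.asarray(cue_log, dtype=float)
    if times.size < 2:
        raise ValueError("need at least 2 cues")
    rates = 1.0 / np.diff(np.sort(times))
    inb = (rates >= band[0]) & (rates <= band[1])
    frac = inb.mean()
    rng = np.random.default_rng(seed)
    boots = rng.choice(inb.astype(float), size=(n_boot, inb.size),
                       replace=True).mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return float(frac), (float(lo), float(hi))


# ---------------------------------------------------------------------------
# the closed loop
# ---------------------------------------------------------------------------

def _resample_to_loop_fs(x, fs, loop_fs):
    """Causal anti-aliased integer-factor decimation."""
    if fs == loop_fs:
        return x
    ratio = fs / loop_fs
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("recording fs must be an integer multiple of loop_fs")
    q = int(round(ratio))
    taps = sps.firwin(63, 0.8 * loop_fs / 2.0, fs=fs)
    y = sps.lfilter(taps, 1.0, x)     # causal: truncation-safe prefixes
    return y[::q]


def _signed_phase_dist(phase, target):
    return (phase - target + 180.0) % 360.0 - 180.0


def run_closed_loop(recording: EEGRecording, config: StimulationConfig = None,
                    seed: int = 0) -> CueLog:
    """Simulate a full stimulation night on ``recording``.

    The detection channel is moving-average filtered (causally); 3-min
    up/down intervals alternate, separated by 1-min rest, starting at
    the first N2/N3 epoch. Within an interval the detector arms on the
    sex-specific threshold crossings and the cue fires when the ecHT
    phase crosses the condition's target phase. Cues are only delivered
    while the hypnogram is in N2/N3; after every cue the loop is locked
    out until the next positive-to-negative zero crossing; the session
    ends ``session_limit_s`` after the first cue. Every cue is scored
    online and validated-cue counters drive down-interval silencing.
    """
    if config is None:
        config = StimulationConfig()
    fs = config.loop_fs
    raw = recording.get_channel(config.detection_channel)
    x = _resample_to_loop_fs(raw, recording.fs, fs)
    n = x.size

    header = {"seed": seed, "config": asdict(config)}
    intervals_rows = []
    cue_rows = []

    # N2/N3 per-sample gate
    spe = int(round(EPOCH_S * fs))
    gate = np.zeros(n, dtype=bool)
    for i, st in enumerate(recording.hypnogram):
        if st in NREM_STAGES:
            gate[i * spe:min((i + 1) * spe, n)] = True
    if not gate.any():
        warnings.warn("no N2/N3 epochs in hypnogram; no stimulation possible")
        return CueLog(_empty_cues(), pd.DataFrame(
            columns=["interval_id", "start_s", "end_s", "kind", "silenced"]),
            header, status="warning: no NREM sleep")

    # causal moving-average prefilter
    ma = sps.lfilter(np.ones(config.ma_window) / config.ma_window, 1.0, x)
    # positive-to-negative zero crossings of the prefiltered trace
    pos = ma > 0
    p2n = np.flatnonzero(pos[:-1] & ~pos[1:]) + 1
    # down-threshold crossings (first sample below threshold)
    below = ma < config.down_threshold
    down_cross = np.flatnonzero(~below[:-1] & below[1:]) + 1
    # causal FIR trace for online validation
    fir = causal_fir_trace(x, config, fs)

    buf_n = int(round(config.echt_buffer_s * fs))
    max_chase = int(round(config.max_chase_s * fs))

    def phase_at(i):
        if i + 1 < buf_n:
            return None
        return echt_phase(x[i + 1 - buf_n:i + 1], config.band, fs,
                          config.echt_filter_order)

    def next_p2n(i):
        j = np.searchsorted(p2n, i, side="right")
        return int(p2n[j]) if j < p2n.size else n

    counters = {"up": 0, "down": 0}
    pending = []                      # cues awaiting validation
    t_first_cue = None
    interval_id = -1
    kind = config.first_interval
    start_idx = int(np.argmax(gate))  # first NREM sample
    i = start_idx
    session_end = n

    while i < n and i < session_end:
        interval_id += 1
        iv_start = i
        iv_end = min(i + int(config.stim_interval_s * fs), n)
        # balancing decision at interval start, on validated counts so far
        _settle_validations(pending, counters, iv_start / fs, fir, fs, config,
                            cue_rows)
        silenced = (balance_conditions(counters, kind) == "silence")
        intervals_rows.append({
            "interval_id": interval_id, "start_s": iv_start / fs,
            "end_s": iv_end / fs, "kind": kind, "silenced": silenced})
        if not silenced:
            target = (config.target_phase_up if kind == "up"
                      else config.target_phase_down)
            j = iv_start
            while True:
                k = np.searchsorted(down_cross, j)
                if k >= down_cross.size or down_cross[k] >= iv_end:
                    break
                arm = int(down_cross[k])
                if arm >= session_end:
                    break
                abort = min(next_p2n(arm), iv_end, n, session_end)
                fire_at = None
                if kind == "up":
                    # additionally require PTP threshold since the trough
                    trough = ma[arm]
                    armed_up = False
                    for m in range(arm, abort):
                        trough = min(trough, ma[m])
                        if (not armed_up and ma[m] > 0.0
                                and ma[m] - trough >= config.ptp_threshold):
                            armed_up = True
                            fire_at = _chase_phase(
                                phase_at, m, min(abort, m + max_chase), target)
                            break
                else:
                    fire_at = _chase_phase(
                        phase_at, arm, min(abort, arm + max_chase), target)
                if fire_at is not None and gate[fire_at]:
                    ph = phase_at(fire_at)
                    cue_rows.append({
                        "onset_s": fire_at / fs, "condition": kind,
                        "phase_deg": ph[0] if ph else np.nan,
                        "amp": ph[1] if ph else np.nan,
                        "online_valid": False, "interval_id": interval_id})
                    pending.append(len(cue_rows) - 1)
                    if t_first_cue is None:
                        t_first_cue = fire_at / fs
                        session_end = min(
                            n, fire_at + int(config.session_limit_s * fs))
                    j = next_p2n(fire_at)       # lockout
                else:
                    j = abort if abort > arm else arm + 1
        i = iv_end + int(config.rest_min_s * fs)
        kind = "down" if kind == "up" else "up"

    _settle_validations(pending, counters, np.inf, fir, fs, config, cue_rows)
    cues = pd.DataFrame(cue_rows) if cue_rows else _empty_cues()
    intervals = pd.DataFrame(intervals_rows)
    status = "ok" if len(cues) else "warning: no cues delivered"
    return CueLog(cues, intervals, header, status)


def _chase_phase(phase_at, start, stop, target):
    """First sample in [start, stop) where the ecHT phase crosses ``target``.

    If the phase already sits just past the target when the chase starts
    (possible under noise and the moving-average prefilter delay), the
    cue fires immediately rather than waiting a full cycle.
    """
    prev = None
    for m in range(start, stop):
        res = phase_at(m)
        if res is None:
            return None
        d = _signed_phase_dist(res[0], target)
        if prev is None and 0.0 <= d < 45.0:
            # already (just) past the target when armed -- deliver now
            # rather than skipping the oscillation
            return m
        if prev is not None and prev < 0.0 <= d and abs(prev) < 90.0:
            return m
        prev = d
    return None


def _settle_validations(pending, counters, now_s, fir, fs, config, cue_rows):
    """Validate pending cues whose ±window is fully in the past."""
    done = []
    for idx in pending:
        row = cue_rows[idx]
        if row["onset_s"] + config.validation_window_s + 0.6 <= now_s:
            ok = online_validate(row["onset_s"], fir, fs, config)
            row["online_valid"] = bool(ok)
            if ok:
                counters[row["condition"]] += 1
            done.append(idx)
    for idx in done:
        pending.remove(idx)
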