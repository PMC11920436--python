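"""Post-hoc cue scoring: true-positive classification, phase accuracy,
circular statistics and sham-cue construction.

Offline validation can use the whole recording, so the phase reference
here is the non-causal one: zero-phase 0.1-4.5 Hz band-pass + analytic
signal (0° rising zero crossing, 90° peak, 270° trough). A cue counts as
*accurate* when it was delivered within a true SO (sex-specific trough
and peak-to-peak criteria) inside the 180° half-plane centered on its
condition's target phase: up gets [0°, 180°] and down gets (180°, 360°)
-- the half-plane boundaries are assigned to the up window by default
and this is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from clsleep.closed_loop import StimulationConfig, oracle_phase, _cycle_bounds
from clsleep.synth import EEGRecording


@dataclass
class CueAccuracyRecord:
    time_s: float
    condition: str
    true_so: bool
    phase_deg: float
    accurate: bool
    trough_uv: float
    ptp_uv: float


_SEX_THRESHOLDS = {"F": (-41.0, 77.0), "M": (-39.5, 74.0)}


def _filtered_and_phase(x, fs, band=(0.1, 4.5)):
    taps = sps.firwin(501, band, pass_zero=False, fs=fs)
    xf = sps.filtfilt(taps, 1.0, x)
    phase = (np.degrees(np.angle(sps.hilbert(xf))) + 90.0) % 360.0
    return xf, phase


def _so_at(xf, idx, fs, window_s=2.0):
    """Trough and PTP of the SO cycle containing sample ``idx``."""
    half = int(round(window_s * fs))
    lo = max(idx - half, 0)
    hi = min(idx + half + 1, xf.size)
    seg = xf[lo:hi]
    bounds = _cycle_bounds(seg, idx - lo)
    if bounds is None:
        return np.nan, np.nan
    s, e = bounds
    cyc = seg[s:e + 1]
    tr = int(np.argmin(cyc))
    trough = float(cyc[tr])
    ptp = float(cyc[tr:].max() - trough)
    return trough, ptp


def in_phase_window(phase_deg, condition, boundary_to_up=True):
    """Is ``phase_deg`` inside the condition's 180° accuracy window?"""
    p = phase_deg % 360.0
    if condition == "up":
        return (0.0 <= p <= 180.0) if boundary_to_up else (0.0 < p < 180.0)
    if condition == "down":
        return (180.0 < p < 360.0) if boundary_to_up else (180.0 <= p < 360.0)
    raise ValueError(f"unknown condition {condition!r}")


def classify_cue_accuracy(cues, recording: EEGRecording, sex="F",
                          channel="Fpz", boundary_to_up=True):
    """Score every delivered cue against the offline phase/amplitude oracle.

    ``cues`` is a DataFrame with ``onset_s`` and ``condition`` columns
    (e.g. ``CueLog.cues``). Returns ``(records, accuracy_pct)`` where
    ``records`` is a DataFrame of :class:`CueAccuracyRecord` fields and
    ``accuracy_pct`` the percentage of accurate cues. Idempotent and
    order-independent.
    """
    if sex not in _SEX_THRESHOLDS:
        raise ValueError(f"unknown sex code {sex!r}")
    trough_thr, ptp_thr = _SEX_THRESHOLDS[sex]
    fs = recording.fs
    x = recording.get_channel(channel)
    xf, phase = _filtered_and_phase(x, fs)
    rows = []
    for _, cue in cues.iterrows():
        idx = int(round(cue["onset_s"] * fs))
        if idx < 0 or idx >= x.size:
            raise ValueError("cue outside recording bounds")
        trough, ptp = _so_at(xf, idx, fs)
        true_so = bool(np.isfinite(trough) and trough <= trough_thr
                       and ptp >= ptp_thr)
        ph = float(phase[idx])
        acc = true_so and in_phase_window(ph, cue["condition"], boundary_to_up)
        rows.append({
            "time_s": float(cue["onset_s"]), "condition": cue["condition"],
            "true_so": true_so, "phase_deg": ph, "accurate": bool(acc),
            "trough_uv": trough, "ptp_uv": ptp,
        })
    records = pd.DataFrame(rows)
    accuracy = 100.0 * records["accurate"].mean() if len(records) else np.nan
    return records, float(accuracy)


def circular_summary(phases_deg, ci=0.95):
    """Mean direction, resultant length and CI of a circular sample.

    Returns a dict with ``mean_deg`` (argument of the mean unit vector),
    ``r`` (resultant length in [0, 1]), ``ci_deg`` (half-width of the
    large-sample confidence interval, Fisher's dispersion-based circular
    standard error) and ``n``. For (near-)uniform samples (r ~ 0) the
    mean direction is undefined and ``mean_deg``/``ci_deg`` are NaN with
    ``defined=False``.
    """
    ph = np.radians(np.asarray(phases_deg, dtype=float))
    if ph.size == 0:
        raise ValueError("empty phase sample")
    z = np.exp(1j * ph).mean()
    r = float(np.abs(z))
    n = ph.size
    if r < 1e-9:
        return {"mean_deg": np.nan, "r": r, "ci_deg": np.nan, "n": n,
                "defined": False}
    mean = float(np.degrees(np.angle(z)) % 360.0)
    # Fisher (1993) large-sample circular SE
    alpha2 = float(np.mean(np.cos(2.0 * (ph - np.angle(z)))))
    se2 = (1.0 - alpha2) / (2.0 * n * r * r)
    from scipy.stats import norm
    zcrit = norm.ppf(0.5 + ci / 2.0)
    arg = zcrit * np.sqrt(max(se2, 0.0))
    ci_deg = float(np.degrees(np.arcsin(min(arg, 1.0)))) if n > 1 else np.nan
    return {"mean_deg": mean, "r": r, "ci_deg": ci_deg, "n": n,
            "defined": True}


def assign_sham_cues(not_stimulated_sos, up_phases, down_phases,
                     recording: EEGRecording, channel="Fpz", seed=0):
    """Give every non-stimulated SO one up-sham and one down-sham time.

    For each SO (events with a ``trough time``, e.g. from
    :func:`clsleep.events.detect_slow_oscillations` restricted to rest
    intervals), a phase is drawn with replacement from the corresponding
    list of true-positive cue phases and converted to a time sample on
    that SO by linear interpolation of the SO's own (unwrapped) analytic
    phase. Returns a DataFrame with columns ``so_trough_s``,
    ``up_sham_s``, ``up_phase_deg``, ``down_sham_s``, ``down_phase_deg``.
    """
    up_phases = np.asarray(up_phases, dtype=float)
    down_phases = np.asarray(down_phases, dtype=float)
    if up_phases.size == 0 or down_phases.size == 0:
        raise ValueError("need at least one true-positive phase per condition")
    rng = np.random.default_rng(seed)
    fs = recording.fs
    x = recording.get_channel(channel)
    phase = oracle_phase(x, (0.1, 4.5), fs)
    # unwrap once for monotone interpolation inside each SO cycle
    unwrapped = np.degrees(np.unwrap(np.radians(phase)))
    rows = []
    for ev in not_stimulated_sos:
        t_tr = getattr(ev, "trough_time", None)
        if t_tr is None:
            t_tr = float(ev)
        idx = int(round(t_tr * fs))
        half = int(round(1.5 * fs))
        lo, hi = max(idx - half, 0), min(idx + half, x.size)
        seg = unwrapped[lo:hi]
        base = unwrapped[idx]
        row = {"so_trough_s": float(t_tr)}
        for cond, pool in (("up", up_phases), ("down", down_phases)):
            target = float(rng.choice(pool))
            # the SO's cycle spans one full turn of unwrapped phase
            # starting a quarter cycle before the trough's phase value;
            # pick the target's unique branch within that turn so the
            # sham lands at exactly the drawn phase on this SO
            want = (base - 90.0) + (target - (base - 90.0)) % 360.0
            t_sham = _interp_phase_time(seg, want, lo, fs)
            row[f"{cond}_sham_s"] = t_sham
            row[f"{cond}_phase_deg"] = target
        rows.append(row)
    return pd.DataFrame(rows)


def _interp_phase_time(unwrapped_seg, want, offset, fs):
    """Time at which the unwrapped phase first equals ``want`` in the segment."""
    d = unwrapped_seg - want
    sign = d > 0
    crossings = np.flatnonzero(sign[:-1] != sign[1:])
    if crossings.size == 0:
        return np.nan
    # crossing nearest the segment center
    c = crossings[np.argmin(np.abs(crossings - unwrapped_seg.size / 2))]
    frac = -d[c] / (d[c + 1] - d[c]) if d[c + 1] != d[c] else 0.0
    return (offset + c + frac) / fs
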