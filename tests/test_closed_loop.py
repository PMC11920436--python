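import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from clsleep import (
    StimulationConfig,
    echt_phase,
    SOCandidateDetector,
    run_closed_loop,
    online_validate,
    balance_conditions,
    cue_rate_in_band,
    generate_sleep_eeg,
    generate_hypnogram,
)
from clsleep.closed_loop import causal_fir_trace, oracle_phase
from clsleep.synth import EEGRecording, so_waveform

FS = 500.0
BAND = (0.1, 4.5)


def circ_mean_deg(deg):
    return np.degrees(np.angle(np.exp(1j * np.radians(np.asarray(deg))).mean())) % 360.0


def circ_err(a, b):
    return (np.asarray(a) - np.asarray(b) + 180.0) % 360.0 - 180.0


class TestEchtPhase:
    def test_pure_tone_peak_and_trough(self):
        t = np.arange(0, 12, 1 / FS)
        x = 100 * np.sin(2 * np.pi * 1.0 * t)
        i_peak = int(5.25 * FS)        # sin peaks at 0.25 + k
        ph, amp = echt_phase(x[i_peak - 1000:i_peak], BAND, FS)
        assert abs(circ_err(ph, 90.0)) < 5.0
        assert amp == pytest.approx(100.0, rel=0.05)
        i_tr = int(5.75 * FS)
        ph, _ = echt_phase(x[i_tr - 1000:i_tr], BAND, FS)
        assert abs(circ_err(ph, 270.0)) < 5.0

    def test_noisy_tone_rms_error_vs_clean_oracle(self):
        """Circular RMS error against the non-causal phase of the clean
        component stays below 20 degrees at SNR 10."""
        rng = np.random.default_rng(1)
        t = np.arange(0, 60, 1 / FS)
        clean = 60 * np.sin(2 * np.pi * 1.0 * t)
        noise_sd = (60 / np.sqrt(2)) / np.sqrt(10.0)
        noisy = clean + noise_sd * rng.standard_normal(t.size)
        oracle = oracle_phase(clean, BAND, FS)
        errs = []
        for i in range(2000, t.size, 177):
            ph, _ = echt_phase(noisy[i - 1000:i + 1], BAND, FS)
            errs.append(circ_err(ph, oracle[i]))
        assert np.sqrt(np.mean(np.square(errs))) < 20.0

    def test_clean_so_train_tracking(self):
        """On trains of symmetric SO cycles the causal estimate matches
        the oracle to better than 10 degrees on average."""
        wave, toff = so_waveform(FS, -80.0, 160.0, 1.0)
        n = int(120 * FS)
        x = np.zeros(n)
        for start in range(10, 110, 10):
            s = int(start * FS) - toff
            for k in range(5):
                x[s + k * wave.size:s + (k + 1) * wave.size] += wave
        oracle = oracle_phase(x, BAND, FS)
        errs = []
        for start in range(10, 110, 10):
            for k in range(1, 5):
                i = int((start + k + 0.5) * FS)    # near each cycle peak
                ph, _ = echt_phase(x[i + 1 - 1000:i + 1], BAND, FS)
                errs.append(circ_err(ph, oracle[i]))
        assert abs(np.mean(errs)) < 10.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            echt_phase(np.zeros(32), BAND, FS)
        bad = np.zeros(128)
        bad[5] = np.nan
        with pytest.raises(ValueError):
            echt_phase(bad, BAND, FS)


class TestCandidateDetector:
    def test_flat_signal_never_fires(self):
        det = SOCandidateDetector(StimulationConfig())
        assert all(det.update(0.0) is None for _ in range(5000))

    def test_down_then_up_detection_matches_offline_scan(self):
        """State machine events coincide with an offline scan of the
        same filtered trace."""
        cfg = StimulationConfig(sex="F")
        wave, toff = so_waveform(FS, -90.0, 150.0, 1.0)
        x = np.zeros(int(10 * FS))
        s = int(5 * FS) - toff
        x[s:s + wave.size] += wave
        ma = sps.lfilter(np.ones(cfg.ma_window) / cfg.ma_window, 1.0, x)
        det = SOCandidateDetector(cfg)
        events = {}
        for i, v in enumerate(ma):
            ev = det.update(v)
            if ev:
                events[ev] = i
        # offline oracle: first sample below threshold; first positive
        # (up-state) sample where the running PTP since the trough has
        # reached the threshold
        below = np.flatnonzero(ma < cfg.down_threshold)
        assert events["down_detected"] == below[0]
        run_min = np.minimum.accumulate(ma)
        ptp_hit = np.flatnonzero(((ma - run_min) >= cfg.ptp_threshold)
                                 & (ma > 0))
        ptp_hit = ptp_hit[ptp_hit > below[0]]
        assert events["up_detected"] == ptp_hit[0]

    def test_low_ptp_wave_gives_down_only(self):
        cfg = StimulationConfig(sex="F")
        wave, toff = so_waveform(FS, -90.0, 50.0, 1.0)   # PTP 50 < 77
        x = np.zeros(int(10 * FS))
        x[int(5 * FS) - toff:int(5 * FS) - toff + wave.size] += wave
        ma = sps.lfilter(np.ones(cfg.ma_window) / cfg.ma_window, 1.0, x)
        det = SOCandidateDetector(cfg)
        events = [det.update(v) for v in ma]
        assert "down_detected" in events and "up_detected" not in events

    def test_unknown_sex_rejected(self):
        with pytest.raises(ValueError):
            StimulationConfig(sex="X")


class TestOnlineValidation:
    def _trace(self, trough, ptp):
        cfg = StimulationConfig()
        wave, toff = so_waveform(FS, trough, ptp, 1.0)
        x = np.zeros(int(20 * FS))
        t_tr = int(10 * FS)
        x[t_tr - toff:t_tr - toff + wave.size] += wave
        return causal_fir_trace(x, cfg, FS), cfg

    def test_boundary_trough_rejected(self):
        filtered, cfg = self._trace(-39.0, 120.0)
        assert online_validate(10.0, filtered, FS, cfg) is False

    def test_clear_so_accepted(self):
        filtered, cfg = self._trace(-80.0, 120.0)
        assert online_validate(10.0, filtered, FS, cfg) is True

    def test_cue_in_edge_transient_counted_invalid(self):
        filtered, cfg = self._trace(-80.0, 120.0)
        assert online_validate(19.9, filtered, FS, cfg) is False

    def test_cue_outside_recording_raises(self):
        filtered, cfg = self._trace(-80.0, 120.0)
        with pytest.raises(ValueError):
            online_validate(25.0, filtered, FS, cfg)


class TestBalancing:
    @pytest.mark.parametrize("up,down,kind,expected", [
        (10, 12, "down", "silence"),
        (12, 10, "down", "run"),
        (10, 10, "down", "run"),
        (0, 5, "up", "run"),
    ])
    def test_rule(self, up, down, kind, expected):
        assert balance_conditions({"up": up, "down": down}, kind) == expected

    def test_silenced_interval_creates_five_minute_gap(self, night_sim):
        """rest + silenced down interval + rest = 5 min without cues."""
        cfg = StimulationConfig()
        span = 2 * cfg.rest_min_s + cfg.stim_interval_s
        assert span == pytest.approx(300.0)


class TestCueRate:
    def test_one_hz_spacing_in_band(self):
        frac, _ = cue_rate_in_band(np.arange(0, 20, 1.0))
        assert frac == 1.0

    def test_band_edge_inclusive(self):
        frac, _ = cue_rate_in_band(np.arange(0, 100, 10.0))   # 0.1 Hz edge
        assert frac == 1.0

    def test_mixed_spacing_matches_hand_count(self):
        times = np.array([0.0, 0.5, 1.0, 16.0, 16.3, 46.3])
        # rates: 2, 2, 1/15, 10/3, 1/30 -> in band: 2, 2, no, 3.33, no
        frac, (lo, hi) = cue_rate_in_band(times)
        assert frac == pytest.approx(3 / 5)
        assert 0.0 <= lo <= frac <= hi <= 1.0

    def test_too_few_cues_rejected(self):
        with pytest.raises(ValueError):
            cue_rate_in_band(np.array([1.0]))


class TestClosedLoopRun:
    def test_no_sos_means_no_cues(self):
        rec, _ = generate_sleep_eeg(400.0, fs=FS, channels=("Fpz",),
                                    so_rate=0.0, spindle_rate=0.0,
                                    noise_sd=5.0, seed=2)
        log = run_closed_loop(rec, StimulationConfig(), seed=0)
        assert len(log.intervals) > 0 and len(log.cues) == 0

    def test_no_nrem_yields_warning_and_empty_log(self):
        rec, _ = generate_sleep_eeg(
            300.0, fs=FS, channels=("Fpz",), seed=2,
            hypnogram=generate_hypnogram(300.0, [("REM", 300.0)]))
        with pytest.warns(UserWarning):
            log = run_closed_loop(rec, StimulationConfig(), seed=0)
        assert len(log.cues) == 0 and "no NREM" in log.status

    def test_lockout_one_cue_per_zero_crossing_segment(self, night_sim):
        rec, _, log = night_sim
        cfg = StimulationConfig()
        x = rec.get_channel("Fpz")
        ma = sps.lfilter(np.ones(cfg.ma_window) / cfg.ma_window, 1.0, x)
        pos = ma > 0
        p2n = np.flatnonzero(pos[:-1] & ~pos[1:]) + 1
        seg = np.searchsorted(p2n, (log.cues["onset_s"] * FS).astype(int))
        assert np.all(np.bincount(seg) <= 1)

    def test_gate_no_cue_outside_nrem(self):
        plan = [("N2", 600.0), ("REM", 600.0)] * 3
        rec, _ = generate_sleep_eeg(
            3600.0, fs=FS, channels=("Fpz",), so_rate=3.4,
            placement="regular", seed=7,
            hypnogram=generate_hypnogram(3600.0, plan))
        log = run_closed_loop(rec, StimulationConfig(), seed=0)
        assert len(log.cues) > 0
        stages = {rec.stage_at(t) for t in log.cues["onset_s"]}
        assert stages <= {"N2", "N3"}

    def test_balancing_bound(self, night_sim):
        """|validated up - validated down| never exceeds the largest
        single-interval cue count."""
        _, _, log = night_sim
        valid = log.cues[log.cues["online_valid"]]
        diff = abs((valid["condition"] == "up").sum()
                   - (valid["condition"] == "down").sum())
        assert diff <= log.cues.groupby("interval_id").size().max()

    def test_cue_conditions_match_their_interval(self, night_sim):
        _, _, log = night_sim
        kinds = log.intervals.set_index("interval_id")["kind"]
        assert (log.cues["condition"].to_numpy()
                == kinds.loc[log.cues["interval_id"]].to_numpy()).all()

    def test_interval_schedule_alternates(self, night_sim):
        _, _, log = night_sim
        kinds = log.intervals["kind"].tolist()
        assert all(a != b for a, b in zip(kinds[:-1], kinds[1:]))

    def test_causality_truncated_run_reproduces_prefix(self):
        rec, _ = generate_sleep_eeg(1800.0, fs=FS, channels=("Fpz",),
                                    so_rate=3.4, placement="regular", seed=9)
        cfg = StimulationConfig()
        full = run_closed_loop(rec, cfg, seed=0)
        cut_s = 1200.0
        rec2 = EEGRecording(rec.signal[:, :int(cut_s * FS)], rec.fs,
                            rec.channels, rec.hypnogram[:40])
        part = run_closed_loop(rec2, cfg, seed=0)
        margin = cut_s - cfg.rest_min_s - 5.0
        cols = ["onset_s", "condition", "phase_deg"]
        a = full.cues[full.cues["onset_s"] < margin][cols].reset_index(drop=True)
        b = part.cues[part.cues["onset_s"] < margin][cols].reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_session_ends_three_hours_after_first_cue(self, night_sim):
        _, _, log = night_sim
        first = log.cues["onset_s"].min()
        assert log.cues["onset_s"].max() <= first + StimulationConfig().session_limit_s
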