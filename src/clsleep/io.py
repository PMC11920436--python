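"""Readers and writers for the package's on-disk formats.

Plain-text sidecars: hypnograms as TSV (one 30-s-epoch stage per row),
cue logs and detected events as TSV, behavior as CSV, generator configs
as JSON with an explicit ``seed``. Recordings are stored in HDF5 with
explicit axis metadata; EDF recordings can be read through MNE when it
is installed. Cue sounds are written as WAV.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from clsleep.synth import EEGRecording
from clsleep.closed_loop import CueLog, StimulationConfig


def write_hypnogram_tsv(path, hypnogram):
    df = pd.DataFrame({"epoch": np.arange(len(hypnogram)),
                       "onset_s": 30.0 * np.arange(len(hypnogram)),
                       "stage": list(hypnogram)})
    df.to_csv(path, sep="\t", index=False)


def read_hypnogram_tsv(path):
    df = pd.read_csv(path, sep="\t")
    return tuple(df["stage"].astype(str))


def write_cues_tsv(path, cue_log: CueLog):
    cols = ["onset_s", "condition", "phase_deg", "online_valid", "interval_id"]
    cue_log.cues[cols].to_csv(path, sep="\t", index=False)


def read_cues_tsv(path):
    return pd.read_csv(path, sep="\t")


def write_events_tsv(path, events):
    rows = [{
        "kind": e.kind, "channel": e.channel, "onset_s": e.onset,
        "offset_s": e.offset, "trough_uV": e.trough_amp, "ptp_uV": e.ptp,
        "freq_hz": e.freq, "amp_uV": e.amp,
    } for e in events]
    pd.DataFrame(rows, columns=["kind", "channel", "onset_s", "offset_s",
                                "trough_uV", "ptp_uV", "freq_hz", "amp_uV"]
                 ).to_csv(path, sep="\t", index=False)


def write_ground_truth_tsv(path, truth):
    """BIDS-style events TSV (onset, duration, trial_type) of planted events."""
    rows = [{"onset": so.trough_time, "duration": 1.0 / so.freq,
             "trial_type": "so", "amp": so.trough_amp, "ptp": so.ptp,
             "freq": so.freq} for so in truth.so_events]
    rows += [{"onset": sp.onset, "duration": sp.duration,
              "trial_type": "spindle", "amp": sp.amp, "ptp": np.nan,
              "freq": sp.freq} for sp in truth.spindle_events]
    pd.DataFrame(rows, columns=["onset", "duration", "trial_type", "amp",
                                "ptp", "freq"]).to_csv(path, sep="\t",
                                                       index=False)


def save_recording_h5(path, recording: EEGRecording):
    with h5py.File(path, "w") as f:
        d = f.create_dataset("signal", data=recording.signal)
        d.attrs["units"] = "uV"
        f.attrs["fs"] = recording.fs
        f.attrs["start_time"] = recording.start_time
        f.create_dataset("channels", data=np.array(recording.channels, dtype="S"))
        f.create_dataset("hypnogram", data=np.array(recording.hypnogram, dtype="S"))


def load_recording_h5(path):
    with h5py.File(path, "r") as f:
        return EEGRecording(
            signal=f["signal"][()],
            fs=float(f.attrs["fs"]),
            channels=tuple(s.decode() for s in f["channels"][()]),
            hypnogram=tuple(s.decode() for s in f["hypnogram"][()]),
            start_time=float(f.attrs.get("start_time", 0.0)),
        )


def read_edf(path, hypnogram=None):
    """Load an EDF recording (requires MNE) into an :class:`EEGRecording`."""
    try:
        import mne
    except ImportError as err:
        raise ImportError("reading EDF requires the 'mne' package") from err
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    sig = raw.get_data() * 1e6          # volts -> µV
    fs = float(raw.info["sfreq"])
    if hypnogram is None:
        n_epochs = int(np.ceil(sig.shape[1] / fs / 30.0))
        hypnogram = ("N3",) * n_epochs
    return EEGRecording(sig, fs, tuple(raw.ch_names), tuple(hypnogram))


def write_wav(path, waveform, fs_audio):
    from scipy.io import wavfile
    x = np.clip(waveform, -1.0, 1.0)
    wavfile.write(path, int(fs_audio), (x * 32767).astype(np.int16))


def load_stimulation_config(path):
    """StimulationConfig from a JSON file mirroring its field names."""
    with open(path) as f:
        cfg = json.load(f)
    return StimulationConfig(**cfg)


def save_tfr_h5(path, tfr):
    with h5py.File(path, "w") as f:
        f.create_dataset("power", data=tfr.power)
        f.create_dataset("freqs", data=tfr.freqs)
        f.create_dataset("times", data=tfr.times)
        f.create_dataset("channels", data=np.array(tfr.channels, dtype="S"))
        f.attrs["baseline_mode"] = tfr.baseline_mode
        f.attrs["condition"] = tfr.condition


def load_tfr_h5(path):
    from clsleep.erp_tfr import TFRArray
    with h5py.File(path, "r") as f:
        return TFRArray(
            power=f["power"][()], freqs=f["freqs"][()], times=f["times"][()],
            channels=tuple(s.decode() for s in f["channels"][()]),
            baseline_mode=str(f.attrs["baseline_mode"]),
            condition=str(f.attrs["condition"]),
        )
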