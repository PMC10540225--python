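"""Readers and writers for the package's portable text formats.

EEG epochs travel as long CSV tables (subject_id, wave, channel, epoch,
sample, rate, value); EDF recordings can be ingested through mne when it is
installed.  Spectra and scores are tidy CSV; fitted models and manifests are
JSON.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .spectra import CHANNELS_1020, EpochedEEG, segment_epochs

__all__ = [
    "write_epoch_table", "read_epoch_table", "read_edf",
    "spectra_to_frame", "zspectra_to_frame", "write_json",
]


def write_epoch_table(eeg, path):
    """Serialize an :class:`EpochedEEG` to a long CSV epoch table."""
    n_ep, n_ch, n_s = eeg.epochs.shape
    ep, ch, sa = np.meshgrid(np.arange(n_ep), np.arange(n_ch), np.arange(n_s),
                             indexing="ij")
    df = pd.DataFrame({
        "subject_id": eeg.subject_id, "wave": eeg.wave,
        "channel": np.asarray(eeg.channel_labels)[ch.ravel()],
        "epoch": ep.ravel(), "sample": sa.ravel(), "rate": eeg.rate,
        "value": eeg.epochs.ravel(),
    })
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def read_epoch_table(path):
    """Read one epoch-table CSV back into an :class:`EpochedEEG`."""
    df = pd.read_csv(path)
    rate = int(df["rate"].iloc[0])
    subject = df["subject_id"].iloc[0]
    wave = df["wave"].iloc[0]
    channels = list(dict.fromkeys(df["channel"]))
    n_ep = int(df["epoch"].max()) + 1
    n_s = int(df["sample"].max()) + 1
    arr = np.empty((n_ep, len(channels), n_s))
    ch_idx = {c: i for i, c in enumerate(channels)}
    arr[df["epoch"], df["channel"].map(ch_idx), df["sample"]] = df["value"]
    return EpochedEEG(subject_id=subject, wave=wave, channel_labels=channels,
                      rate=rate, epochs=arr)


def read_edf(path, subject_id=None, wave=None, min_epochs=20):
    """Ingest an EDF recording (requires the optional mne dependency).

    Channels are matched case-insensitively against the 19-channel 10-20
    montage; the continuous signal is converted to microvolts and epoched.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    lookup = {c.lower(): c for c in raw.ch_names}
    picks = [lookup[c.lower()] for c in CHANNELS_1020 if c.lower() in lookup]
    if len(picks) < 2:
        raise ValueError("EDF does not contain 10-20 channels")
    rate = int(round(raw.info["sfreq"]))
    data = raw.get_data(picks=picks) * 1e6
    labels = [c for c in CHANNELS_1020 if c.lower() in lookup]
    return segment_epochs(data, rate, min_epochs=min_epochs,
                          subject_id=subject_id, wave=wave, channel_labels=labels)


def spectra_to_frame(spectra_list):
    """Tidy frame (subject_id, wave, channel, freq_hz, log_power)."""
    rows = []
    for s in spectra_list:
        for ci, ch in enumerate(s.channel_labels):
            rows.append(pd.DataFrame({
                "subject_id": s.subject_id, "wave": s.wave, "channel": ch,
                "freq_hz": s.freqs, "log_power": s.values[ci]}))
    return pd.concat(rows, ignore_index=True)


def zspectra_to_frame(z_list):
    """Tidy frame (subject_id, wave, channel, freq_hz, z) plus gsf map."""
    rows = []
    gsf = {}
    for s in z_list:
        gsf[f"{s.subject_id}/{s.wave}"] = s.gsf
        from .spectra import FREQ_GRID
        for ci, ch in enumerate(s.channel_labels):
            rows.append(pd.DataFrame({
                "subject_id": s.subject_id, "wave": s.wave, "channel": ch,
                "freq_hz": FREQ_GRID, "z": s.z[ci]}))
    return pd.concat(rows, ignore_index=True), gsf


def write_json(obj, path):
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=default)
    return path
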