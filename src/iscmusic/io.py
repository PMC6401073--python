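"""Readers and writers: raw EEG (EDF/BDF via MNE or the package's .npz
layout), annotation sidecars, WAV audio, and result tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .datatypes import Annotation, EEGRecording

__all__ = [
    "read_raw",
    "load_study_dir",
    "read_wav",
    "write_wav",
]


def read_raw(path, eog_labels=(), bad_labels=()) -> EEGRecording:
    """Read one subject's recording from EDF/BDF (via MNE) or .npz."""
    path = Path(path)
    if path.suffix.lower() == ".npz":
        return _read_npz(path)
    import mne

    if path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif path.suffix.lower() == ".bdf":
        raw = mne.io.read_raw_bdf(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported raw format: {path.suffix}")
    data = raw.get_data() * 1e6  # volts -> microvolts
    coords = {}
    montage = raw.get_montage()
    if montage is not None:
        coords = {
            k: tuple(map(float, v))
            for k, v in montage.get_positions()["ch_pos"].items()
            if np.isfinite(v).all()
        }
    return EEGRecording(
        data=data,
        rate=float(raw.info["sfreq"]),
        labels=list(raw.ch_names),
        eog_labels=[l for l in eog_labels if l in raw.ch_names],
        coords=coords,
        bad_labels=list(bad_labels),
    )


def _read_npz(path: Path) -> EEGRecording:
    with np.load(path, allow_pickle=False) as z:
        coords = {
            str(lab): tuple(xyz)
            for lab, xyz in zip(z["coord_labels"], z["coord_xyz"])
        }
        return EEGRecording(
            data=z["data"].astype(float),
            rate=float(z["rate"]),
            labels=[str(s) for s in z["labels"]],
            eog_labels=[str(s) for s in z["eog_labels"]],
            coords=coords,
            bad_labels=[str(s) for s in z["bad_labels"]],
        )


def load_study_dir(study_dir) -> tuple[dict, list, dict]:
    """Load (recordings, annotations, subject_meta) written by SimulatedStudy.save."""
    study_dir = Path(study_dir)
    with open(study_dir / "annotations.json") as fh:
        meta = json.load(fh)
    annotations = [Annotation(**a) for a in meta["annotations"]]
    subject_meta = meta["subject_meta"]
    recordings = {
        p.stem: read_raw(p) for p in sorted(study_dir.glob("*.npz"))
    }
    return recordings, annotations, subject_meta


def read_wav(path) -> tuple[np.ndarray, int]:
    """Mono float waveform in [-1, 1] plus rate; stereo is downmixed."""
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.dtype.kind == "i":
        data = data / float(np.iinfo(data.dtype).max)
    elif data.dtype.kind == "u":
        info = np.iinfo(data.dtype)
        data = (data.astype(float) - info.max / 2) / (info.max / 2)
    if data.ndim == 2:
        data = data.mean(axis=1)
    return data.astype(float), int(rate)


def write_wav(path, audio: np.ndarray, rate: int) -> None:
    """Write mono float audio as 16-bit PCM."""
    x = np.clip(np.asarray(audio, dtype=float), -1.0, 1.0)
    wavfile.write(path, int(rate), (x * 32767).astype(np.int16))
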