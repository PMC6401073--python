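"""Core data containers shared across the pipeline.

The analysis moves through three representations: a continuous per-subject
recording (:class:`EEGRecording`), a time-locked multi-subject tensor for one
stimulus presentation (:class:`SegmentStack`), and long-format tables of
inter-subject correlation values (built by :mod:`iscmusic.corrca`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = ["Annotation", "EEGRecording", "SegmentStack"]


@dataclass(frozen=True)
class Annotation:
    """One stimulus presentation, shared (time-locked) across subjects."""

    piece: str
    repeat: int
    familiarity: str  # "familiar" | "unfamiliar"
    attention: str  # "attend" | "distract"
    onset_s: float
    duration_s: float

    def to_dict(self) -> dict:
        return {
            "piece": self.piece,
            "repeat": int(self.repeat),
            "familiarity": self.familiarity,
            "attention": self.attention,
            "onset_s": float(self.onset_s),
            "duration_s": float(self.duration_s),
        }


@dataclass
class EEGRecording:
    """One subject's continuous multichannel recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts. Row order matches ``labels``.
    rate : float
        Sampling rate in Hz.
    labels : sequence of str
        Unique channel names (10/10 system for scalp channels).
    eog_labels : sequence of str
        Subset of ``labels`` carrying electro-oculogram channels.
    coords : mapping label -> (x, y, z)
        3-D cartesian electrode positions for every scalp channel
        (arbitrary units; only relative geometry is used).
    bad_labels : sequence of str
        Scalp channels flagged as high-variance / broken.
    """

    data: np.ndarray
    rate: float
    labels: Sequence[str]
    eog_labels: Sequence[str] = ()
    coords: Mapping[str, tuple] = field(default_factory=dict)
    bad_labels: Sequence[str] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = list(self.labels)
        self.eog_labels = list(self.eog_labels)
        self.bad_labels = list(self.bad_labels)
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.labels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but {len(self.labels)} labels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        unknown = set(self.eog_labels) - set(self.labels)
        if unknown:
            raise ValueError(f"eog_labels not in labels: {sorted(unknown)}")
        missing = [
            lab for lab in self.scalp_labels if self.coords and lab not in self.coords
        ]
        if missing:
            raise ValueError(f"coords missing for scalp channels: {missing}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def scalp_labels(self) -> list:
        eog = set(self.eog_labels)
        return [lab for lab in self.labels if lab not in eog]

    def indices(self, labels: Sequence[str]) -> np.ndarray:
        pos = {lab: i for i, lab in enumerate(self.labels)}
        return np.array([pos[lab] for lab in labels], dtype=int)

    @property
    def scalp(self) -> np.ndarray:
        """View of the scalp-channel rows (EOG excluded)."""
        return self.data[self.indices(self.scalp_labels)]

    @property
    def eog(self) -> np.ndarray:
        return self.data[self.indices(self.eog_labels)]

    def copy_with(self, **kwargs) -> "EEGRecording":
        out = replace(self, **kwargs)
        return out


@dataclass
class SegmentStack:
    """Aligned subjects x channels x samples tensor for one presentation.

    ``mask`` flags valid samples per subject (``True`` = usable); samples
    zeroed by the outlier stage are marked ``False`` so that downstream
    covariance and correlation sums can exclude them pairwise.
    """

    tensor: np.ndarray  # (n_subjects, n_channels, n_samples)
    rate: float
    annotation: Annotation
    subjects: Sequence[str]
    channel_labels: Sequence[str]
    mask: np.ndarray | None = None  # (n_subjects, n_samples) bool

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=float)
        if self.tensor.ndim != 3:
            raise ValueError("tensor must be 3-D (subjects x channels x samples)")
        n_subj, n_chan, n_samp = self.tensor.shape
        if len(self.subjects) != n_subj:
            raise ValueError("subjects length does not match tensor")
        if len(self.channel_labels) != n_chan:
            raise ValueError("channel_labels length does not match tensor")
        if self.mask is None:
            self.mask = np.ones((n_subj, n_samp), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (n_subj, n_samp):
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match (subjects, samples) "
                    f"({n_subj}, {n_samp})"
                )

    @property
    def n_subjects(self) -> int:
        return self.tensor.shape[0]

    @property
    def n_channels(self) -> int:
        return self.tensor.shape[1]

    @property
    def n_samples(self) -> int:
        return self.tensor.shape[2]

    @property
    def fully_valid(self) -> bool:
        return bool(self.mask.all())
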