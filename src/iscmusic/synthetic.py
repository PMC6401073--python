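"""Synthetic multi-subject EEG and stimulus audio with known ground truth.

The generator emulates the design of a repeated music-listening study: each
subject hears every piece several times in a row (time-locked across
subjects), half the pieces are in a familiar style and half in an unfamiliar
one, an optional distracted listening pass follows the attentive blocks, and
half the subjects count as musically trained.

A small number of source time courses are shared by all subjects through a
common mixing topography; everything else (1/f + white sensor noise, blink
artifacts, sample outliers, broken channels) is subject-specific. The
shared-signal amplitude in each design cell is controlled by an
``snr_by_cell`` table, so the condition effects that the statistical stages
must recover are known exactly.

Two entry points:

* :func:`simulate_study` — full continuous recordings with artifacts, to be
  fed through the preprocessing chain (writes EDF-like raw data).
* :func:`simulate_segment_stacks` — already-clean, already-segmented stacks
  at the analysis rate, for fast statistical studies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import scipy.signal

from .datatypes import Annotation, EEGRecording, SegmentStack

__all__ = [
    "StudyDesign",
    "GroundTruth",
    "SimulatedStudy",
    "default_snr_table",
    "simulate_study",
    "simulate_segment_stacks",
    "simulate_audio",
    "standard_layout",
]

FAMILIAR = "familiar"
UNFAMILIAR = "unfamiliar"
ATTEND = "attend"
DISTRACT = "distract"
TRAINED = "trained"
UNTRAINED = "untrained"


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

def standard_layout(n_channels: int = 64) -> tuple[list, dict]:
    """Scalp labels and 3-D positions from the standard 64-electrode cap.

    Channels are drawn from the BioSemi 64 10/10 layout; for
    ``n_channels < 64`` an evenly spaced subset is used so that coverage
    stays roughly whole-head.
    """
    import mne

    montage = mne.channels.make_standard_montage("biosemi64")
    pos = montage.get_positions()["ch_pos"]
    labels = list(montage.ch_names)
    if not 1 <= n_channels <= len(labels):
        raise ValueError(f"n_channels must be in [1, {len(labels)}], got {n_channels}")
    idx = np.linspace(0, len(labels) - 1, n_channels).round().astype(int)
    labels = [labels[i] for i in idx]
    coords = {lab: tuple(float(v) for v in pos[lab]) for lab in labels}
    return labels, coords


# ---------------------------------------------------------------------------
# design / ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class StudyDesign:
    """Counts and condition labels of the simulated listening study.

    Defaults mirror the second-experiment conditions: 20 subjects, 8 pieces
    (half familiar style), 3 attentive repeats per piece plus one distracted
    pass, 60 s segments, 64-channel cap sampled at 256 Hz.
    """

    n_subjects: int = 20
    n_pieces: int = 8
    n_repeats: int = 3
    segment_s: float = 60.0
    rate: float = 256.0
    n_channels: int = 64
    n_eog: int = 4
    include_distract: bool = True
    gap_s: float = 2.0

    def validate(self) -> None:
        if self.n_subjects < 3:
            raise ValueError(f"n_subjects must be >= 3, got {self.n_subjects}")
        if self.n_pieces < 2:
            raise ValueError(f"n_pieces must be >= 2, got {self.n_pieces}")
        if self.n_repeats < 1:
            raise ValueError(f"n_repeats must be >= 1, got {self.n_repeats}")
        if self.segment_s < 5.0:
            raise ValueError(f"segment_s must be >= 5 s, got {self.segment_s}")
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")

    @property
    def pieces(self) -> list:
        return [f"piece{p:02d}" for p in range(1, self.n_pieces + 1)]

    def familiarity_of(self, piece: str) -> str:
        # first half familiar, second half unfamiliar
        k = self.pieces.index(piece)
        return FAMILIAR if k < self.n_pieces // 2 else UNFAMILIAR


def default_snr_table(
    n_repeats: int = 3,
    familiar_by_repeat: Sequence[float] = (1.0, 0.8, 0.6),
    unfamiliar_by_repeat: Sequence[float] = (0.8, 0.8, 0.8),
    distract_factor: float = 0.4,
    training_scale: Mapping[str, float] | None = None,
) -> dict:
    """Shared-signal amplitude scale per (familiarity, repeat, attention, training).

    The familiar scale decreases across repeats while the unfamiliar scale is
    sustained; the distracted pass is globally attenuated and trained
    listeners carry a higher scale than untrained ones. All values are
    unitless multipliers of the base signal amplitude.
    """
    if training_scale is None:
        training_scale = {TRAINED: 1.2, UNTRAINED: 0.8}
    fam = list(familiar_by_repeat)
    unf = list(unfamiliar_by_repeat)
    if len(fam) < n_repeats:
        fam = fam + [fam[-1]] * (n_repeats - len(fam))
    if len(unf) < n_repeats:
        unf = unf + [unf[-1]] * (n_repeats - len(unf))
    table = {}
    for r in range(1, n_repeats + 1):
        for famlab, scale_r in ((FAMILIAR, fam[r - 1]), (UNFAMILIAR, unf[r - 1])):
            for att, att_fac in ((ATTEND, 1.0), (DISTRACT, distract_factor)):
                for train, tr_fac in training_scale.items():
                    val = scale_r * att_fac * tr_fac
                    if val < 0:
                        raise ValueError("snr scales must be >= 0")
                    table[(famlab, r, att, train)] = val
    return table


@dataclass
class GroundTruth:
    """Everything needed to verify recovery of the planted structure."""

    mixing: np.ndarray  # (n_scalp, K), unit-norm columns
    sources: dict  # (piece, repeat, attention) -> (K, n_samples) unit-SD courses
    snr_by_cell: dict  # (familiarity, repeat, attention, training) -> scale
    signal_amp: float  # microvolts at scale 1.0
    noise_sd: float  # per-channel noise SD, microvolts
    eog_gain: np.ndarray  # per-scalp-channel blink leakage coefficients
    bad_channels: tuple
    outlier_rate: float  # events per channel per minute
    outlier_amp: float  # multiples of noise_sd
    seed: int

    def __post_init__(self) -> None:
        if self.mixing.shape[1] < 1:
            raise ValueError("K must be >= 1")
        norms = np.linalg.norm(self.mixing, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("mixing columns must have unit norm")
        if any(v < 0 for v in self.snr_by_cell.values()):
            raise ValueError("all snr scales must be >= 0")

    @property
    def k(self) -> int:
        return self.mixing.shape[1]


@dataclass
class SimulatedStudy:
    recordings: dict  # subject id -> EEGRecording
    annotations: list  # [Annotation], identical timing for all subjects
    subject_meta: dict  # subject id -> {"training": trained|untrained}
    truth: GroundTruth
    design: StudyDesign = field(default=None)

    @property
    def subjects(self) -> list:
        return list(self.recordings)

    def save(self, out_dir) -> None:
        """One .npz per subject plus JSON annotation / ground-truth sidecars."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for subj, rec in self.recordings.items():
            np.savez_compressed(
                out_dir / f"{subj}.npz",
                data=rec.data.astype(np.float32),
                rate=rec.rate,
                labels=np.array(rec.labels),
                eog_labels=np.array(rec.eog_labels),
                bad_labels=np.array(rec.bad_labels),
                coord_labels=np.array(list(rec.coords)),
                coord_xyz=np.array([rec.coords[c] for c in rec.coords], dtype=float)
                if rec.coords
                else np.zeros((0, 3)),
            )
        with open(out_dir / "annotations.json", "w") as fh:
            json.dump(
                {
                    "annotations": [a.to_dict() for a in self.annotations],
                    "subject_meta": self.subject_meta,
                },
                fh,
                indent=1,
            )
        with open(out_dir / "ground_truth.json", "w") as fh:
            json.dump(
                {
                    "mixing": self.truth.mixing.tolist(),
                    "snr_by_cell": {
                        "|".join(map(str, k)): v
                        for k, v in self.truth.snr_by_cell.items()
                    },
                    "signal_amp": self.truth.signal_amp,
                    "noise_sd": self.truth.noise_sd,
                    "bad_channels": list(self.truth.bad_channels),
                    "seed": self.truth.seed,
                },
                fh,
                indent=1,
            )


# ---------------------------------------------------------------------------
# signal building blocks
# ---------------------------------------------------------------------------

def _source_courses(rng: np.random.Generator, k: int, n: int, rate: float) -> np.ndarray:
    """Unit-SD shared source time courses.

    Band-limited (0.5-16 Hz) Gaussian noise convolved with a 300 ms
    exponential kernel: smooth enough to look like evoked activity, fast
    enough to carry sub-second structure.
    """
    pad = int(rate)  # absorb filter edge effects
    x = rng.standard_normal((k, n + 2 * pad))
    nyq = rate / 2.0
    hi = min(16.0, 0.9 * nyq)
    sos = scipy.signal.butter(4, [0.5 / nyq, hi / nyq], btype="band", output="sos")
    x = scipy.signal.sosfiltfilt(sos, x, axis=-1)
    tau = 0.3  # s
    klen = max(3, int(round(5 * tau * rate)))
    kern = np.exp(-np.arange(klen) / (tau * rate))
    kern /= kern.sum()
    x = scipy.signal.fftconvolve(x, kern[None, :], mode="full")[:, : n + 2 * pad]
    x = x[:, pad : pad + n]
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _pink_white_noise(
    rng: np.random.Generator, shape: tuple, rate: float, sd: float
) -> np.ndarray:
    """1/f-shaped channel noise plus white sensor noise, total SD = ``sd``."""
    if sd == 0:
        return np.zeros(shape)
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(rng.standard_normal(shape), axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    shaping = np.ones_like(freqs)
    knee = 1.0  # Hz; flat below to keep variance finite
    above = freqs > knee
    shaping[above] = np.sqrt(knee / freqs[above])
    pink = np.fft.irfft(spec * shaping, n=n, axis=-1)
    psd = pink.std(axis=-1, keepdims=True)
    psd[psd == 0] = 1.0
    pink /= psd
    # 50/50 variance split between the two colours
    return sd * np.sqrt(0.5) * (pink + white)


def _blink_trace(
    rng: np.random.Generator, n: int, rate: float, rate_per_min: float = 12.0
) -> np.ndarray:
    """Blink artifact trace: random smooth ~200 ms bumps, unit peak height."""
    out = np.zeros(n)
    n_events = rng.poisson(rate_per_min * n / rate / 60.0)
    if n_events == 0:
        return out
    width = 0.1 * rate  # gaussian sigma in samples
    half = int(round(4 * width))
    bump = np.exp(-0.5 * (np.arange(-half, half + 1) / width) ** 2)
    centers = rng.integers(0, n, size=n_events)
    for c in centers:
        lo, hi = max(0, c - half), min(n, c + half + 1)
        out[lo:hi] += bump[lo - (c - half) : hi - (c - half)]
    return out


def _inject_outliers(
    rng: np.random.Generator,
    data: np.ndarray,
    rate: float,
    events_per_min: float,
    amp: float,
) -> None:
    """Add short large-amplitude bursts in place (per channel, Poisson)."""
    if events_per_min <= 0 or amp == 0:
        return
    n_ch, n = data.shape
    lam = events_per_min * n / rate / 60.0
    for c in range(n_ch):
        for t in rng.integers(0, max(1, n - 3), size=rng.poisson(lam)):
            data[c, t : t + 3] += amp * rng.choice([-1.0, 1.0])


# ---------------------------------------------------------------------------
# main generators
# ---------------------------------------------------------------------------

def _cell_scale(truth_table: Mapping, ann: Annotation, training: str) -> float:
    return truth_table[(ann.familiarity, ann.repeat, ann.attention, training)]


def _build_annotations(design: StudyDesign) -> list:
    anns = []
    t = design.gap_s
    for piece in design.pieces:
        fam = design.familiarity_of(piece)
        for r in range(1, design.n_repeats + 1):
            anns.append(Annotation(piece, r, fam, ATTEND, t, design.segment_s))
            t += design.segment_s + design.gap_s
    if design.include_distract:
        for piece in design.pieces:
            fam = design.familiarity_of(piece)
            anns.append(Annotation(piece, 1, fam, DISTRACT, t, design.segment_s))
            t += design.segment_s + design.gap_s
    return anns


def simulate_study(
    design: StudyDesign | None = None,
    *,
    k: int = 3,
    snr_by_cell: Mapping | None = None,
    signal_amp: float = 3.0,
    noise_sd: float = 10.0,
    eog_strength: float = 0.4,
    n_bad_channels: int = 1,
    outlier_rate: float = 1.0,
    outlier_amp: float = 8.0,
    seed: int = 0,
) -> SimulatedStudy:
    """Generate a full synthetic listening study with artifacts.

    Each subject's recording is ``mixing @ (scale * sources)`` inside the
    annotated windows, plus 1/f + white noise, blink leakage with a
    front-to-back gradient, injected outlier bursts, and (optionally)
    bad channels replaced by high-variance noise. EOG channels are appended
    after the scalp channels.

    Parameters
    ----------
    k : int
        Number of shared source components.
    snr_by_cell : mapping, optional
        (familiarity, repeat, attention, training) -> amplitude scale;
        defaults to :func:`default_snr_table`.
    signal_amp : float
        Shared-signal SD in microvolts at scale 1.0.
    noise_sd : float
        Total per-channel noise SD in microvolts.
    eog_strength : float
        Peak blink leakage (fraction of ~100 uV blink) at the frontmost
        electrodes; 0 disables ocular artifacts.
    outlier_rate, outlier_amp : float
        Burst events per channel per minute and their amplitude in multiples
        of ``noise_sd``.
    seed : int
        Single master seed; all randomness is split from it, so a fixed seed
        reproduces the study bit for bit.
    """
    design = design or StudyDesign()
    design.validate()
    if snr_by_cell is None:
        snr_by_cell = default_snr_table(design.n_repeats)
    if outlier_amp < 0 or outlier_rate < 0:
        raise ValueError("outlier_rate and outlier_amp must be >= 0")

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 + design.n_subjects)
    rng_struct = np.random.default_rng(children[0])
    rng_sources = np.random.default_rng(children[1])
    subject_seqs = children[2:]

    labels, coords = standard_layout(design.n_channels)
    eog_labels = [f"EOG{i + 1}" for i in range(design.n_eog)]
    n_scalp = len(labels)

    # common mixing topography, orthonormal columns (unit norm guaranteed)
    raw = rng_struct.standard_normal((n_scalp, k))
    mixing, _ = np.linalg.qr(raw)
    mixing = mixing[:, :k] * np.sign(mixing[np.abs(mixing).argmax(axis=0), range(k)])

    # blink leakage gradient: strongest at anterior (y > 0) electrodes
    ys = np.array([coords[lab][1] for lab in labels])
    y_norm = (ys - ys.min()) / (ys.max() - ys.min() + 1e-12)
    eog_gain = eog_strength * y_norm**2

    bad_channels = tuple(
        sorted(
            str(lab)
            for lab in rng_struct.choice(
                labels, size=min(n_bad_channels, n_scalp), replace=False
            )
        )
    ) if n_bad_channels > 0 else ()

    annotations = _build_annotations(design)
    n_seg = int(round(design.segment_s * design.rate))
    total_s = annotations[-1].onset_s + annotations[-1].duration_s + design.gap_s
    n_total = int(round(total_s * design.rate))

    sources = {
        (a.piece, a.repeat, a.attention): _source_courses(
            rng_sources, k, n_seg, design.rate
        )
        for a in annotations
    }

    subjects = [f"sub{ix + 1:02d}" for ix in range(design.n_subjects)]
    half = design.n_subjects // 2
    subject_meta = {
        s: {"training": TRAINED if ix < half else UNTRAINED}
        for ix, s in enumerate(subjects)
    }

    truth = GroundTruth(
        mixing=mixing,
        sources=sources,
        snr_by_cell=dict(snr_by_cell),
        signal_amp=signal_amp,
        noise_sd=noise_sd,
        eog_gain=eog_gain,
        bad_channels=bad_channels,
        outlier_rate=outlier_rate,
        outlier_amp=outlier_amp,
        seed=seed,
    )

    recordings = {}
    for six, subj in enumerate(subjects):
        srng = np.random.default_rng(subject_seqs[six])
        training = subject_meta[subj]["training"]

        scalp = _pink_white_noise(srng, (n_scalp, n_total), design.rate, noise_sd)

        blink = _blink_trace(srng, n_total, design.rate)
        blink_uv = 100.0 * blink
        scalp += eog_gain[:, None] * blink_uv

        for ann in annotations:
            s0 = int(round(ann.onset_s * design.rate))
            scale = _cell_scale(truth.snr_by_cell, ann, training)
            src = sources[(ann.piece, ann.repeat, ann.attention)]
            scalp[:, s0 : s0 + n_seg] += signal_amp * scale * (mixing @ src)

        _inject_outliers(srng, scalp, design.rate, outlier_rate, outlier_amp * noise_sd)

        for bad in bad_channels:
            ci = labels.index(bad)
            scalp[ci] = srng.standard_normal(n_total) * 5.0 * noise_sd

        # EOG electrodes see the blink at ~1.5x scalp amplitude plus sensor noise
        eog = 1.5 * np.tile(blink_uv, (design.n_eog, 1))
        eog += srng.standard_normal((design.n_eog, n_total)) * 5.0

        data = np.vstack([scalp, eog])
        recordings[subj] = EEGRecording(
            data=data,
            rate=design.rate,
            labels=labels + eog_labels,
            eog_labels=eog_labels,
            coords=coords,
            bad_labels=list(bad_channels),
        )

    return SimulatedStudy(
        recordings=recordings,
        annotations=annotations,
        subject_meta=subject_meta,
        truth=truth,
        design=design,
    )


def simulate_segment_stacks(
    n_subjects: int = 20,
    n_pieces: int = 8,
    n_repeats: int = 3,
    duration_s: float = 30.0,
    rate: float = 128.0,
    n_channels: int = 16,
    *,
    k: int = 3,
    snr_by_cell: Mapping | None = None,
    signal_amp: float = 3.0,
    component_scales: Sequence[float] | None = None,
    noise_sd: float = 10.0,
    include_distract: bool = False,
    seed: int = 0,
) -> tuple[list, GroundTruth, dict]:
    """Already-clean, already-segmented study at the analysis rate.

    Returns ``(stacks, truth, subject_meta)`` where ``stacks`` is a list of
    :class:`SegmentStack`, one per presentation, generated directly at
    ``rate`` with no artifacts. This is the fast path for statistical
    studies: it skips the raw-recording and preprocessing stages entirely
    while keeping the same shared-source model and condition encoding.

    ``component_scales`` (length ``k``, default all 1.0) sets distinct
    relative amplitudes per component; separated amplitudes make the
    component basis identifiable, whereas exactly equal ones leave it
    rotation-degenerate.
    """
    design = StudyDesign(
        n_subjects=n_subjects,
        n_pieces=n_pieces,
        n_repeats=n_repeats,
        segment_s=duration_s,
        rate=rate,
        n_channels=min(n_channels, 64),
        include_distract=include_distract,
    )
    design.validate()
    if snr_by_cell is None:
        snr_by_cell = default_snr_table(n_repeats)
    if component_scales is None:
        component_scales = np.ones(k)
    else:
        component_scales = np.asarray(component_scales, dtype=float)
        if component_scales.shape != (k,):
            raise ValueError(f"component_scales must have length k={k}")

    ss = np.random.SeedSequence(seed)
    rng_struct, rng_sources, rng_noise = [np.random.default_rng(s) for s in ss.spawn(3)]

    labels, _ = standard_layout(design.n_channels)
    n_ch = len(labels)
    raw = rng_struct.standard_normal((n_ch, k))
    mixing, _ = np.linalg.qr(raw)
    mixing = mixing[:, :k] * np.sign(mixing[np.abs(mixing).argmax(axis=0), range(k)])

    annotations = _build_annotations(design)
    n_seg = int(round(duration_s * rate))

    subjects = [f"sub{ix + 1:02d}" for ix in range(n_subjects)]
    half = n_subjects // 2
    subject_meta = {
        s: {"training": TRAINED if ix < half else UNTRAINED}
        for ix, s in enumerate(subjects)
    }
    scale_by_training = {
        t: np.array(
            [1.0 if subject_meta[s]["training"] == t else 0.0 for s in subjects]
        )
        for t in (TRAINED, UNTRAINED)
    }

    sources = {}
    stacks = []
    for ann in annotations:
        src = _source_courses(rng_sources, k, n_seg, rate)
        sources[(ann.piece, ann.repeat, ann.attention)] = src
        noise = _pink_white_noise(rng_noise, (n_subjects, n_ch, n_seg), rate, noise_sd)
        shared = mixing @ (component_scales[:, None] * src)  # (n_ch, n_seg)
        scales = np.zeros(n_subjects)
        for t, ind in scale_by_training.items():
            scales += ind * snr_by_cell[(ann.familiarity, ann.repeat, ann.attention, t)]
        tensor = noise + signal_amp * scales[:, None, None] * shared[None, :, :]
        stacks.append(
            SegmentStack(
                tensor=tensor,
                rate=rate,
                annotation=ann,
                subjects=subjects,
                channel_labels=labels,
            )
        )

    truth = GroundTruth(
        mixing=mixing,
        sources=sources,
        snr_by_cell=dict(snr_by_cell),
        signal_amp=signal_amp,
        noise_sd=noise_sd,
        eog_gain=np.zeros(n_ch),
        bad_channels=(),
        outlier_rate=0.0,
        outlier_amp=0.0,
        seed=seed,
    )
    return stacks, truth, subject_meta


def simulate_audio(
    duration_s: float,
    modulation_depth: float = 1.0,
    seed: int = 0,
    *,
    rate: int = 22050,
    mod_freq: float = 2.0,
    n_tones: int = 5,
) -> tuple[np.ndarray, int]:
    """Amplitude-modulated multi-tone stand-in for a music excerpt.

    ``modulation_depth`` in [0, 1] scales a sinusoidal envelope at
    ``mod_freq`` Hz; depth 0 yields a stationary signal (zero spectral flux
    after onset frames), depth 1 a fully modulated one. Tone frequencies are
    jittered around a small just-ish scale so different seeds give different
    "pieces". Returns ``(mono waveform in [-1, 1], rate)``.
    """
    if duration_s <= 0:
        raise ValueError(f"duration_s must be positive, got {duration_s}")
    if modulation_depth < 0 or modulation_depth > 1:
        raise ValueError(
            f"modulation_depth must be in [0, 1], got {modulation_depth}"
        )
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    # octave-spaced, slightly detuned tones: wide spacing keeps any two tones
    # out of a common auditory band, so depth 0 really is stationary (no
    # audible beating -> negligible spectral flux)
    base = 220.0 * 2.0 ** (np.arange(n_tones) + rng.uniform(-0.04, 0.04, n_tones))
    phases = rng.uniform(0, 2 * np.pi, size=n_tones)
    amps = rng.uniform(0.5, 1.0, size=n_tones)
    x = np.zeros(n)
    for f, ph, a in zip(base, phases, amps):
        x += a * np.sin(2 * np.pi * f * t + ph)
    envelope = 1.0 + modulation_depth * np.sin(2 * np.pi * mod_freq * t)
    x = x * envelope
    peak = np.abs(x).max()
    if peak > 0:
        x = 0.9 * x / peak
    return x, rate
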