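"""EEG cleaning chain: filters, robust PCA, interpolation, EOG regression,
outlier zeroing and segmentation.

Stage order used by the pipeline driver:

    high-pass (0.5 Hz) -> 60 Hz notch -> robust PCA -> low-pass (64 Hz)
    -> downsample to 128 Hz -> segmentation -> bad-channel interpolation
    -> EOG regression (per segment) -> outlier zeroing (per channel)

Every stage is callable on its own. All filters are zero-phase
(forward-backward Butterworth / IIR notch), which preserves the time
alignment between subjects that inter-subject correlation depends on.
"""

from __future__ import annotations

import logging
import warnings
from fractions import Fraction
from typing import Sequence

import numpy as np
import scipy.signal

from .datatypes import Annotation, EEGRecording, SegmentStack

__all__ = [
    "highpass",
    "notch",
    "lowpass",
    "downsample",
    "filter_chain",
    "robust_pca_clean",
    "interpolate_bad_channels",
    "regress_out_eog",
    "zero_outlier_samples",
    "segment",
    "stack_segments",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def _apply_sos(data: np.ndarray, sos: np.ndarray) -> np.ndarray:
    return scipy.signal.sosfiltfilt(sos, data, axis=-1)


def highpass(rec: EEGRecording, cutoff: float = 0.5, order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth high-pass (default 0.5 Hz)."""
    nyq = rec.rate / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError(f"high-pass cutoff {cutoff} outside (0, {nyq}) Hz")
    sos = scipy.signal.butter(order, cutoff / nyq, btype="high", output="sos")
    return rec.copy_with(data=_apply_sos(rec.data, sos))


def notch(rec: EEGRecording, freq: float = 60.0, q: float = 30.0) -> EEGRecording:
    """Zero-phase IIR notch at the line frequency (default 60 Hz, Q=30)."""
    nyq = rec.rate / 2.0
    if not 0 < freq < nyq:
        raise ValueError(f"notch frequency {freq} outside (0, {nyq}) Hz")
    b, a = scipy.signal.iirnotch(freq, q, fs=rec.rate)
    data = scipy.signal.filtfilt(b, a, rec.data, axis=-1)
    return rec.copy_with(data=data)


def lowpass(rec: EEGRecording, cutoff: float = 64.0, order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth low-pass (default 64 Hz)."""
    nyq = rec.rate / 2.0
    if cutoff >= nyq:
        raise ValueError(
            f"low-pass cutoff {cutoff} Hz requires rate > {2 * cutoff} Hz "
            f"(got {rec.rate} Hz): aliasing"
        )
    sos = scipy.signal.butter(order, cutoff / nyq, btype="low", output="sos")
    return rec.copy_with(data=_apply_sos(rec.data, sos))


def downsample(rec: EEGRecording, target_rate: float = 128.0) -> EEGRecording:
    """Polyphase resampling to the analysis rate (default 128 Hz)."""
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if rec.rate == target_rate:
        return rec
    frac = Fraction(target_rate / rec.rate).limit_denominator(1000)
    data = scipy.signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=-1)
    return rec.copy_with(data=data, rate=target_rate)


def filter_chain(
    rec: EEGRecording,
    *,
    hp_cutoff: float = 0.5,
    notch_freq: float = 60.0,
    lp_cutoff: float = 64.0,
    target_rate: float = 128.0,
) -> EEGRecording:
    """High-pass, notch, low-pass and downsample in order.

    Requires an input rate of at least twice the low-pass cutoff so the
    anti-aliasing low-pass is legal before decimation. The pipeline driver
    inserts robust PCA between the notch and the low-pass; called directly,
    this runs the four filter stages back to back.
    """
    if rec.rate < 2 * lp_cutoff:
        raise ValueError(
            f"rate {rec.rate} Hz < 2 x low-pass cutoff {lp_cutoff} Hz: aliasing"
        )
    out = highpass(rec, hp_cutoff)
    out = notch(out, notch_freq)
    out = lowpass(out, lp_cutoff)
    return downsample(out, target_rate)


# ---------------------------------------------------------------------------
# robust PCA (principal component pursuit)
# ---------------------------------------------------------------------------

def robust_pca_clean(
    data: np.ndarray,
    lam: float | None = None,
    tol: float = 1e-7,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Split a channels x samples matrix into low-rank + sparse parts.

    Principal component pursuit: minimise ``||L||_* + lam * ||S||_1`` subject
    to ``L + S = M``, solved with inexact augmented-Lagrange iterations.
    The low-rank part ``L`` is the cleaned EEG; ``S`` absorbs sparse
    artifacts and outliers. Default ``lam = 1/sqrt(max(n_channels,
    n_samples))``.

    Returns
    -------
    (lowrank, sparse) : ndarray pair with ``lowrank + sparse == data`` to
    solver tolerance.
    """
    M = np.asarray(data, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("data must be 2-D with at least 2 channels")
    if np.isnan(M).any():
        raise ValueError("data contains NaNs")
    if not M.any():
        return np.zeros_like(M), np.zeros_like(M)
    if lam is None:
        lam = 1.0 / np.sqrt(max(M.shape))

    norm_fro = np.linalg.norm(M)
    norm_two = np.linalg.norm(M, 2)
    norm_inf = np.abs(M).max() / lam
    Y = M / max(norm_two, norm_inf)
    mu = 1.25 / norm_two
    rho = 1.5
    S = np.zeros_like(M)

    residual = np.inf
    for it in range(max_iter):
        U, sig, Vt = np.linalg.svd(M - S + Y / mu, full_matrices=False)
        sig = np.maximum(sig - 1.0 / mu, 0.0)
        rank = int((sig > 0).sum())
        L = (U[:, :rank] * sig[:rank]) @ Vt[:rank]
        tmp = M - L + Y / mu
        S = np.sign(tmp) * np.maximum(np.abs(tmp) - lam / mu, 0.0)
        Z = M - L - S
        Y = Y + mu * Z
        mu = min(mu * rho, 1e7 * mu)
        residual = np.linalg.norm(Z) / norm_fro
        if residual < tol:
            break
    else:
        warnings.warn(
            f"robust PCA did not converge in {max_iter} iterations "
            f"(relative residual {residual:.2e})",
            RuntimeWarning,
        )
    return L, S


# ---------------------------------------------------------------------------
# bad-channel interpolation
# ---------------------------------------------------------------------------

def suggest_bad_channels(rec: EEGRecording, z_thresh: float = 4.0) -> list[str]:
    """Advisory list of scalp channels with outlying log-variance.

    Channels whose log variance deviates from the median by more than
    ``z_thresh`` robust z-scores are suggested for the bad-channel list.
    This is a convenience for screening only — the pipeline takes its bad
    channels from configuration, because flagging broken electrodes is
    ultimately a judgement call on the raw traces.
    """
    scalp = rec.scalp
    logv = np.log(scalp.var(axis=1) + 1e-30)
    med = np.median(logv)
    mad = np.median(np.abs(logv - med)) * 1.4826 + 1e-12
    z = (logv - med) / mad
    labels = rec.scalp_labels
    return [labels[i] for i in np.flatnonzero(np.abs(z) > z_thresh)]


def _azimuthal_projection(coords: np.ndarray) -> np.ndarray:
    """Project 3-D electrode positions onto a plane (azimuthal equidistant).

    Distance from the projection origin equals the polar angle from the
    vertex, so the relative geometry of the cap is preserved.
    """
    xyz = np.asarray(coords, dtype=float)
    norms = np.linalg.norm(xyz, axis=1)
    norms[norms == 0] = 1.0
    unit = xyz / norms[:, None]
    polar = np.arccos(np.clip(unit[:, 2], -1.0, 1.0))
    azim = np.arctan2(unit[:, 1], unit[:, 0])
    return np.column_stack([polar * np.cos(azim), polar * np.sin(azim)])


def interpolate_bad_channels(
    rec: EEGRecording, power: float = 2.0, eps: float = 1e-9
) -> EEGRecording:
    """Replace flagged channels with inverse-distance-weighted good channels.

    Electrode positions are projected onto a plane and each bad channel is
    rebuilt as a weighted sum of all good scalp channels with weights
    ``1/d**power``; a bad electrode coincident with a good one copies it
    exactly. Good channels pass through unchanged.
    """
    bad = [lab for lab in rec.bad_labels if lab in rec.scalp_labels]
    if not bad:
        return rec
    good = [lab for lab in rec.scalp_labels if lab not in bad]
    if len(good) < 4:
        raise ValueError(
            f"need at least 4 good scalp channels to interpolate, have {len(good)}"
        )
    if not rec.coords:
        raise ValueError("electrode coordinates are required for interpolation")

    labs = good + bad
    pts2d = _azimuthal_projection(np.array([rec.coords[lab] for lab in labs]))
    good_pts, bad_pts = pts2d[: len(good)], pts2d[len(good) :]

    data = rec.data.copy()
    good_idx = rec.indices(good)
    for b_lab, b_pt in zip(bad, bad_pts):
        d = np.linalg.norm(good_pts - b_pt, axis=1)
        if (d < eps).any():
            # coincident electrode: copy it
            src = good_idx[int(np.argmin(d))]
            data[rec.labels.index(b_lab)] = rec.data[src]
            continue
        w = 1.0 / d**power
        w /= w.sum()
        data[rec.labels.index(b_lab)] = w @ rec.data[good_idx]
    return rec.copy_with(data=data, bad_labels=[])


# ---------------------------------------------------------------------------
# EOG regression
# ---------------------------------------------------------------------------

def regress_out_eog(eeg: np.ndarray, eog: np.ndarray) -> np.ndarray:
    """Least-squares noise cancellation of ocular activity.

    Both inputs are demeaned internally; the EEG is projected onto the
    orthogonal complement of the EOG channels, so the residual has zero
    inner product with every EOG trace. Rank-deficient EOG (e.g. a
    duplicated electrode) is handled by the least-squares pseudoinverse with
    a logged warning.
    """
    eeg = np.asarray(eeg, dtype=float)
    eog = np.atleast_2d(np.asarray(eog, dtype=float))
    if eeg.shape[-1] != eog.shape[-1]:
        raise ValueError(
            f"sample counts differ: eeg {eeg.shape[-1]} vs eog {eog.shape[-1]}"
        )
    eeg_d = eeg - eeg.mean(axis=-1, keepdims=True)
    eog_d = eog - eog.mean(axis=-1, keepdims=True)
    rank = np.linalg.matrix_rank(eog_d)
    if rank < eog_d.shape[0]:
        logger.warning(
            "EOG channels are rank deficient (rank %d of %d); using pseudoinverse",
            rank,
            eog_d.shape[0],
        )
    # B: (n_eeg, n_eog) regression coefficients
    B, *_ = np.linalg.lstsq(eog_d.T, eeg_d.T, rcond=None)
    return eeg_d - B.T @ eog_d


# ---------------------------------------------------------------------------
# outlier zeroing
# ---------------------------------------------------------------------------

def zero_outlier_samples(
    x: np.ndarray,
    rate: float,
    iqr_multiplier: float = 4.0,
    pad_s: float = 0.040,
) -> tuple[np.ndarray, np.ndarray]:
    """Zero out extreme samples of a single channel, with a guard window.

    A sample is an outlier when its absolute median-centred value exceeds
    ``iqr_multiplier`` times the interquartile range (Q75 - Q25) of the
    median-centred channel. Outliers plus ``round(pad_s * rate)`` samples on
    each side are set to zero and flagged in the returned mask
    (``True`` = zeroed). A constant channel (IQR = 0) is returned unchanged
    with a logged warning.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 10:
        raise ValueError("x must be 1-D with at least 10 samples")
    centred = x - np.median(x)
    q25, q75 = np.percentile(centred, [25, 75])
    iqr = q75 - q25
    mask = np.zeros(x.size, dtype=bool)
    if iqr == 0:
        logger.warning("constant channel (IQR = 0): outlier rule vacuous")
        return x.copy(), mask
    threshold = iqr_multiplier * iqr
    hits = np.flatnonzero(np.abs(centred) > threshold)
    if hits.size == 0:
        return x.copy(), mask
    pad = int(round(pad_s * rate))
    for t in hits:
        mask[max(0, t - pad) : t + pad + 1] = True
    out = x.copy()
    out[mask] = 0.0
    return out, mask


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment(
    rec: EEGRecording, annotations: Sequence[Annotation]
) -> list[tuple[Annotation, np.ndarray]]:
    """Extract half-open sample windows [round(onset*rate), +round(dur*rate)).

    Returns one ``(annotation, channels x samples)`` pair per annotation;
    raises if a window exceeds the recording.
    """
    out = []
    for ann in annotations:
        start = int(round(ann.onset_s * rec.rate))
        length = int(round(ann.duration_s * rec.rate))
        if start < 0 or start + length > rec.n_samples:
            raise ValueError(
                f"segment for piece {ann.piece!r} (repeat {ann.repeat}) "
                f"[{start}, {start + length}) exceeds recording of "
                f"{rec.n_samples} samples"
            )
        out.append((ann, rec.data[:, start : start + length]))
    return out


def stack_segments(
    recordings: dict,
    annotations: Sequence[Annotation],
    channel_labels: Sequence[str] | None = None,
) -> list[SegmentStack]:
    """Cut every subject's recording and stack subjects per presentation.

    All recordings must share rate and channel layout (stimuli are
    time-locked, so annotation timing is common). ``channel_labels``
    restricts the stack to a subset (e.g. scalp only).
    """
    subjects = list(recordings)
    if not subjects:
        raise ValueError("no recordings given")
    first = recordings[subjects[0]]
    rate = first.rate
    labels = list(channel_labels) if channel_labels is not None else first.scalp_labels
    stacks = []
    for ann in annotations:
        per_subj = []
        for subj in subjects:
            rec = recordings[subj]
            if rec.rate != rate:
                raise ValueError(f"subject {subj} has rate {rec.rate}, expected {rate}")
            (_, sl), = segment(rec, [ann])
            per_subj.append(sl[rec.indices(labels)])
        lengths = {a.shape[-1] for a in per_subj}
        if len(lengths) != 1:
            raise ValueError(f"unequal segment lengths across subjects: {lengths}")
        stacks.append(
            SegmentStack(
                tensor=np.stack(per_subj),
                rate=rate,
                annotation=ann,
                subjects=subjects,
                channel_labels=labels,
            )
        )
    return stacks
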