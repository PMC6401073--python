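"""Correlated component analysis (CorrCA) and inter-subject correlation.

CorrCA finds a single set of electrode weightings, shared by all subjects,
whose projected time courses are maximally correlated between subjects. With
per-subject data matrices ``X_i`` (channels x samples, demeaned), define the
pooled covariances

    R_w = sum_i  X_i X_i^T          (within-subject)
    R_b = sum_{i != j}  X_i X_j^T   (between-subject)

The projection vectors ``W`` solve the generalized eigenvalue problem
``R_b w = lambda R_w w`` (largest eigenvalues first), optionally with
shrinkage of ``R_w`` toward its diagonal for conditioning. This is
conceptually canonical correlation analysis constrained to use the *same*
projections for every subject.

The forward model ``A = R_w W (W^T R_w W)^{-1}`` maps components back to
scalp topographies for physiological interpretation.

The reported ISC statistic is the pairwise-mean Pearson correlation of the
projected time courses: for subject ``i`` and component ``k``, the mean over
all other subjects ``j`` of ``r(y_ik, y_jk)``; eigenvalues are used only to
order components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .datatypes import SegmentStack

__all__ = [
    "PooledCovariances",
    "CorrCAModel",
    "pooled_covariances",
    "fit_model",
    "project",
    "isc_per_subject",
    "isc_table",
    "summed_isc",
]

logger = logging.getLogger(__name__)


@dataclass
class PooledCovariances:
    """Within- and between-subject covariance sums over one or more segments."""

    R_w: np.ndarray
    R_b: np.ndarray
    n_subjects: int
    n_samples_effective: int

    def __post_init__(self) -> None:
        if self.R_w.shape != self.R_b.shape or self.R_w.shape[0] != self.R_w.shape[1]:
            raise ValueError("R_w and R_b must be square and same shape")

    def __add__(self, other: "PooledCovariances") -> "PooledCovariances":
        if other.n_subjects != self.n_subjects:
            raise ValueError("cannot pool covariances over different subject counts")
        return PooledCovariances(
            R_w=self.R_w + other.R_w,
            R_b=self.R_b + other.R_b,
            n_subjects=self.n_subjects,
            n_samples_effective=self.n_samples_effective + other.n_samples_effective,
        )


@dataclass
class CorrCAModel:
    """Fitted projections ``W``, forward model ``A`` and eigenvalues."""

    W: np.ndarray  # (n_channels, K)
    A: np.ndarray  # (n_channels, K)
    eigenvalues: np.ndarray  # (K,), descending
    n_channels: int

    def __post_init__(self) -> None:
        if self.W.shape != self.A.shape:
            raise ValueError("W and A must have the same shape")
        if self.W.shape[0] != self.n_channels:
            raise ValueError("W rows must equal n_channels")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be sorted descending")

    @property
    def k(self) -> int:
        return self.W.shape[1]

    def to_dict(self) -> dict:
        return {
            "W": self.W.tolist(),
            "A": self.A.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "n_channels": int(self.n_channels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CorrCAModel":
        return cls(
            W=np.asarray(d["W"], dtype=float),
            A=np.asarray(d["A"], dtype=float),
            eigenvalues=np.asarray(d["eigenvalues"], dtype=float),
            n_channels=int(d["n_channels"]),
        )


def _demean_valid(x: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Demean each channel over its valid samples only."""
    out = x.astype(float, copy=True)
    nv = valid.sum()
    if nv:
        out -= out[:, valid].mean(axis=1, keepdims=True)
    return out


def pooled_covariances(
    stacks: SegmentStack | Iterable[SegmentStack],
) -> PooledCovariances:
    """Accumulate R_w and R_b over segments.

    Each subject's channels are demeaned per segment (over that subject's
    valid samples). When outlier masks are present, cross-covariances use
    only the samples valid for *both* subjects of a pair, so zeroed samples
    never bias correlations toward zero. Segments contribute additively.
    """
    if isinstance(stacks, SegmentStack):
        stacks = [stacks]
    stacks = list(stacks)
    if not stacks:
        raise ValueError("no segments given")
    n_subj = stacks[0].n_subjects
    n_chan = stacks[0].n_channels
    if n_subj < 2:
        raise ValueError(f"need at least 2 subjects, got {n_subj}")

    R_w = np.zeros((n_chan, n_chan))
    R_b = np.zeros((n_chan, n_chan))
    n_eff = 0
    for stack in stacks:
        if stack.n_subjects != n_subj or stack.n_channels != n_chan:
            raise ValueError("all segments must share subject and channel counts")
        if not stack.mask.any(axis=1).all():
            logger.warning(
                "segment %s has a fully masked subject; excluding segment",
                stack.annotation,
            )
            continue
        if stack.n_samples < n_chan + 1:
            raise ValueError(
                f"segment has {stack.n_samples} samples; need > n_channels ({n_chan})"
            )
        if stack.fully_valid:
            X = stack.tensor - stack.tensor.mean(axis=2, keepdims=True)
            # sum trick: sum_ij C_ij = S S^T with S = sum_i X_i
            S = X.sum(axis=0)
            Rw_seg = np.einsum("ict,idt->cd", X, X)
            R_w += Rw_seg
            R_b += S @ S.T - Rw_seg
            n_eff += stack.n_samples
        else:
            Xd = [
                _demean_valid(stack.tensor[i], stack.mask[i]) for i in range(n_subj)
            ]
            for i in range(n_subj):
                vi = stack.mask[i]
                R_w += Xd[i][:, vi] @ Xd[i][:, vi].T
                for j in range(i + 1, n_subj):
                    v = vi & stack.mask[j]
                    if v.sum() < 3:
                        logger.warning(
                            "pair (%d, %d) has <3 jointly valid samples; skipped",
                            i,
                            j,
                        )
                        continue
                    C = Xd[i][:, v] @ Xd[j][:, v].T
                    R_b += C + C.T
            n_eff += int(stack.mask.all(axis=0).sum())
    R_b = 0.5 * (R_b + R_b.T)  # exact symmetry for the symmetric eigensolver
    return PooledCovariances(R_w=R_w, R_b=R_b, n_subjects=n_subj, n_samples_effective=n_eff)


def fit_model(
    cov: PooledCovariances, k_max: int | None = None, shrinkage: float = 0.1
) -> CorrCAModel:
    """Solve the generalized eigenproblem and build the forward model.

    ``W`` holds the top ``k_max`` eigenvectors of
    ``((1 - g) R_w + g diag(R_w))^{-1} R_b`` with ``g = shrinkage``,
    eigenvalues descending. Each component's sign is flipped so the
    largest-magnitude entry of its forward-model column is positive, making
    topographies deterministic.
    """
    n = cov.R_w.shape[0]
    k_max = n if k_max is None else int(k_max)
    if not 1 <= k_max <= n:
        raise ValueError(f"k_max must be in [1, {n}], got {k_max}")
    if not 0 <= shrinkage <= 1:
        raise ValueError(f"shrinkage must be in [0, 1], got {shrinkage}")

    Rw_reg = (1.0 - shrinkage) * cov.R_w + shrinkage * np.diag(np.diag(cov.R_w))
    # guard: the whitening matrix must be positive definite
    min_eig = scipy.linalg.eigvalsh(Rw_reg, subset_by_index=[0, 0])[0]
    if min_eig <= 1e-12 * max(1.0, np.abs(Rw_reg).max()):
        raise np.linalg.LinAlgError(
            "pooled within-subject covariance is near singular; "
            "refit with shrinkage > 0"
        )

    evals, evecs = scipy.linalg.eigh(cov.R_b, Rw_reg)
    order = np.argsort(evals)[::-1][:k_max]
    W = evecs[:, order]
    evals = evals[order]

    M = W.T @ cov.R_w @ W
    A = cov.R_w @ W @ np.linalg.inv(M)

    flip = np.sign(A[np.abs(A).argmax(axis=0), range(A.shape[1])])
    flip[flip == 0] = 1.0
    return CorrCAModel(W=W * flip, A=A * flip, eigenvalues=evals, n_channels=n)


def project(stack: SegmentStack | np.ndarray, W: np.ndarray) -> np.ndarray:
    """Project a stack onto components: returns (subjects, K, samples)."""
    tensor = stack.tensor if isinstance(stack, SegmentStack) else np.asarray(stack)
    if tensor.shape[1] != W.shape[0]:
        raise ValueError(
            f"channel mismatch: data has {tensor.shape[1]}, W expects {W.shape[0]}"
        )
    return np.einsum("ck,ict->ikt", W, tensor)


def isc_per_subject(
    components: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    """Per-subject, per-component ISC.

    ``isc[i, k]`` is the mean over all other subjects ``j`` of the Pearson
    correlation between ``components[i, k]`` and ``components[j, k]`` over
    the samples valid for both subjects. A zero-variance course makes the
    pairs it touches undefined; those pairs are excluded (with a warning)
    and the mean taken over the remaining ones.
    """
    y = np.asarray(components, dtype=float)
    if y.ndim != 3:
        raise ValueError("components must be (subjects, K, samples)")
    n_subj, K, T = y.shape
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")

    if mask is None or mask.all():
        yc = y - y.mean(axis=2, keepdims=True)
        norm = np.linalg.norm(yc, axis=2)
        bad = norm == 0
        norm[bad] = 1.0
        z = yc / norm[:, :, None]
        G = np.einsum("ikt,jkt->kij", z, z)  # (K, n_subj, n_subj) correlations
        if bad.any():
            logger.warning("%d zero-variance subject/component pairs excluded", bad.sum())
        isc = np.empty((n_subj, K))
        for k in range(K):
            g = G[k]
            valid = ~bad[:, k]
            for i in range(n_subj):
                others = valid.copy()
                others[i] = False
                isc[i, k] = g[i, others].mean() if (valid[i] and others.any()) else np.nan
        return isc

    isc = np.full((n_subj, K), np.nan)
    dropped = 0
    for i in range(n_subj):
        for k in range(K):
            rs = []
            for j in range(n_subj):
                if j == i:
                    continue
                v = mask[i] & mask[j]
                if v.sum() < 3:
                    dropped += 1
                    continue
                a, b = y[i, k, v], y[j, k, v]
                sa, sb = a.std(), b.std()
                if sa == 0 or sb == 0:
                    dropped += 1
                    continue
                rs.append(float(np.corrcoef(a, b)[0, 1]))
            if rs:
                isc[i, k] = np.mean(rs)
    if dropped:
        logger.warning("%d undefined subject pairs excluded from ISC", dropped)
    return isc


def isc_table(
    stacks: Sequence[SegmentStack],
    model: CorrCAModel,
    subject_meta: dict | None = None,
) -> pd.DataFrame:
    """Long-format ISC records over segments.

    One row per (subject, piece, repeat, attention, component) with columns
    ``subject, piece, repeat, familiarity, attention, training, component,
    isc``. Component indices are 1-based in eigenvalue order.
    """
    rows = []
    for stack in stacks:
        comps = project(stack, model.W)
        isc = isc_per_subject(comps, mask=stack.mask)
        ann = stack.annotation
        for i, subj in enumerate(stack.subjects):
            training = (
                subject_meta[subj]["training"] if subject_meta else "unknown"
            )
            for k in range(model.k):
                rows.append(
                    {
                        "subject": subj,
                        "piece": ann.piece,
                        "repeat": ann.repeat,
                        "familiarity": ann.familiarity,
                        "attention": ann.attention,
                        "training": training,
                        "component": k + 1,
                        "isc": isc[i, k],
                    }
                )
    return pd.DataFrame(rows)


def summed_isc(table: pd.DataFrame, significant: Iterable[int]) -> pd.DataFrame:
    """Sum ISC over the significant components per presentation.

    Returns one row per (subject, piece, repeat, attention) with an
    ``isc_sum`` column. An empty significant set yields ``isc_sum = 0``
    everywhere and sets ``attrs['no_significant_components'] = True`` on the
    result so callers can surface it.
    """
    significant = sorted(set(int(s) for s in significant))
    missing = set(significant) - set(table["component"].unique())
    if missing:
        raise ValueError(f"components not present in table: {sorted(missing)}")
    keys = ["subject", "piece", "repeat", "familiarity", "attention", "training"]
    keys = [k for k in keys if k in table.columns]
    if significant:
        sub = table[table["component"].isin(significant)]
        out = sub.groupby(keys, as_index=False)["isc"].sum()
        out = out.rename(columns={"isc": "isc_sum"})
        out.attrs["no_significant_components"] = False
    else:
        out = table.groupby(keys, as_index=False)["isc"].first()
        out["isc_sum"] = 0.0
        out = out.drop(columns=["isc"])
        out.attrs["no_significant_components"] = True
        logger.warning("no significant components: summed ISC set to 0")
    return out
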