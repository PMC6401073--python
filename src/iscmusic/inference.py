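"""Statistical machinery around the component model.

Significance of ISC is assessed non-parametrically: component models are
trained leaving one piece out and evaluated on the held-out piece, and the
evaluated ISC values are compared against a circular-shift null in which
each subject's component time course is rotated by an independent random
offset. Rotation preserves each subject's autocorrelation but destroys the
inter-subject alignment, so the null keeps the marginal signal statistics.
The familywise threshold is the single largest shuffle ISC over *all*
components and shuffles; with ``n`` shuffles the familywise false-positive
level is ``1/(n+1)``.

Condition effects are then tested on the summed significant-component ISC
with classical balanced repeated-measures ANOVA (subject as random factor),
per-piece repetition slopes, and paired contrasts.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .corrca import (
    CorrCAModel,
    fit_model,
    isc_per_subject,
    pooled_covariances,
    project,
)
from .datatypes import SegmentStack

__all__ = [
    "NullDistribution",
    "SlopeRecord",
    "LooResult",
    "circular_shift_null",
    "loo_crossval",
    "component_test_isc",
    "select_significant",
    "isc_slope",
    "slope_group_test",
    "aggregate_cells",
    "rm_anova",
    "attend_distract_delta",
    "preference_split",
]

logger = logging.getLogger(__name__)

ATTEND = "attend"


# ---------------------------------------------------------------------------
# circular-shift null
# ---------------------------------------------------------------------------

@dataclass
class NullDistribution:
    """Component ISCs under circular-shift surrogates."""

    shuffle_iscs: np.ndarray  # (n_shuffles, K) group-level ISC per component
    n_shuffles: int
    seed: int

    @property
    def threshold(self) -> float:
        """Largest shuffle ISC over all components — the familywise cutoff."""
        return float(self.shuffle_iscs.max())


def _group_isc(comps: np.ndarray) -> np.ndarray:
    """Group-level ISC per component: mean pairwise correlation (fast path)."""
    n_subj, K, T = comps.shape
    yc = comps - comps.mean(axis=2, keepdims=True)
    norm = np.linalg.norm(yc, axis=2)
    norm[norm == 0] = 1.0
    z = yc / norm[:, :, None]
    G = np.einsum("ikt,jkt->kij", z, z)
    # mean over off-diagonal entries
    s = G.sum(axis=(1, 2)) - np.trace(G, axis1=1, axis2=2)
    return s / (n_subj * (n_subj - 1))


def _as_components(
    segments: Sequence, model: CorrCAModel | None
) -> list[np.ndarray]:
    out = []
    for seg in segments:
        if isinstance(seg, SegmentStack):
            if model is None:
                raise ValueError("a model is required to project SegmentStacks")
            out.append(project(seg, model.W))
        else:
            out.append(np.asarray(seg, dtype=float))
    return out


def circular_shift_null(
    segments: Sequence,
    model: CorrCAModel | None = None,
    n_shuffles: int = 100,
    seed: int = 0,
    offset_sampler: Callable[[np.random.Generator, int], int] | None = None,
) -> NullDistribution:
    """Null distribution of component ISC under per-subject circular shifts.

    ``segments`` is a list of :class:`SegmentStack` (projected with
    ``model``) or of pre-projected ``(subjects, K, samples)`` arrays. For
    each shuffle every subject's course in every segment is rotated by an
    independent offset drawn uniformly from ``[1, T - 1]``; group ISC per
    component is the average over segments. ``offset_sampler(rng, T)`` can
    override the offset draw (e.g. forced to 0 in tests, which reproduces
    the unshuffled ISC exactly).
    """
    if n_shuffles < 1:
        raise ValueError(f"n_shuffles must be >= 1, got {n_shuffles}")
    comps = _as_components(segments, model)
    if not comps:
        raise ValueError("no segments given")
    for c in comps:
        if c.shape[2] < 4:
            raise ValueError("segments must have at least 4 samples")
    K = comps[0].shape[1]
    rng = np.random.default_rng(seed)
    if offset_sampler is None:
        offset_sampler = lambda r, T: int(r.integers(1, T))  # noqa: E731

    # The Pearson correlation of two circularly shifted courses depends only
    # on the relative offset, so the pairwise circular cross-correlation at
    # every lag is computed once per segment (FFT) and each shuffle reduces
    # to a lookup at lag (d_i - d_j) mod T.
    shuffle_iscs = np.zeros((n_shuffles, K))
    for c in comps:
        n_subj, _, T = c.shape
        yc = c - c.mean(axis=2, keepdims=True)
        norm = np.linalg.norm(yc, axis=2)
        norm[norm == 0] = 1.0
        z = yc / norm[:, :, None]
        F = np.fft.rfft(z, axis=-1)
        pairs = [(i, j) for i in range(n_subj) for j in range(i + 1, n_subj)]
        # (n_pairs, K, T): correlation of pair (i, j) at every relative lag
        cross = np.fft.irfft(
            np.conj(F[[i for i, _ in pairs]]) * F[[j for _, j in pairs]], n=T, axis=-1
        )
        offsets = np.array(
            [[offset_sampler(rng, T) for _ in range(n_subj)] for _ in range(n_shuffles)]
        )
        lag = np.array(
            [(offsets[:, i] - offsets[:, j]) % T for i, j in pairs]
        )  # (n_pairs, n_shuffles)
        # gather: for each shuffle s, mean over pairs of cross[p, k, lag[p, s]]
        picked = np.take_along_axis(
            cross[:, None, :, :], lag[:, :, None, None], axis=3
        )[..., 0]  # (n_pairs, n_shuffles, K)
        shuffle_iscs += picked.mean(axis=0)
    shuffle_iscs /= len(comps)
    return NullDistribution(shuffle_iscs=shuffle_iscs, n_shuffles=n_shuffles, seed=seed)


# ---------------------------------------------------------------------------
# leave-one-piece-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class LooResult:
    """Held-out ISC per piece plus the per-piece models and projections."""

    table: pd.DataFrame
    models: dict  # piece -> CorrCAModel
    test_components: dict  # (piece, repeat, attention) -> (subjects, K, samples)
    test_masks: dict = field(default_factory=dict)


def loo_crossval(
    stacks: Sequence[SegmentStack],
    k_max: int | None = None,
    shrinkage: float = 0.1,
    train_attention: str = ATTEND,
    subject_meta: Mapping | None = None,
) -> LooResult:
    """Train on all pieces but one; evaluate ISC on the held-out piece.

    For each piece the model is fitted on every *attentive* segment of the
    remaining pieces (all repeats), then ISC is computed on all of the
    held-out piece's segments (including a distract pass when present).
    Results over pieces are concatenated into one long-format table.
    """
    pieces = sorted({s.annotation.piece for s in stacks})
    if len(pieces) < 2:
        raise ValueError(f"need at least 2 pieces, got {len(pieces)}")

    # per-piece covariance sums so each fold is train-total minus held-out
    train_stacks = [
        s for s in stacks if s.annotation.attention == train_attention
    ]
    cov_by_piece = {}
    for p in pieces:
        segs = [s for s in train_stacks if s.annotation.piece == p]
        if not segs:
            logger.warning("piece %s has no training segments; fold skipped", p)
            continue
        cov_by_piece[p] = pooled_covariances(segs)

    rows = []
    models = {}
    test_components = {}
    test_masks = {}
    for p in pieces:
        train_covs = [c for q, c in cov_by_piece.items() if q != p]
        if not train_covs:
            logger.warning("no training data when holding out %s; skipped", p)
            continue
        cov = train_covs[0]
        for c in train_covs[1:]:
            cov = cov + c
        model = fit_model(cov, k_max=k_max, shrinkage=shrinkage)
        models[p] = model
        for stack in (s for s in stacks if s.annotation.piece == p):
            comps = project(stack, model.W)
            ann = stack.annotation
            test_components[(p, ann.repeat, ann.attention)] = comps
            if not stack.fully_valid:
                test_masks[(p, ann.repeat, ann.attention)] = stack.mask
            isc = isc_per_subject(comps, mask=None if stack.fully_valid else stack.mask)
            for i, subj in enumerate(stack.subjects):
                training = (
                    subject_meta[subj]["training"] if subject_meta else "unknown"
                )
                for k in range(model.k):
                    rows.append(
                        {
                            "subject": subj,
                            "piece": p,
                            "repeat": ann.repeat,
                            "familiarity": ann.familiarity,
                            "attention": ann.attention,
                            "training": training,
                            "component": k + 1,
                            "isc": isc[i, k],
                        }
                    )
    return LooResult(
        table=pd.DataFrame(rows),
        models=models,
        test_components=test_components,
        test_masks=test_masks,
    )


def component_test_isc(loo: LooResult, attention: str = ATTEND) -> np.ndarray:
    """Group-level held-out ISC per component (mean over subjects/segments)."""
    tab = loo.table[loo.table["attention"] == attention]
    return (
        tab.groupby("component")["isc"].mean().sort_index().to_numpy()
    )


def select_significant(test_isc: np.ndarray, null: NullDistribution) -> list[int]:
    """1-based indices of components whose held-out ISC beats the threshold."""
    test_isc = np.asarray(test_isc, dtype=float)
    if test_isc.size != null.shuffle_iscs.shape[1]:
        raise ValueError(
            f"component count mismatch: {test_isc.size} vs "
            f"{null.shuffle_iscs.shape[1]}"
        )
    return [int(k + 1) for k in np.flatnonzero(test_isc > null.threshold)]


# ---------------------------------------------------------------------------
# repetition slopes
# ---------------------------------------------------------------------------

@dataclass
class SlopeRecord:
    """OLS slope of ISC against repeat index for one piece/group."""

    piece: str
    group: str
    slope: float  # ISC change per repeat (multiply by 1000 only for reporting)
    intercept: float
    n_repeats: int
    complete: bool = True


def isc_slope(
    isc_by_repeat: Sequence[float],
    piece: str = "",
    group: str = "",
) -> SlopeRecord:
    """Least-squares slope of ISC over repeats 1..R.

    ``NaN`` entries (missing repeats) are dropped from the fit and the
    record is flagged incomplete; at least two finite values are required.
    """
    y = np.asarray(isc_by_repeat, dtype=float)
    x = np.arange(1, y.size + 1, dtype=float)
    ok = np.isfinite(y)
    if ok.sum() < 2:
        raise ValueError("need ISC at >= 2 repeats to fit a slope")
    if not ok.all():
        logger.warning("piece %s: fitting slope on %d of %d repeats", piece, ok.sum(), y.size)
    slope, intercept = np.polyfit(x[ok], y[ok], 1)
    return SlopeRecord(
        piece=piece,
        group=group,
        slope=float(slope),
        intercept=float(intercept),
        n_repeats=int(ok.sum()),
        complete=bool(ok.all()),
    )


def slope_group_test(
    slopes_a: Sequence[float], slopes_b: Sequence[float]
) -> tuple[float, int, float]:
    """Two-sample equal-variance t-test on per-piece slopes.

    Returns ``(t, df, p)`` with ``df = n_a + n_b - 2`` (e.g. df = 18 when
    comparing 10 familiar against 10 unfamiliar pieces).
    """
    a = np.asarray(slopes_a, dtype=float)
    b = np.asarray(slopes_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 pieces per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("degenerate (zero-variance) slope groups")
    res = scipy.stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), int(a.size + b.size - 2), float(res.pvalue)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA (classical balanced sums of squares)
# ---------------------------------------------------------------------------

def aggregate_cells(
    table: pd.DataFrame,
    dv: str,
    subject: str = "subject",
    factors: Sequence[str] = ("repeat", "familiarity"),
) -> pd.DataFrame:
    """Average the dependent variable over pieces within each design cell.

    The ANOVA expects one observation per subject per cell ("averaged across
    stimuli"); this collapses the piece dimension.
    """
    keys = [subject, *factors]
    return table.groupby(keys, as_index=False)[dv].mean()


def _margin_ss(df: pd.DataFrame, dv: str, factors: Sequence[str]) -> float:
    """U(T) = sum over cells of n_cell * mean_cell^2 for the factor set T."""
    if not factors:
        return float(len(df) * df[dv].mean() ** 2)
    g = df.groupby(list(factors))[dv]
    return float((g.count() * g.mean() ** 2).sum())


def _ie_ss(df: pd.DataFrame, dv: str, effect: Sequence[str]) -> float:
    """Inclusion-exclusion sum of squares for a (possibly interaction) effect."""
    effect = list(effect)
    total = 0.0
    for r in range(len(effect) + 1):
        for sub in itertools.combinations(effect, r):
            total += (-1) ** (len(effect) - r) * _margin_ss(df, dv, sub)
    return total


def rm_anova(
    table: pd.DataFrame,
    dv: str,
    subject: str = "subject",
    within: Sequence[str] = ("repeat", "familiarity"),
    between: str | None = None,
) -> pd.DataFrame:
    """Classical sums-of-squares repeated-measures ANOVA.

    Subjects are the random factor; ``within`` factors are crossed with
    subjects and an optional single ``between`` factor (e.g. musical
    training) nests subjects into groups. The design must be complete and
    balanced: exactly one observation per subject per within-cell (aggregate
    over pieces first with :func:`aggregate_cells`) and, with a between
    factor, equal group sizes.

    Error terms follow the classical mixed-model conventions: each within
    effect (and its interaction with the between factor) is tested against
    its interaction with subjects (within groups); the between effect is
    tested against subjects-within-groups.

    Returns a tidy table with one row per effect: ``effect, ss, df1, df2,
    ms, ms_err, F, p``.
    """
    within = list(within)
    if not within and between is None:
        raise ValueError("need at least one factor")
    df = table.copy()
    cells = df.groupby([subject, *within]).size()
    if (cells != 1).any():
        raise ValueError(
            "design is unbalanced: expected exactly one observation per "
            "subject per within-cell; aggregate over pieces first "
            "(see aggregate_cells)"
        )
    n_subj = df[subject].nunique()
    levels = {f: df[f].nunique() for f in within}

    if between is not None:
        groups = df.groupby(subject)[between].nunique()
        if (groups != 1).any():
            raise ValueError("each subject must belong to exactly one between group")
        sizes = df.drop_duplicates(subject).groupby(between).size()
        if sizes.nunique() != 1:
            raise ValueError(f"between groups must be equal size, got {dict(sizes)}")
        n_groups = int(len(sizes))
    else:
        n_groups = 1

    results = []

    def _error_within(effect_within: Sequence[str]) -> tuple[float, int]:
        """SS and df of effect x subjects(within groups)."""
        ew = list(effect_within)
        ss = 0.0
        for r in range(len(ew) + 1):
            for sub in itertools.combinations(ew, r):
                sign = (-1) ** (len(ew) - r)
                ss += sign * _margin_ss(df, dv, [*sub, subject])
                if between is not None:
                    ss -= sign * _margin_ss(df, dv, [*sub, between])
                else:
                    ss -= sign * _margin_ss(df, dv, sub)
        dfe = int(np.prod([levels[f] - 1 for f in ew])) * (n_subj - n_groups)
        return ss, dfe

    # between-subject effect
    if between is not None:
        ss_g = _ie_ss(df, dv, [between])
        df_g = n_groups - 1
        ss_err = _margin_ss(df, dv, [subject]) - _margin_ss(df, dv, [between])
        df_err = n_subj - n_groups
        F = (ss_g / df_g) / (ss_err / df_err)
        results.append((between, ss_g, df_g, df_err, ss_err, F))

    # within effects and their interactions (incl. with the between factor)
    for r in range(1, len(within) + 1):
        for combo in itertools.combinations(within, r):
            for with_g in ([False, True] if between is not None else [False]):
                effect = list(combo) + ([between] if with_g else [])
                ss_e = _ie_ss(df, dv, effect)
                df_e = int(np.prod([levels[f] - 1 for f in combo])) * (
                    (n_groups - 1) if with_g else 1
                )
                ss_err, df_err = _error_within(combo)
                F = (ss_e / df_e) / (ss_err / df_err)
                results.append((" x ".join(effect), ss_e, df_e, df_err, ss_err, F))

    out = pd.DataFrame(
        results, columns=["effect", "ss", "df1", "df2", "ss_err", "F"]
    )
    out["ms"] = out["ss"] / out["df1"]
    out["ms_err"] = out["ss_err"] / out["df2"]
    out["p"] = scipy.stats.f.sf(out["F"], out["df1"], out["df2"])
    out.attrs["design"] = {
        "within": within,
        "between": between,
        "n_subjects": n_subj,
        "repeated_factor": subject,
    }
    return out[["effect", "ss", "df1", "df2", "ms", "ms_err", "F", "p"]]


# ---------------------------------------------------------------------------
# attend/distract contrast and preference split
# ---------------------------------------------------------------------------

def attend_distract_delta(summed: pd.DataFrame) -> pd.DataFrame:
    """Per-subject attention effect by familiarity.

    Delta(subject, familiarity) is the mean over pieces of the difference
    between the first attentive repetition's summed ISC and the distracted
    pass's summed ISC. Pieces without a distract run are excluded (logged).
    """
    att = summed[(summed["attention"] == "attend") & (summed["repeat"] == 1)]
    dis = summed[summed["attention"] == "distract"]
    keys = ["subject", "piece", "familiarity"]
    merged = att.merge(dis, on=keys, suffixes=("_att", "_dis"))
    missing = set(map(tuple, att[keys].values)) - set(map(tuple, merged[keys].values))
    if missing:
        logger.warning(
            "%d (subject, piece) cells lack a distract run; excluded", len(missing)
        )
    merged["delta"] = merged["isc_sum_att"] - merged["isc_sum_dis"]
    extra = ["training_att"] if "training_att" in merged.columns else []
    out = merged.groupby(["subject", "familiarity", *extra], as_index=False)["delta"].mean()
    if extra:
        out = out.rename(columns={"training_att": "training"})
    return out


def preference_split(ratings: Mapping[str, float], table: pd.DataFrame) -> pd.DataFrame:
    """Median-split pieces into high/low preference groups.

    Pieces are sorted by mean rating (ties broken by ascending piece id, so
    group sizes stay as equal as possible and the split is deterministic);
    the lower half is labelled ``low``, the upper half ``high``. Returns the
    table with a ``preference`` column. Identical ratings everywhere admit
    no split and are rejected.
    """
    if len(set(ratings.values())) < 2:
        raise ValueError("all preference ratings identical: no split possible")
    order = sorted(ratings, key=lambda p: (ratings[p], p))
    n_low = len(order) // 2
    group = {p: ("low" if i < n_low else "high") for i, p in enumerate(order)}
    missing = set(table["piece"].unique()) - set(group)
    if missing:
        raise ValueError(f"no rating for pieces: {sorted(missing)}")
    out = table.copy()
    out["preference"] = out["piece"].map(group)
    return out
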