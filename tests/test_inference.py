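"""Permutation null, cross-validation, slopes and ANOVA against oracles."""

import numpy as np
import pandas as pd
import pytest

from iscmusic.corrca import fit_model, pooled_covariances, project, summed_isc
from iscmusic.inference import (
    NullDistribution,
    _group_isc,
    aggregate_cells,
    attend_distract_delta,
    circular_shift_null,
    component_test_isc,
    isc_slope,
    loo_crossval,
    preference_split,
    rm_anova,
    select_significant,
    slope_group_test,
)


class TestCircularShiftNull:
    def test_zero_offsets_reproduce_original_isc(self, rng):
        comps = [rng.standard_normal((4, 3, 64)) for _ in range(2)]
        null = circular_shift_null(
            comps, n_shuffles=1, seed=0, offset_sampler=lambda r, T: 0
        )
        orig = np.mean([_group_isc(c) for c in comps], axis=0)
        np.testing.assert_allclose(null.shuffle_iscs[0], orig, atol=1e-12)

    def test_shift_preserves_sample_multiset(self, rng):
        """Rotation leaves per-subject variance untouched, so shuffle ISCs
        stay in [-1, 1] and the threshold is their max."""
        comps = [rng.standard_normal((3, 2, 50))]
        null = circular_shift_null(comps, n_shuffles=20, seed=1)
        assert np.abs(null.shuffle_iscs).max() <= 1.0 + 1e-12
        assert null.threshold == null.shuffle_iscs.max()

    def test_matches_naive_roll_implementation(self, rng):
        comps = [rng.standard_normal((3, 2, 40))]
        forced = lambda r, T: 13  # noqa: E731
        null = circular_shift_null(comps, n_shuffles=1, seed=0, offset_sampler=forced)
        rolled = np.stack([np.roll(comps[0][i], 13, axis=-1) for i in range(3)])
        np.testing.assert_allclose(null.shuffle_iscs[0], _group_isc(rolled), atol=1e-12)

    def test_too_short_segments_rejected(self, rng):
        with pytest.raises(ValueError, match="4 samples"):
            circular_shift_null([rng.standard_normal((3, 2, 3))], n_shuffles=1)

    def test_shuffle_count_validated(self, rng):
        with pytest.raises(ValueError, match="n_shuffles"):
            circular_shift_null([rng.standard_normal((3, 2, 40))], n_shuffles=0)


class TestSelectSignificant:
    def test_threshold_comparison(self):
        null = NullDistribution(
            shuffle_iscs=np.full((2, 3), 0.01), n_shuffles=2, seed=0
        )
        assert select_significant(np.array([0.04, 0.02, 0.004]), null) == [1, 2]

    def test_all_below_threshold_empty(self):
        null = NullDistribution(shuffle_iscs=np.full((1, 2), 0.5), n_shuffles=1, seed=0)
        assert select_significant(np.array([0.1, 0.2]), null) == []

    def test_component_count_mismatch(self):
        null = NullDistribution(shuffle_iscs=np.zeros((1, 2)), n_shuffles=1, seed=0)
        with pytest.raises(ValueError, match="mismatch"):
            select_significant(np.zeros(3), null)


class TestLooCrossval:
    def test_piece_count_bookkeeping(self, small_study):
        stacks, _, meta = small_study
        loo = loo_crossval(stacks, k_max=4, subject_meta=meta)
        assert set(loo.models) == {"piece01", "piece02", "piece03"}
        # every (piece, repeat) evaluated held-out
        assert len(loo.test_components) == 6

    def test_identical_pieces_symmetric(self, rng):
        from tests.test_corrca import _stack

        X = rng.standard_normal((4, 5, 200))
        shared = rng.standard_normal((1, 5, 200)) * 2
        tensor = X + shared
        s1 = _stack(tensor, piece="pA")
        s2 = _stack(tensor.copy(), piece="pB")
        loo = loo_crossval([s1, s2], k_max=3)
        a = loo.table[loo.table["piece"] == "pA"]["isc"].to_numpy()
        b = loo.table[loo.table["piece"] == "pB"]["isc"].to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_heldout_isc_close_to_train_at_high_snr(self, small_study):
        stacks, _, meta = small_study
        loo = loo_crossval(stacks, k_max=4, subject_meta=meta)
        test_isc = component_test_isc(loo)[0]
        model = fit_model(pooled_covariances(stacks), k_max=4)
        comps = np.concatenate([project(s, model.W) for s in stacks], axis=2)
        train_isc = _group_isc(comps)[0]
        assert abs(test_isc - train_isc) / train_isc < 0.2

    def test_single_piece_rejected(self, small_study):
        stacks, _, _ = small_study
        only = [s for s in stacks if s.annotation.piece == "piece01"]
        with pytest.raises(ValueError, match="2 pieces"):
            loo_crossval(only)


class TestSlopes:
    def test_exact_line(self):
        rec = isc_slope([0.03, 0.02, 0.01])
        assert abs(rec.slope - (-0.01)) < 1e-14
        assert abs(rec.slope * 1000 - (-10.0)) < 1e-10

    def test_constant_isc_zero_slope(self):
        assert abs(isc_slope([0.02, 0.02, 0.02]).slope) < 1e-14

    def test_matches_closed_form_ols(self, rng):
        for _ in range(20):
            y = rng.standard_normal(3)
            x = np.array([1.0, 2.0, 3.0])
            beta = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
            assert abs(isc_slope(y).slope - beta) < 1e-14

    def test_missing_repeat_flagged(self):
        rec = isc_slope([0.03, np.nan, 0.01])
        assert not rec.complete and rec.n_repeats == 2

    def test_group_test_identical_groups(self):
        t, df, p = slope_group_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and df == 4 and abs(p - 1.0) < 1e-12

    def test_group_test_textbook_formula(self, rng):
        a = rng.standard_normal(10)
        b = rng.standard_normal(10) + 0.5
        t, df, p = slope_group_test(a, b)
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
        t_ref = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        assert abs(t - t_ref) < 1e-12
        assert df == 18

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            slope_group_test([1.0, 1.0], [1.0, 1.0])


def _within_table(rng, n_subj=6, levels_a=3, levels_b=2, effect=0.0):
    rows = []
    for s in range(n_subj):
        off = rng.standard_normal()
        for a in range(levels_a):
            for b in range(levels_b):
                rows.append(
                    {
                        "subject": f"s{s}",
                        "repeat": a,
                        "familiarity": b,
                        "y": off + effect * a * b + rng.standard_normal(),
                    }
                )
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_null_effect_has_zero_ss(self, rng):
        rows = []
        for s in range(5):
            off = rng.standard_normal()
            for a in range(3):
                for b in range(2):
                    rows.append(
                        {"subject": f"s{s}", "repeat": a, "familiarity": b, "y": off}
                    )
        res = rm_anova(pd.DataFrame(rows), "y", within=["repeat", "familiarity"])
        assert (res["ss"].abs() < 1e-20).all()

    def test_two_condition_f_equals_paired_t_squared(self, rng):
        import scipy.stats

        rows = []
        vals = {}
        for s in range(8):
            vals[s] = rng.standard_normal(2) + [0.0, 0.4]
            for c in range(2):
                rows.append({"subject": f"s{s}", "cond": c, "y": vals[s][c]})
        res = rm_anova(pd.DataFrame(rows), "y", within=["cond"])
        diffs = np.array([vals[s][1] - vals[s][0] for s in range(8)])
        t = scipy.stats.ttest_1samp(diffs, 0.0).statistic
        assert abs(res["F"].iloc[0] - t**2) < 1e-10

    def test_matches_pingouin_two_way_within(self, rng):
        pg = pytest.importorskip("pingouin")
        df = _within_table(rng, effect=0.3)
        res = rm_anova(df, "y", within=["repeat", "familiarity"])
        ref = pg.rm_anova(
            data=df, dv="y", within=["repeat", "familiarity"], subject="subject"
        )
        np.testing.assert_allclose(res["F"].to_numpy(), ref["F"].to_numpy(), rtol=1e-8)
        np.testing.assert_allclose(
            res["p"].to_numpy(), ref["p_unc"].to_numpy(), rtol=1e-8
        )

    def test_matches_pingouin_mixed_design(self, rng):
        pg = pytest.importorskip("pingouin")
        rows = []
        for s in range(10):
            g = "trained" if s < 5 else "untrained"
            off = rng.standard_normal()
            for a in range(3):
                rows.append(
                    {
                        "subject": f"s{s}",
                        "training": g,
                        "repeat": a,
                        "y": off + (0.5 if g == "trained" else 0) + 0.2 * a
                        + rng.standard_normal(),
                    }
                )
        df = pd.DataFrame(rows)
        res = rm_anova(df, "y", within=["repeat"], between="training")
        ref = pg.mixed_anova(
            data=df, dv="y", within="repeat", between="training", subject="subject"
        )
        np.testing.assert_allclose(res["F"].to_numpy(), ref["F"].to_numpy(), rtol=1e-8)
        assert list(res["df1"]) == list(ref["DF1"])
        assert list(res["df2"]) == list(ref["DF2"])

    def test_matches_hand_ss_decomposition_2x2(self, rng):
        """Brute-force sums of squares on a 4-subject 2x2 within design."""
        df = _within_table(rng, n_subj=4, levels_a=2, levels_b=2, effect=0.5)
        res = rm_anova(df, "y", within=["repeat", "familiarity"])
        y = df.pivot_table(
            index="subject", columns=["repeat", "familiarity"], values="y"
        ).to_numpy()  # (4 subjects, 4 cells ordered a0b0 a0b1 a1b0 a1b1)
        grand = y.mean()
        a_means = np.array([y[:, :2].mean(), y[:, 2:].mean()])
        b_means = np.array([y[:, [0, 2]].mean(), y[:, [1, 3]].mean()])
        ss_a = 8 * ((a_means - grand) ** 2).sum()
        ss_b = 8 * ((b_means - grand) ** 2).sum()
        cell_means = y.mean(axis=0).reshape(2, 2)
        ss_ab = 4 * (
            (cell_means - a_means[:, None] - b_means[None, :] + grand) ** 2
        ).sum()
        got = dict(zip(res["effect"], res["ss"]))
        assert abs(got["repeat"] - ss_a) < 1e-8
        assert abs(got["familiarity"] - ss_b) < 1e-8
        assert abs(got["repeat x familiarity"] - ss_ab) < 1e-8

    def test_unbalanced_design_instructs_aggregation(self, rng):
        df = _within_table(rng)
        df = pd.concat([df, df.iloc[[0]]])  # duplicate one observation
        with pytest.raises(ValueError, match="aggregate"):
            rm_anova(df, "y", within=["repeat", "familiarity"])

    def test_aggregate_cells_averages_pieces(self):
        df = pd.DataFrame(
            {
                "subject": ["a"] * 4,
                "repeat": [1, 1, 2, 2],
                "familiarity": ["f"] * 4,
                "piece": ["p1", "p2", "p1", "p2"],
                "isc_sum": [0.1, 0.3, 0.2, 0.4],
            }
        )
        agg = aggregate_cells(df, "isc_sum", factors=["repeat", "familiarity"])
        assert len(agg) == 2
        np.testing.assert_allclose(sorted(agg["isc_sum"]), [0.2, 0.3])


class TestAttendDistract:
    def _summed(self, shift=0.0):
        rows = []
        for subj in ("a", "b"):
            for piece in ("p1", "p2", "p3"):
                for att, rep in (("attend", 1), ("attend", 2), ("distract", 1)):
                    base = 0.1 + 0.01 * (subj == "b")
                    val = base + (shift if att == "attend" else 0.0)
                    rows.append(
                        {
                            "subject": subj,
                            "piece": piece,
                            "repeat": rep,
                            "familiarity": "familiar",
                            "attention": att,
                            "training": "trained",
                            "isc_sum": val,
                        }
                    )
        return pd.DataFrame(rows)

    def test_equal_conditions_zero_delta(self):
        out = attend_distract_delta(self._summed(0.0))
        np.testing.assert_allclose(out["delta"], 0.0, atol=1e-14)

    def test_constant_shift_recovered(self):
        out = attend_distract_delta(self._summed(0.01))
        np.testing.assert_allclose(out["delta"], 0.01, atol=1e-14)

    def test_matches_explicit_loop(self, rng):
        tab = self._summed()
        tab["isc_sum"] = rng.standard_normal(len(tab))
        out = attend_distract_delta(tab)
        for subj in ("a", "b"):
            deltas = []
            for piece in ("p1", "p2", "p3"):
                att = tab[
                    (tab.subject == subj)
                    & (tab.piece == piece)
                    & (tab.attention == "attend")
                    & (tab["repeat"] == 1)
                ]["isc_sum"].iloc[0]
                dis = tab[
                    (tab.subject == subj)
                    & (tab.piece == piece)
                    & (tab.attention == "distract")
                ]["isc_sum"].iloc[0]
                deltas.append(att - dis)
            got = out[(out.subject == subj)]["delta"].iloc[0]
            assert abs(got - np.mean(deltas)) < 1e-12


class TestPreferenceSplit:
    def _table(self, pieces):
        return pd.DataFrame({"piece": pieces, "isc_sum": np.arange(len(pieces))})

    def test_distinct_ratings_equal_groups(self):
        pieces = [f"p{i:02d}" for i in range(20)]
        ratings = {p: float(i) for i, p in enumerate(pieces)}
        out = preference_split(ratings, self._table(pieces))
        assert (out["preference"] == "low").sum() == 10
        assert (out["preference"] == "high").sum() == 10

    def test_tie_broken_by_piece_id(self):
        ratings = {"pA": 1.0, "pB": 2.0, "pC": 2.0, "pD": 3.0}
        out = preference_split(ratings, self._table(["pA", "pB", "pC", "pD"]))
        by_piece = dict(zip(out["piece"], out["preference"]))
        # pB sorts before pC at the tied rating -> pB low, pC high
        assert by_piece == {"pA": "low", "pB": "low", "pC": "high", "pD": "high"}

    def test_identical_ratings_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            preference_split({"a": 2.0, "b": 2.0}, self._table(["a", "b"]))

    def test_preference_familiarity_correlation_oracle(self, rng):
        pref = rng.standard_normal(12)
        fam = 0.6 * pref + 0.8 * rng.standard_normal(12)
        r = np.corrcoef(pref, fam)[0, 1]
        pd_ = pref - pref.mean()
        fd = fam - fam.mean()
        r_ref = (pd_ * fd).sum() / np.sqrt((pd_**2).sum() * (fd**2).sum())
        assert abs(r - r_ref) < 1e-12
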