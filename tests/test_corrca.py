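"""Correlated component analysis against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from iscmusic.corrca import (
    CorrCAModel,
    fit_model,
    isc_per_subject,
    isc_table,
    pooled_covariances,
    project,
    summed_isc,
)
from iscmusic.datatypes import Annotation, SegmentStack


def _stack(tensor, mask=None, **ann_kw):
    defaults = dict(
        piece="p1", repeat=1, familiarity="familiar", attention="attend",
        onset_s=0.0, duration_s=tensor.shape[2] / 128.0,
    )
    defaults.update(ann_kw)
    n_subj = tensor.shape[0]
    return SegmentStack(
        tensor=tensor,
        rate=128.0,
        annotation=Annotation(**defaults),
        subjects=[f"s{i}" for i in range(n_subj)],
        channel_labels=[f"c{i}" for i in range(tensor.shape[1])],
        mask=mask,
    )


def _brute_force_cov(tensor):
    """Double-loop pairwise covariance sums (independent oracle)."""
    n_subj, n_chan, _ = tensor.shape
    X = tensor - tensor.mean(axis=2, keepdims=True)
    R_w = np.zeros((n_chan, n_chan))
    R_b = np.zeros((n_chan, n_chan))
    for i in range(n_subj):
        for j in range(n_subj):
            C = X[i] @ X[j].T
            if i == j:
                R_w += C
            else:
                R_b += C
    return R_w, R_b


class TestPooledCovariances:
    def test_identical_subjects_degenerate(self, rng):
        X = rng.standard_normal((5, 50))
        cov = pooled_covariances(_stack(np.stack([X, X])))
        Xd = X - X.mean(axis=1, keepdims=True)
        C = Xd @ Xd.T
        np.testing.assert_allclose(cov.R_w, 2 * C, atol=1e-10)
        np.testing.assert_allclose(cov.R_b, 2 * C, atol=1e-10)

    def test_matches_double_loop_oracle(self, rng):
        tensor = rng.standard_normal((3, 5, 50))
        cov = pooled_covariances(_stack(tensor))
        R_w, R_b = _brute_force_cov(tensor)
        np.testing.assert_allclose(cov.R_w, R_w, rtol=1e-12, atol=1e-12)
        np.testing.assert_allclose(cov.R_b, R_b, rtol=1e-12, atol=1e-10)

    def test_independent_noise_has_small_between(self, rng):
        tensor = rng.standard_normal((4, 3, 20000))
        cov = pooled_covariances(_stack(tensor))
        assert np.linalg.norm(cov.R_b) / np.linalg.norm(cov.R_w) < 0.05

    def test_segments_add(self, rng):
        t1 = rng.standard_normal((3, 4, 60))
        t2 = rng.standard_normal((3, 4, 80))
        both = pooled_covariances([_stack(t1), _stack(t2)])
        single = pooled_covariances(_stack(t1)) + pooled_covariances(_stack(t2))
        np.testing.assert_allclose(both.R_b, single.R_b, atol=1e-10)
        assert both.n_samples_effective == 140

    def test_masked_samples_excluded_pairwise(self, rng):
        tensor = rng.standard_normal((3, 4, 100))
        mask = np.ones((3, 100), dtype=bool)
        mask[0, :30] = False
        mask[2, 60:] = False
        cov = pooled_covariances(_stack(tensor, mask=mask))
        # oracle: demean per subject over its valid samples, then pairwise
        X = np.array(
            [tensor[i] - tensor[i][:, mask[i]].mean(axis=1, keepdims=True)
             for i in range(3)]
        )
        R_b = np.zeros((4, 4))
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                v = mask[i] & mask[j]
                R_b += X[i][:, v] @ X[j][:, v].T
        np.testing.assert_allclose(cov.R_b, 0.5 * (R_b + R_b.T), atol=1e-10)

    def test_single_subject_rejected(self, rng):
        with pytest.raises(ValueError, match="2 subjects"):
            pooled_covariances(_stack(rng.standard_normal((1, 4, 50))))


class TestFitModel:
    def test_identical_subjects_equal_eigenvalues(self, rng):
        X = rng.standard_normal((4, 200))
        cov = pooled_covariances(_stack(np.stack([X, X])))
        model = fit_model(cov, shrinkage=0.0)
        np.testing.assert_allclose(model.eigenvalues, 1.0, atol=1e-8)

    def test_whitened_limit_reduces_to_rb_eigenvectors(self, rng):
        from iscmusic.corrca import PooledCovariances

        B = rng.standard_normal((5, 5))
        R_b = B + B.T
        cov = PooledCovariances(
            R_w=np.eye(5), R_b=R_b, n_subjects=2, n_samples_effective=100
        )
        model = fit_model(cov, shrinkage=1.0)
        evals = np.linalg.eigvalsh(R_b)[::-1]
        np.testing.assert_allclose(model.eigenvalues, evals, atol=1e-10)
        for k in range(5):
            resid = R_b @ model.W[:, k] - model.eigenvalues[k] * model.W[:, k]
            assert np.abs(resid).max() < 1e-8

    def test_single_source_forward_model_recovered(self, small_study):
        stacks, truth, _ = small_study
        cov = pooled_covariances(stacks)
        model = fit_model(cov, k_max=4)
        a = truth.mixing[:, 0]
        cos = abs(model.A[:, 0] @ a) / np.linalg.norm(model.A[:, 0])
        assert cos >= 0.95

    def test_eigenvalue_order_matches_component_isc(self, small_study):
        stacks, truth, _ = small_study
        cov = pooled_covariances(stacks)
        model = fit_model(cov, k_max=4)
        comps = np.concatenate(
            [project(s, model.W) for s in stacks], axis=2
        )
        isc = isc_per_subject(comps).mean(axis=0)
        assert isc[0] > isc[1] > isc[2]  # planted 1.0 > 0.7 > noise

    def test_near_singular_without_shrinkage_instructs(self, rng):
        tensor = rng.standard_normal((2, 6, 100))
        tensor[:, 5] = tensor[:, 4]  # duplicated channel -> singular R_w
        cov = pooled_covariances(_stack(tensor))
        with pytest.raises(np.linalg.LinAlgError, match="shrinkage"):
            fit_model(cov, shrinkage=0.0)
        fit_model(cov, shrinkage=0.1)  # regularized fit succeeds

    def test_k_max_validated(self, rng):
        cov = pooled_covariances(_stack(rng.standard_normal((2, 4, 50))))
        with pytest.raises(ValueError, match="k_max"):
            fit_model(cov, k_max=5)

    def test_sign_convention_deterministic(self, small_study):
        stacks, _, _ = small_study
        cov = pooled_covariances(stacks)
        model = fit_model(cov)
        peaks = model.A[np.abs(model.A).argmax(axis=0), range(model.k)]
        assert (peaks > 0).all()

    def test_forward_model_projection_consistency(self, small_study):
        """W^T A = I: reconstructing channels from components and
        re-projecting returns the components exactly."""
        stacks, _, _ = small_study
        model = fit_model(pooled_covariances(stacks), k_max=5)
        np.testing.assert_allclose(model.W.T @ model.A, np.eye(5), atol=1e-10)


class TestProjectAndISC:
    def test_one_hot_projection_selects_electrode(self, rng):
        tensor = rng.standard_normal((2, 4, 30))
        W = np.zeros((4, 1))
        W[2, 0] = 1.0
        comps = project(_stack(tensor), W)
        np.testing.assert_array_equal(comps[:, 0, :], tensor[:, 2, :])

    def test_projection_matches_matmul_oracle(self, rng):
        tensor = rng.standard_normal((3, 5, 40))
        W = rng.standard_normal((5, 2))
        comps = project(_stack(tensor), W)
        for i in range(3):
            np.testing.assert_allclose(comps[i], W.T @ tensor[i], atol=1e-12)

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            project(_stack(rng.standard_normal((2, 4, 30))), np.zeros((5, 1)))

    def test_identical_components_give_isc_one(self, rng):
        y = rng.standard_normal((1, 2, 100))
        comps = np.repeat(y, 4, axis=0)
        np.testing.assert_allclose(isc_per_subject(comps), 1.0, atol=1e-12)

    def test_anticorrelated_pair(self, rng):
        y = rng.standard_normal((1, 1, 100))
        comps = np.concatenate([y, -y], axis=0)
        np.testing.assert_allclose(isc_per_subject(comps), -1.0, atol=1e-12)

    def test_matches_double_loop_pearson_oracle(self, rng):
        comps = rng.standard_normal((4, 3, 60))
        isc = isc_per_subject(comps)
        for i in range(4):
            for k in range(3):
                rs = [
                    np.corrcoef(comps[i, k], comps[j, k])[0, 1]
                    for j in range(4)
                    if j != i
                ]
                assert abs(isc[i, k] - np.mean(rs)) < 1e-12

    def test_masked_isc_matches_pairwise_exclusion_oracle(self, rng):
        comps = rng.standard_normal((3, 2, 80))
        mask = np.ones((3, 80), dtype=bool)
        mask[1, 40:] = False
        isc = isc_per_subject(comps, mask=mask)
        for i in range(3):
            rs = []
            for j in range(3):
                if j == i:
                    continue
                v = mask[i] & mask[j]
                rs.append(np.corrcoef(comps[i, 0, v], comps[j, 0, v])[0, 1])
            assert abs(isc[i, 0] - np.mean(rs)) < 1e-12


class TestSummedISC:
    def _table(self):
        rows = []
        for subj in ("a", "b"):
            for comp, val in ((1, 0.02), (2, 0.01), (3, 0.005)):
                rows.append(
                    {
                        "subject": subj,
                        "piece": "p1",
                        "repeat": 1,
                        "familiarity": "familiar",
                        "attention": "attend",
                        "training": "trained",
                        "component": comp,
                        "isc": val,
                    }
                )
        return pd.DataFrame(rows)

    def test_single_component_passthrough(self):
        out = summed_isc(self._table(), [1])
        np.testing.assert_allclose(out["isc_sum"], 0.02)

    def test_two_components_add(self):
        out = summed_isc(self._table(), [1, 2])
        np.testing.assert_allclose(out["isc_sum"], 0.03)

    def test_empty_set_flagged(self):
        out = summed_isc(self._table(), [])
        assert (out["isc_sum"] == 0).all()
        assert out.attrs["no_significant_components"]

    def test_random_table_vs_hand_sum(self, rng):
        tab = self._table()
        tab["isc"] = rng.standard_normal(len(tab))
        out = summed_isc(tab, [1, 3])
        for subj in ("a", "b"):
            expected = tab[
                (tab["subject"] == subj) & (tab["component"].isin([1, 3]))
            ]["isc"].sum()
            got = out.loc[out["subject"] == subj, "isc_sum"].iloc[0]
            assert abs(got - expected) < 1e-12

    def test_unknown_component_rejected(self):
        with pytest.raises(ValueError, match="not present"):
            summed_isc(self._table(), [9])


def test_model_dict_round_trip(small_study):
    stacks, _, _ = small_study
    model = fit_model(pooled_covariances(stacks), k_max=3)
    again = CorrCAModel.from_dict(model.to_dict())
    np.testing.assert_allclose(again.W, model.W, atol=1e-15)
    np.testing.assert_allclose(again.A, model.A, atol=1e-15)
    np.testing.assert_allclose(again.eigenvalues, model.eigenvalues, atol=1e-15)


def test_isc_table_long_format(small_study):
    stacks, _, meta = small_study
    model = fit_model(pooled_covariances(stacks), k_max=3)
    tab = isc_table(stacks, model, meta)
    assert len(tab) == 6 * len(stacks) * 3  # subjects x segments x components
    assert tab["isc"].between(-1, 1).all()
    assert set(tab["training"]) == {"trained", "untrained"}
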