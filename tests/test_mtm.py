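"""Macro-to-micro augmentation: splits, weight solving, generation, SVD baseline."""

import numpy as np
import pytest

from microexpr.containers import FeatureMatrix
from microexpr.mtm import (MtMConfig, MtMError, generate_micro, mtm_transform,
                           solve_weights, split_ref_probe, svd_mtm,
                           svd_mtm_model)
from microexpr.synth import make_macro_micro_pair


class TestSplit:
    def test_even_split_counts(self, rng):
        X = rng.uniform(0, 1, (5, 792))
        ref, probe = split_ref_probe(X, 0.5, seed=0)
        assert ref.shape[1] == 396 and probe.shape[1] == 396

    def test_odd_split_probe_gets_floor(self, rng):
        ref, probe = split_ref_probe(rng.uniform(0, 1, (4, 3)), 0.5, seed=1)
        assert ref.shape[1] == 2 and probe.shape[1] == 1

    def test_deterministic(self, rng):
        X = rng.uniform(0, 1, (4, 10))
        a = split_ref_probe(X, seed=5)
        b = split_ref_probe(X, seed=5)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_partition_is_disjoint_and_complete(self, rng):
        X = np.arange(20, dtype=float)[None]
        ref, probe = split_ref_probe(X, seed=3)
        merged = sorted(np.concatenate([ref.ravel(), probe.ravel()]))
        assert merged == list(range(20))

    def test_too_few_columns(self):
        with pytest.raises(MtMError):
            split_ref_probe(np.ones((3, 1)))


class TestSolveWeights:
    def test_planted_solution_residual(self, rng):
        X_ref = rng.uniform(0.1, 1, (30, 6))
        H_star = rng.uniform(0.2, 1, (6, 4))
        res = solve_weights(X_ref, X_ref @ H_star)
        assert res.residual <= 1e-3
        assert res.H_emo.min() >= 0

    def test_one_dimensional_closed_form(self, rng):
        x = rng.uniform(0.1, 1, (20, 1))
        res = solve_weights(x, 2.0 * x)
        assert res.H_emo == pytest.approx(np.array([[2.0]]), abs=1e-6)

    def test_zero_probe(self, rng):
        res = solve_weights(rng.uniform(0.1, 1, (10, 3)), np.zeros((10, 2)))
        assert np.abs(res.H_emo).max() == 0.0
        assert res.residual == 0.0

    def test_residual_trace_non_increasing(self, rng):
        X_ref = rng.uniform(0, 1, (15, 5))
        X_probe = rng.uniform(0, 1, (15, 7))
        res = solve_weights(X_ref, X_probe)
        assert (np.diff(res.residual_trace) <= 1e-10).all()

    def test_kl_loss_variant(self, rng):
        X_ref = rng.uniform(0.1, 1, (20, 4))
        H_star = rng.uniform(0.2, 1, (4, 3))
        res = solve_weights(X_ref, X_ref @ H_star, MtMConfig(loss="kl"))
        assert res.residual <= 1e-2
        assert res.H_emo.min() >= 0

    def test_negative_input_rejected(self, rng):
        with pytest.raises(MtMError, match="non-negative"):
            solve_weights(-np.ones((4, 2)), np.ones((4, 2)))


class TestGenerateMicro:
    def test_identity_weights(self, rng):
        Y = rng.uniform(0, 1, (8, 4))
        assert np.allclose(generate_micro(Y, np.eye(4)), Y)

    def test_scalar_weight(self, rng):
        Y = rng.uniform(0, 1, (8, 1))
        assert np.allclose(generate_micro(Y, np.array([[2.0]])), 2 * Y)

    def test_nonnegative_output(self, rng):
        Y = rng.uniform(0, 1, (8, 4))
        H = rng.uniform(0, 1, (4, 6))
        assert generate_micro(Y, H).min() >= 0

    def test_dimension_mismatch(self):
        with pytest.raises(MtMError, match="mismatch"):
            generate_micro(np.ones((3, 4)), np.ones((5, 2)))


class TestMtMTransform:
    def test_count_conservation_and_provenance(self):
        pair = make_macro_micro_pair(["happy", "disgust", "fear"],
                                     ref_count=5, seed=2)
        aug, results = mtm_transform(pair.X, pair.Y, seed=0)
        for r in results:
            # generated columns == probe columns of that emotion
            n_probe = pair.X.F[:, pair.X.labels == r.emo].shape[1] - \
                (pair.X.labels == r.emo).sum() // 2
            assert r.Y_new.shape[1] == n_probe
            assert r.Y_new.min() >= 0
        assert (aug.provenance == "mtm_augmented").all()
        assert set(aug.labels) == {"happy", "disgust", "fear"}

    def test_small_emotion_count_contract(self, rng):
        # 4 macro (2 ref / 2 probe) and 2 micro samples -> 2 generated
        X = FeatureMatrix(rng.uniform(0.1, 1, (6, 4)), ["joy"] * 4,
                          ["a", "b", "c", "d"], ["original"] * 4)
        Y = FeatureMatrix(rng.uniform(0.1, 1, (5, 2)), ["joy"] * 2,
                          ["m1", "m2"], ["original"] * 2)
        aug, results = mtm_transform(X, Y, seed=1)
        assert aug.n_samples == 2
        assert results[0].H_emo.shape == (2, 2)

    def test_skips_unusable_emotions(self, rng):
        X = FeatureMatrix(rng.uniform(0.1, 1, (4, 5)),
                          ["a", "a", "a", "a", "b"], ["s"] * 5,
                          ["original"] * 5)
        Y = FeatureMatrix(rng.uniform(0.1, 1, (3, 3)), ["a", "a", "c"],
                          ["m"] * 3, ["original"] * 3)
        with pytest.warns(UserWarning, match="skipped"):
            aug, results = mtm_transform(X, Y, emotions=["a", "b", "c"], seed=0)
        assert [r.emo for r in results] == ["a"]


class TestSvdBaseline:
    def test_svd_reconstruction_contract(self, rng):
        m = svd_mtm_model(rng.uniform(0, 1, (10, 4)), rng.uniform(0, 1, (8, 4)))
        assert np.allclose(m.M, m.U @ np.diag(m.S) @ m.Vt, atol=1e-8)
        assert m.R_x.shape[0] == 10 and m.R_y.shape[0] == 8

    def test_exact_column_identity(self, rng):
        # a probe equal to a reference column must reproduce the paired
        # micro column exactly (full-rank linear identity)
        X_ref = rng.uniform(0, 1, (12, 4))
        Y = rng.uniform(0, 1, (7, 4))
        Y_new = svd_mtm(X_ref, Y, X_ref[:, [2]])
        assert np.allclose(Y_new[:, 0], Y[:, 2], atol=1e-6)

    def test_generic_inputs_produce_negatives(self):
        # sparse non-negative inputs (the shape LNMF features take): the
        # orthogonal decomposition forces sign-indefinite weights, so the
        # baseline violates non-negativity — the motivation for the
        # improved transform
        neg = 0
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            X_ref = rng.uniform(0, 1, (30, 8)) * (rng.random((30, 8)) < 0.4)
            Y = rng.uniform(0, 1, (20, 8)) * (rng.random((20, 8)) < 0.4)
            X_probe = rng.uniform(0, 1, (30, 5)) * (rng.random((30, 5)) < 0.4)
            neg += svd_mtm(X_ref, Y, X_probe).min() < -1e-12
        assert neg >= 18

    def test_rank_deficient_warns(self, rng):
        x = rng.uniform(0, 1, (6, 1))
        X_ref = np.hstack([x, x])  # duplicated column -> rank-deficient R_x
        with pytest.warns(UserWarning, match="rank-deficient"):
            svd_mtm(X_ref, rng.uniform(0, 1, (4, 2)), x)
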