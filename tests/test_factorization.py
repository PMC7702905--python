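"""NMF/LNMF multiplicative updates: loss, constraints, recovery, features."""

import numpy as np
import pytest

from microexpr.factorization import (FactorizationError, LNMFConfig, _iterate,
                                     encode_with_fixed_basis, extract_features,
                                     kl_divergence, lnmf_fit, nmf_fit)
from microexpr.synth import make_classed_roi_stacks, make_parts_data

from conftest import support_jaccards


class TestKLDivergence:
    def test_identity_is_zero(self, rng):
        X = rng.uniform(0.1, 1, (5, 6))
        assert kl_divergence(X, X) == pytest.approx(0.0, abs=1e-9)

    def test_scalar_closed_form(self):
        # 1*log(1/2) - 1 + 2
        assert kl_divergence(np.array([[1.0]]), np.array([[2.0]])) == \
            pytest.approx(np.log(0.5) + 1.0)

    def test_zero_log_zero_convention(self):
        assert kl_divergence(np.array([[0.0]]), np.array([[1.0]])) == \
            pytest.approx(1.0)

    def test_shape_mismatch(self):
        with pytest.raises(FactorizationError, match="shape"):
            kl_divergence(np.ones((2, 2)), np.ones((2, 3)))


class TestNmfFit:
    def test_planted_rank3_recovery(self, rng):
        W0 = rng.uniform(0, 1, (50, 3))
        H0 = rng.uniform(0, 1, (3, 40))
        D = W0 @ H0
        m = nmf_fit(D, 3, LNMFConfig(max_iter=2000), seed=0)
        assert m.objective_trace[-1] / np.abs(D).sum() <= 1e-3

    def test_full_rank_near_zero_divergence(self, rng):
        D = rng.uniform(0.1, 1.0, (8, 5))
        m = nmf_fit(D, 5, LNMFConfig(max_iter=5000, tol=1e-15), seed=0)
        assert m.objective_trace[-1] < 1e-6 * D.sum()

    def test_columns_sum_to_one(self, rng):
        D = rng.uniform(0, 1, (20, 15))
        for variant_fit in (nmf_fit, lnmf_fit):
            m = variant_fit(D, 4, LNMFConfig(max_iter=50), seed=1)
            assert np.abs(m.W.sum(axis=0) - 1.0).max() <= 1e-12

    def test_monotone_objective(self, rng):
        D = rng.uniform(0, 1, (30, 20))
        m = nmf_fit(D, 5, LNMFConfig(max_iter=300, tol=1e-14), seed=2)
        tr = m.objective_trace
        assert (np.diff(tr) <= 1e-8 * np.abs(tr[:-1]) + 1e-12).all()

    def test_invalid_inputs(self):
        with pytest.raises(FactorizationError):
            nmf_fit(-np.ones((4, 4)), 2)
        with pytest.raises(FactorizationError):
            nmf_fit(np.ones((4, 4)), 0)
        with pytest.raises(FactorizationError):
            lnmf_fit(np.ones((4, 4)), 5)

    def test_deterministic_trace(self, rng):
        D = rng.uniform(0, 1, (25, 12))
        a = nmf_fit(D, 3, LNMFConfig(max_iter=40), seed=9)
        b = nmf_fit(D, 3, LNMFConfig(max_iter=40), seed=9)
        assert np.array_equal(a.objective_trace, b.objective_trace)
        assert np.array_equal(a.W, b.W)

    def test_update_scale_equivariance(self, rng):
        # scaling D by c with H scaled by c reproduces the same W exactly
        # for the non-sqrt updates (H absorbs the scale)
        D = rng.uniform(0.1, 1, (15, 10))
        W = rng.uniform(0.1, 1, (15, 4))
        W /= W.sum(0, keepdims=True)
        H = rng.uniform(0.1, 1, (4, 10))
        c = 7.3
        W1, H1 = _iterate(D, W.copy(), H.copy(), "nmf_kl", 1e-12)
        W2, H2 = _iterate(c * D, W.copy(), c * H.copy(), "nmf_kl", 1e-12)
        assert np.allclose(W1, W2, atol=1e-9)
        assert np.allclose(c * H1, H2, rtol=1e-9)


class TestLnmfFit:
    def test_planted_parts_support_recovery(self):
        pf = make_parts_data(5, (40, 40), 60, seed=3)
        m = lnmf_fit(pf.D, 5, seed=3)
        err = np.abs(pf.D - m.reconstruction()).sum() / pf.D.sum()
        assert err <= 0.05
        j = support_jaccards(m.W, pf.part_supports)
        assert (j > 0.5).sum() >= 4

    def test_both_variants_reconstruct(self):
        # the square-root update's fixed point is H = W^T(D/WH), which
        # biases reconstruction toward locality: it plateaus at a higher
        # residual than the plain multiplicative update by design
        pf = make_parts_data(4, (24, 24), 30, seed=5)
        bounds = {"lnmf_printed": 0.05, "lnmf_sqrt": 0.25}
        for variant, bound in bounds.items():
            m = lnmf_fit(pf.D, 4, LNMFConfig(max_iter=800), seed=5,
                         variant=variant)
            err = np.linalg.norm(pf.D - m.reconstruction()) / np.linalg.norm(pf.D)
            assert err <= bound, variant

    def test_sqrt_variant_monotone(self, rng):
        D = rng.uniform(0, 1, (30, 20))
        m = lnmf_fit(D, 5, LNMFConfig(max_iter=300, tol=1e-14), seed=4,
                     variant="lnmf_sqrt")
        tr = m.objective_trace
        assert (np.diff(tr) <= 1e-8 * np.abs(tr[:-1]) + 1e-12).all()

    def test_nonnegativity_closure(self, rng):
        D = rng.uniform(0, 1, (20, 10))
        for variant in ("lnmf_printed", "lnmf_sqrt"):
            m = lnmf_fit(D, 3, LNMFConfig(max_iter=100), seed=0, variant=variant)
            assert m.W.min() >= 0 and m.H.min() >= 0

    def test_basis_sparsity_on_parts(self):
        pf = make_parts_data(5, (40, 40), 60, seed=1)
        m = lnmf_fit(pf.D, 5, seed=1)
        # disjoint parts: each basis covers ~1/5 of pixels, so most entries
        # are near zero
        assert m.basis_sparsity > 0.5


class TestEncodeFixedBasis:
    def test_planted_coefficient_residual(self, rng):
        W = rng.uniform(0.1, 1, (40, 6))
        W /= W.sum(0, keepdims=True)
        h = rng.uniform(0.2, 1, 6)
        d = W @ h
        h_hat = encode_with_fixed_basis(W, d, LNMFConfig(max_iter=3000, tol=1e-14))
        rel = np.abs(W @ h_hat - d).sum() / np.abs(d).sum()
        assert rel <= 1e-4

    def test_zero_column_maps_to_zero(self, rng):
        W = rng.uniform(0.1, 1, (10, 3))
        W /= W.sum(0, keepdims=True)
        h = encode_with_fixed_basis(W, np.zeros(10), LNMFConfig(max_iter=200))
        assert np.abs(h).max() <= 1e-6

    def test_nonnegative_output(self, rng):
        W = rng.uniform(0.1, 1, (12, 4))
        W /= W.sum(0, keepdims=True)
        H = encode_with_fixed_basis(W, rng.uniform(0, 1, (12, 7)))
        assert H.min() >= 0

    def test_dimension_mismatch(self, rng):
        with pytest.raises(FactorizationError, match="mismatch"):
            encode_with_fixed_basis(np.ones((5, 2)) / 5, np.ones(4))


class TestExtractFeatures:
    def _stacks(self, seed=11):
        return make_classed_roi_stacks(2, 2, eye_size=(6, 7), mouth_size=(5, 8),
                                       separation=8.0, seed=seed, n_per=2)

    def test_feature_height_is_rank_sum(self):
        stacks, labels, subjects, ids = self._stacks()
        fm, models = extract_features(stacks, (3, 4, 5),
                                      LNMFConfig(max_iter=60), labels,
                                      subjects, ids, seed=0)
        assert fm.dim == 12
        assert fm.n_samples == len(stacks)
        assert set(models) == {"left_eye", "right_eye", "mouth"}

    def test_permuting_samples_permutes_columns(self, rng):
        stacks, labels, subjects, ids = self._stacks()
        fm, _ = extract_features(stacks, (3, 3, 3), LNMFConfig(max_iter=60),
                                 labels, subjects, ids, seed=2)
        perm = rng.permutation(len(stacks))
        fm_p, _ = extract_features([stacks[i] for i in perm], (3, 3, 3),
                                   LNMFConfig(max_iter=60),
                                   [labels[i] for i in perm],
                                   [subjects[i] for i in perm],
                                   [ids[i] for i in perm], seed=2)
        assert np.allclose(fm.F[:, perm], fm_p.F, rtol=1e-6, atol=1e-9)

    def test_mirroring_doubles_columns(self):
        stacks, labels, subjects, ids = self._stacks()
        fm, _ = extract_features(stacks, (3, 3, 3), LNMFConfig(max_iter=40),
                                 labels, subjects, ids, add_mirrored=True)
        n = len(stacks)
        assert fm.n_samples == 2 * n
        assert (fm.provenance[:n] == "original").all()
        assert (fm.provenance[n:] == "mirrored").all()
        assert list(fm.subjects[:n]) == list(fm.subjects[n:])

    def test_inconsistent_sizes_error(self):
        stacks, labels, subjects, ids = self._stacks()
        other, *_ = make_classed_roi_stacks(2, 2, eye_size=(4, 4),
                                            mouth_size=(5, 8), seed=1, n_per=1)
        with pytest.raises(FactorizationError, match="inconsistent"):
            extract_features(stacks + other[:1], (2, 2, 2))
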