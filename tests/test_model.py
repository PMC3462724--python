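import logging

import numpy as np
import pytest

from connmvpa.model import (decision_score, fit_pca, fit_svm, from_json,
                            project, to_json)


class TestPca:
    def test_rank_one_data(self):
        t = np.linspace(-1, 1, 10)
        X = np.column_stack([t, 2 * t])  # points on a line through the origin
        pca = fit_pca(X, 2)
        total = np.trace(np.cov(X, rowvar=False))
        assert pca.eigenvalues[0] == pytest.approx(total)
        # d capped at n-1 but second direction carries nothing
        if pca.n_components > 1:
            assert pca.eigenvalues[1] == pytest.approx(0.0, abs=1e-12)

    def test_mean_projects_to_zero(self, rng):
        X = rng.standard_normal((15, 6)) + 3.0
        pca = fit_pca(X, 3)
        assert np.allclose(project(pca, pca.mean), 0.0, atol=1e-12)

    def test_matches_covariance_eigendecomposition(self, rng):
        X = rng.standard_normal((20, 8))
        pca = fit_pca(X, 3)
        cov = np.cov(X, rowvar=False)
        vals, vecs = np.linalg.eigh(cov)
        vals, vecs = vals[::-1], vecs[:, ::-1]
        assert np.allclose(pca.eigenvalues, vals[:3], atol=1e-10)
        for c in range(3):
            ref = vecs[:, c]
            if ref[np.argmax(np.abs(ref))] < 0:
                ref = -ref
            assert np.allclose(pca.components[:, c], ref, atol=1e-8)

    def test_orthonormal_columns(self, rng):
        pca = fit_pca(rng.standard_normal((25, 10)), 5)
        assert np.allclose(pca.components.T @ pca.components, np.eye(5), atol=1e-8)

    def test_d_capped_with_warning(self, rng, caplog):
        with caplog.at_level(logging.WARNING):
            pca = fit_pca(rng.standard_normal((5, 10)), 9)
        assert pca.n_components == 4
        assert "capping" in caplog.text

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(np.ones((5, 3)), 2)

    def test_projection_isometry_at_full_rank(self, rng):
        X = rng.standard_normal((8, 5))
        pca = fit_pca(X, 5)
        proj = project(pca, X)
        from scipy.spatial.distance import pdist
        assert np.allclose(pdist(X), pdist(proj), atol=1e-8)


class TestSvm:
    def test_symmetric_1d_margin(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array([-1, 1])
        svm = fit_svm(X, y, C=100.0)
        assert svm.w[0] == pytest.approx(1.0, abs=1e-6)
        assert svm.b == pytest.approx(0.0, abs=1e-6)

    def test_label_flip_negates_parameters(self, rng):
        X = rng.standard_normal((20, 3))
        y = np.array([-1] * 10 + [1] * 10)
        a, b = fit_svm(X, y, 1.0), fit_svm(X, -y, 1.0)
        assert np.allclose(a.w, -b.w, atol=1e-6)
        assert a.b == pytest.approx(-b.b, abs=1e-6)

    def test_separable_blobs_fit_exactly(self, rng):
        X = np.vstack([rng.standard_normal((15, 2)) - 4,
                       rng.standard_normal((15, 2)) + 4])
        y = np.array([-1] * 15 + [1] * 15)
        svm = fit_svm(X, y, C=100.0)
        margins = y * (X @ svm.w - svm.b)
        assert np.all(margins >= 1 - 1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_svm(np.random.default_rng(0).standard_normal((5, 2)),
                    np.ones(5, dtype=int), 1.0)


class TestDecisionScore:
    def test_two_step_equals_back_projected_form(self, rng):
        # (U w)^T (x - mean) - b must equal w^T U^T (x - mean) - b
        for _ in range(200):
            k, d = rng.integers(3, 12), rng.integers(1, 4)
            X = rng.standard_normal((int(k) + 3, int(k)))
            pca = fit_pca(X, int(d))
            w = rng.standard_normal(pca.n_components)
            b = float(rng.standard_normal())
            from connmvpa.model import SvmModel
            svm = SvmModel(w, b, 1.0)
            x = rng.standard_normal(int(k))
            y_two_step, _ = decision_score(pca, svm, x)
            lam = pca.components @ w
            y_direct = lam @ (x - pca.mean) - b
            assert y_two_step == pytest.approx(y_direct, abs=1e-10)

    def test_score_at_mean_is_minus_b(self, rng):
        X = rng.standard_normal((10, 4))
        pca = fit_pca(X, 2)
        from connmvpa.model import SvmModel
        svm = SvmModel(np.array([1.0, -2.0]), 0.7, 1.0)
        score, label = decision_score(pca, svm, pca.mean)
        assert score == pytest.approx(-0.7)
        assert label == -1  # Y <= 0 is the patient side

    def test_dimension_mismatch_rejected(self, rng):
        X = rng.standard_normal((10, 4))
        pca = fit_pca(X, 2)
        from connmvpa.model import SvmModel
        svm = SvmModel(np.array([1.0, 1.0, 1.0]), 0.0, 1.0)
        with pytest.raises(ValueError):
            decision_score(pca, svm, np.zeros(4))


class TestSerialization:
    def test_json_round_trip(self, rng):
        X = rng.standard_normal((12, 5))
        y = np.array([-1] * 6 + [1] * 6)
        pca = fit_pca(X, 2)
        svm = fit_svm(project(pca, X), y, 0.5)
        sel = np.array([3, 1, 4, 0, 2])
        pca2, svm2, sel2 = from_json(to_json(pca, svm, sel))
        assert np.allclose(pca.components, pca2.components)
        assert np.allclose(svm.w, svm2.w) and svm.b == svm2.b
        assert np.array_equal(sel, sel2)
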