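import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.svm import SVC

from forgesel import KernelSpec, KernelSVC, kernel_eval, kernel_matrix, train_svm
from forgesel.svm import SVMConvergenceError, predict as svm_predict

from oracles import qp_dual_objective, random_separable_toy

vectors = st.lists(st.floats(-5, 5), min_size=2, max_size=4)


class TestKernels:
    def test_linear_orthogonal_vectors(self):
        assert kernel_eval([1, 0], [0, 1], KernelSpec("linear")) == 0.0

    def test_polynomial_closed_form(self):
        # x.z = 1, degree 2 -> (1 + 1)^2 = 4
        assert kernel_eval([1, 0], [1, 5], KernelSpec("polynomial", degree=2)) == 4.0

    def test_rbf_at_zero_distance_is_one(self):
        assert kernel_eval([1.5, -2], [1.5, -2], KernelSpec("rbf", sigma=0.7)) == 1.0

    def test_rbf_range(self, rng):
        X = rng.normal(size=(10, 3))
        K = kernel_matrix(X, X, KernelSpec("rbf", sigma=2.0))
        assert (K > 0).all() and (K <= 1.0).all()

    def test_sigmoid_closed_form(self):
        got = kernel_eval([1, 1], [1, 0], KernelSpec("sigmoid", k_scale=2.0, theta=0.5))
        assert got == pytest.approx(np.tanh(2.5))

    @settings(deadline=None, max_examples=30)
    @given(vectors, st.data())
    def test_symmetry_in_arguments(self, x, data):
        z = data.draw(st.lists(st.floats(-5, 5), min_size=len(x), max_size=len(x)))
        for spec in [KernelSpec("linear"), KernelSpec("rbf", sigma=1.3),
                     KernelSpec("polynomial", degree=3), KernelSpec("sigmoid")]:
            assert kernel_eval(x, z, spec) == pytest.approx(kernel_eval(z, x, spec))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length|width"):
            kernel_eval([1, 2], [1, 2, 3], KernelSpec())

    def test_gram_psd_linear_and_rbf(self, rng):
        X = rng.normal(size=(12, 4))
        for spec in [KernelSpec("linear"), KernelSpec("rbf", sigma=1.0)]:
            K = kernel_matrix(X, X, spec)
            assert np.allclose(K, K.T)
            assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_invalid_spec_raises(self):
        with pytest.raises(ValueError):
            KernelSpec("rbf", sigma=0.0)
        with pytest.raises(ValueError):
            KernelSpec("spiral")


class TestTwoPointClosedForm:
    """x1=(1,0) y=+1, x2=(-1,0) y=-1: alpha = (0.5, 0.5), b = 0."""

    @pytest.fixture()
    def model(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0]])
        return KernelSVC(kernel="linear", C=1e6).fit(X, np.array([1, -1]))

    def test_dual_solution(self, model):
        assert np.allclose(np.sort(model.alpha_), [0.5, 0.5], atol=1e-6)
        assert model.intercept_ == pytest.approx(0.0, abs=1e-9)

    def test_decision_boundary_is_axis(self, model):
        assert model.predict(np.array([[0.3, 7.0]]))[0] == 1
        assert model.predict(np.array([[-0.3, -7.0]]))[0] == -1

    def test_margin_condition_on_support_vectors(self, model):
        d = model.decision_function(model.support_vectors_)
        assert np.allclose(np.abs(d), 1.0, atol=1e-4)


class TestTraining:
    def test_xor_with_rbf_kernel(self):
        X = np.array([[0.0, 0], [1, 1], [0, 1], [1, 0]])
        y = np.array([1, 1, -1, -1])
        model = KernelSVC(kernel="rbf", sigma=1.0, C=1e6).fit(X, y)
        assert np.array_equal(model.predict(X), y)

    def test_equality_constraint_satisfied(self, rng):
        for _ in range(5):
            X = rng.normal(size=(30, 4))
            y = np.where(rng.random(30) < 0.5, 1, -1)
            y[:2] = [1, -1]
            model = KernelSVC(C=1.0).fit(X, y)  # non-separable, box active
            assert abs(model.equality_residual_) <= 1e-6

    def test_dual_objective_matches_qp_oracle(self, rng):
        for _ in range(5):
            X, y = random_separable_toy(rng)
            model = KernelSVC(C=1e6, tol=1e-6).fit(X, y)
            want = qp_dual_objective(X, y, C=1e6)
            assert model.dual_objective_ == pytest.approx(want, abs=1e-4)

    def test_separable_training_errors_zero(self, rng):
        X, y = random_separable_toy(rng)
        model = KernelSVC(C=1e6).fit(X, y)
        assert np.array_equal(model.predict(X), y)

    def test_prediction_invariant_to_column_permutation(self, rng):
        X = rng.normal(size=(40, 6))
        y = np.where(X[:, 0] + X[:, 3] > 0, 1, -1)
        X_new = rng.normal(size=(10, 6))
        perm = rng.permutation(6)
        for spec in [KernelSpec("linear"), KernelSpec("rbf", sigma=1.5)]:
            m1 = train_svm(X, y, spec, C=1.0)
            m2 = train_svm(X[:, perm], y, spec, C=1.0)
            assert np.array_equal(m1.predict(X_new), m2.predict(X_new[:, perm]))

    def test_agrees_with_reference_svc(self, rng):
        X = rng.normal(size=(50, 5))
        y = np.where(X @ rng.normal(size=5) > 0, 1, -1)
        ours = KernelSVC(kernel="linear", C=1.0).fit(X, y)
        ref = SVC(kernel="linear", C=1.0).fit(X, y)
        X_new = rng.normal(size=(30, 5))
        assert (ours.predict(X_new) == ref.predict(X_new)).mean() == 1.0
        assert ours.intercept_ == pytest.approx(float(ref.intercept_[0]), abs=1e-3)

    def test_single_class_raises(self, rng):
        with pytest.raises(ValueError, match="classes"):
            KernelSVC().fit(rng.normal(size=(5, 2)), np.ones(5))

    def test_nonconvergence_raises_with_diagnostics(self, rng):
        X = rng.normal(size=(60, 3))
        y = np.where(rng.random(60) < 0.5, 1, -1)
        y[:2] = [1, -1]
        with pytest.raises(SVMConvergenceError) as exc:
            KernelSVC(C=1.0, max_iter=2).fit(X, y)
        assert exc.value.violation > 0

    def test_width_mismatch_raises(self, rng):
        X, y = random_separable_toy(rng)
        model = KernelSVC().fit(X, y)
        with pytest.raises(ValueError, match="width"):
            model.predict(np.zeros((1, X.shape[1] + 1)))


class TestPredictAndExport:
    def test_sign_zero_goes_positive(self, rng):
        X, y = random_separable_toy(rng)
        model = KernelSVC(C=1e6).fit(X, y)
        model.intercept_ = 0.0
        model.dual_coef_ = np.zeros_like(model.dual_coef_)  # decision value 0
        assert (model.predict(X) == model.classes_[1]).all()

    def test_predict_returns_raw_decision_values(self, rng):
        X, y = random_separable_toy(rng)
        model = KernelSVC(C=1e6).fit(X, y)
        labels, dec = svm_predict(model, X)
        assert np.array_equal(np.where(dec >= 0, 1, -1), labels)

    def test_json_export(self, tmp_path, rng):
        import json

        X, y = random_separable_toy(rng)
        model = KernelSVC(C=1e6).fit(X, y)
        path = tmp_path / "model.json"
        model.export_json(path)
        payload = json.loads(path.read_text())
        assert payload["kernel"]["kind"] == "linear"
        assert len(payload["dual_coef"]) == len(model.support_)
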