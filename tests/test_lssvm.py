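"""Kernel identities, KKT solution quality, prediction symmetry and
stratified cross-validation mechanics."""

import numpy as np
import pytest

from rtqwt import (
    InvalidInputError,
    KernelSpec,
    LSSVMModel,
    cross_validate,
    kernel_eval,
    kernel_matrix,
    lssvm_predict,
    lssvm_train,
)

ALL_KERNELS = [
    KernelSpec(kind="linear"),
    KernelSpec(kind="polynomial", degree=3),
    KernelSpec(kind="mexican_hat", scale=1.2),
    KernelSpec(kind="morlet", scale=1.0, omega0=5.0),
    KernelSpec(kind="rbf", sigma=0.8),
]


class TestKernels:
    @pytest.mark.parametrize("spec", ALL_KERNELS, ids=lambda s: s.kind)
    def test_symmetry(self, spec, rng):
        for _ in range(10):
            u, v = rng.standard_normal((2, 5))
            assert kernel_eval(spec, u, v) == pytest.approx(kernel_eval(spec, v, u), rel=1e-12)

    @pytest.mark.parametrize(
        "spec",
        [KernelSpec(kind="rbf", sigma=2.0), KernelSpec(kind="mexican_hat"), KernelSpec(kind="morlet")],
        ids=lambda s: s.kind,
    )
    def test_unit_self_similarity(self, spec, rng):
        u = rng.standard_normal(7)
        assert kernel_eval(spec, u, u) == pytest.approx(1.0, abs=1e-12)

    def test_rbf_gram_positive_semidefinite(self, rng):
        x = rng.standard_normal((40, 6))
        k = kernel_matrix(KernelSpec(kind="rbf", sigma=1.3), x, x)
        assert np.linalg.eigvalsh(k).min() > -1e-10

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            kernel_eval(KernelSpec(kind="linear"), [1.0, 2.0], [1.0, 2.0, 3.0])


class TestTraining:
    def test_separable_pair_boundary_at_midpoint(self):
        x = np.array([[-1.0, -1.0], [1.0, 1.0]])
        z = np.array([-1, 1])
        model = lssvm_train(x, z, KernelSpec(kind="linear"), gamma=10.0)
        pred, _ = lssvm_predict(model, x)
        assert list(pred) == [-1, 1]
        midpoint_value = model.decision_function([[0.0, 0.0]])[0]
        assert abs(midpoint_value) < 1e-8

    def test_xor_with_rbf_kernel(self):
        x = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        z = np.array([-1, -1, 1, 1])
        model = lssvm_train(x, z, KernelSpec(kind="rbf", sigma=0.5), gamma=100.0)
        pred, _ = lssvm_predict(model, x)
        assert list(pred) == list(z)

    def test_kkt_residual_small(self, rng):
        x = rng.standard_normal((30, 4))
        z = np.where(x[:, 0] + 0.3 * rng.standard_normal(30) > 0, 1, -1)
        model = lssvm_train(x, z, KernelSpec(kind="rbf"), gamma=5.0)
        assert model.kkt_residual() < 1e-8
        # bias constraint sum(a_i z_i) = 0
        assert abs(model.alphas @ model.support_labels) < 1e-8

    def test_residuals_shrink_with_gamma(self, rng):
        x = rng.standard_normal((25, 3))
        z = np.where(rng.uniform(size=25) > 0.5, 1, -1)
        norms = []
        for gamma in (0.1, 1.0, 10.0, 100.0):
            model = lssvm_train(x, z, KernelSpec(kind="rbf"), gamma=gamma)
            values = model.decision_function(x)
            norms.append(np.linalg.norm(z - values))
        assert all(b < a for a, b in zip(norms, norms[1:]))

    def test_near_interpolation_at_large_gamma(self, rng):
        x = np.vstack([rng.standard_normal((10, 2)) - 3, rng.standard_normal((10, 2)) + 3])
        z = np.repeat([-1, 1], 10)
        model = lssvm_train(x, z, KernelSpec(kind="rbf"), gamma=1e6)
        pred, _ = lssvm_predict(model, x)
        assert list(pred) == list(z)

    def test_flipped_labels_negate_decision_values(self, rng):
        x = rng.standard_normal((16, 3))
        z = np.where(rng.uniform(size=16) > 0.5, 1, -1)
        m1 = lssvm_train(x, z, KernelSpec(kind="linear"), gamma=2.0)
        m2 = lssvm_train(x, -z, KernelSpec(kind="linear"), gamma=2.0)
        q = rng.standard_normal((5, 3))
        np.testing.assert_allclose(
            m1.decision_function(q), -m2.decision_function(q), rtol=1e-8, atol=1e-10
        )

    def test_decision_continuity_rbf(self, rng):
        x = rng.standard_normal((20, 3))
        z = np.where(x.sum(axis=1) > 0, 1, -1)
        model = lssvm_train(x, z, KernelSpec(kind="rbf"), gamma=10.0)
        q = rng.standard_normal(3)
        a = model.decision_function([q])[0]
        b = model.decision_function([q + 1e-9])[0]
        assert abs(a - b) < 1e-6

    def test_json_round_trip(self, tmp_path, rng):
        x = rng.standard_normal((12, 3))
        z = np.where(rng.uniform(size=12) > 0.5, 1, -1)
        model = lssvm_train(x, z, KernelSpec(kind="morlet"), gamma=3.0)
        path = model.to_json(tmp_path / "model.json")
        loaded = LSSVMModel.from_json(path)
        q = rng.standard_normal((4, 3))
        np.testing.assert_allclose(
            loaded.decision_function(q), model.decision_function(q), rtol=1e-12
        )


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(3)
    x = np.vstack([rng.standard_normal((40, 4)) - 4, rng.standard_normal((40, 4)) + 4])
    z = np.repeat(["task1", "task2"], 40)
    return x, z


class TestCrossValidation:
    def test_every_sample_in_exactly_one_test_fold(self, separable):
        x, z = separable
        result = cross_validate(x, z, KernelSpec(kind="rbf"), k=10, seed=1)
        seen = np.concatenate([f.test_idx for f in result.folds])
        assert sorted(seen) == list(range(len(z)))

    def test_folds_are_stratified(self, separable):
        x, z = separable
        result = cross_validate(x, z, KernelSpec(kind="rbf"), k=10, seed=1)
        for fold in result.folds:
            labels = np.asarray(z)[fold.test_idx]
            counts = [np.sum(labels == c) for c in ("task1", "task2")]
            assert abs(counts[0] - counts[1]) <= 1

    def test_separable_data_fully_recovered(self, separable):
        x, z = separable
        result = cross_validate(x, z, KernelSpec(kind="rbf"), gamma=10.0, k=10, seed=0)
        assert result.panel["ACC"] == 1.0
        assert result.auc == 1.0

    def test_class_smaller_than_k_rejected(self, rng):
        x = rng.standard_normal((12, 2))
        z = np.array(["a"] * 9 + ["b"] * 3)
        with pytest.raises(InvalidInputError):
            cross_validate(x, z, k=5)

    def test_no_test_fold_leakage_into_training(self, separable):
        """Poisoning one fold's test rows leaves that fold's trained model
        bit-identical (standardization and training see training rows only)."""
        x, z = separable
        clean = cross_validate(x, z, KernelSpec(kind="rbf"), k=5, seed=2)
        target = clean.folds[0]
        poisoned = x.copy()
        poisoned[target.test_idx] = 1e6  # garbage in the held-out rows
        dirty = cross_validate(poisoned, z, KernelSpec(kind="rbf"), k=5, seed=2)
        np.testing.assert_array_equal(dirty.folds[0].test_idx, target.test_idx)
        np.testing.assert_array_equal(dirty.folds[0].model.alphas, target.model.alphas)
        assert dirty.folds[0].model.bias == target.model.bias

    def test_same_seed_reproducible(self, separable):
        x, z = separable
        a = cross_validate(x, z, KernelSpec(kind="rbf"), k=5, seed=7)
        b = cross_validate(x, z, KernelSpec(kind="rbf"), k=5, seed=7)
        assert a.panel == b.panel
        assert a.auc == b.auc
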