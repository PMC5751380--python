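import numpy as np
import pytest

import gaitjsrc as g
from gaitjsrc.jsrc import RidgeScorer


@pytest.fixture()
def toy_dictionary(rng):
    """12 compressed samples, 3 classes, 2 sensors of 8 rows each."""
    X = rng.normal(size=(12, 16))
    labels = np.repeat([1, 2, 3], 4)
    return g.build_dictionary(X, labels, n_sensors=2)


class TestBuildDictionary:
    def test_columns_grouped_by_class_with_unit_norm(self, rng):
        X = rng.normal(size=(6, 10))
        labels = np.array([3, 1, 2, 1, 3, 2])
        d = g.build_dictionary(X, labels, n_sensors=1)
        assert d.labels.tolist() == [1, 1, 2, 2, 3, 3]
        np.testing.assert_allclose(np.linalg.norm(d.atoms, axis=0), 1.0, atol=1e-12)
        assert d.class_counts == {1: 2, 2: 2, 3: 2}

    def test_class_blocks_are_contiguous(self, toy_dictionary):
        assert np.all(np.diff(toy_dictionary.labels) >= 0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            g.build_dictionary(np.zeros((0, 4)), np.zeros(0, dtype=int), n_sensors=1)

    def test_label_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="label"):
            g.build_dictionary(rng.normal(size=(4, 6)), np.array([1, 2]), n_sensors=1)


class TestSrccNeighbors:
    def test_ridge_matches_normal_equations_oracle(self, toy_dictionary, rng):
        # Brute force: w = (A^T A + lam I)^-1 A^T y on each sensor block.
        lam = 1e-2
        y = rng.normal(size=16)
        coeffs = RidgeScorer(toy_dictionary, lam).coefficients(y)
        for j, sl in enumerate(toy_dictionary.sensor_slices):
            A = toy_dictionary.atoms[sl]
            oracle = np.linalg.solve(A.T @ A + lam * np.eye(12), A.T @ y[sl])
            np.testing.assert_allclose(coeffs[j], oracle, atol=1e-8)

    def test_orthonormal_atoms_reduce_to_correlation_ranking(self):
        # With orthonormal atoms the ridge solution is A^T y / (1 + lam),
        # so SRCC selection equals top-|correlation| selection.
        Q = np.linalg.qr(np.random.default_rng(3).normal(size=(8, 8)))[0]
        d = g.build_dictionary(Q.T, np.repeat([1, 2], 4), n_sensors=1)
        y = Q @ np.array([0.1, 3.0, 0.2, 0.0, 0.0, 2.0, 0.1, 0.05])
        lam = 0.5
        coeffs = RidgeScorer(d, lam).coefficients(y)[0]
        np.testing.assert_allclose(coeffs, d.atoms.T @ y / (1 + lam), atol=1e-10)
        nd = g.srcc_neighbors(y, d, lam=lam, m=1)
        corr = np.abs(d.atoms.T @ y)
        expected = {int(np.argmax(np.where(d.labels == c, corr, -1))) for c in (1, 2)}
        assert set(nd.indices.tolist()) == expected

    def test_full_dictionary_returned_when_m_large(self, toy_dictionary, rng):
        nd = g.srcc_neighbors(rng.normal(size=16), toy_dictionary, m=100)
        assert nd.n == toy_dictionary.n
        np.testing.assert_array_equal(nd.indices, np.arange(12))

    def test_atom_identical_test_scores_highest(self):
        Q = np.linalg.qr(np.random.default_rng(9).normal(size=(10, 10)))[0]
        d = g.build_dictionary(Q.T, np.repeat([1, 2], 5), n_sensors=1)
        y = d.atoms[:, 7].copy()
        nd = g.srcc_neighbors(y, d, lam=1e-6, m=1)
        assert 7 in nd.indices

    def test_selection_invariant_to_positive_rescaling(self, toy_dictionary, rng):
        y = rng.normal(size=16)
        a = g.srcc_neighbors(y, toy_dictionary, m=2)
        b = g.srcc_neighbors(37.5 * y, toy_dictionary, m=2)
        np.testing.assert_array_equal(a.indices, b.indices)

    def test_nonpositive_lambda_rejected(self, toy_dictionary, rng):
        with pytest.raises(ValueError, match="lambda"):
            g.srcc_neighbors(rng.normal(size=16), toy_dictionary, lam=0.0)

    def test_pooled_variant_runs_and_selects_per_class(self, toy_dictionary, rng):
        nd = g.srcc_neighbors(rng.normal(size=16), toy_dictionary, m=2, pooled=True)
        assert nd.n == 6


class TestKnnNeighbors:
    def test_identical_atom_selected_first_in_its_class(self, toy_dictionary):
        y = toy_dictionary.atoms[:, 5].copy()
        nd = g.knn_neighbors(y, toy_dictionary, m=1)
        assert 5 in nd.indices

    def test_m_one_with_two_classes_keeps_two_atoms(self, rng):
        d = g.build_dictionary(rng.normal(size=(8, 6)), np.repeat([1, 2], 4), n_sensors=1)
        assert g.knn_neighbors(rng.normal(size=6), d, m=1).n == 2

    def test_matches_brute_force_distance_sort(self, toy_dictionary, rng):
        y = rng.normal(size=16)
        nd = g.knn_neighbors(y, toy_dictionary, m=2)
        yn = y / np.linalg.norm(y)
        dist = np.linalg.norm(toy_dictionary.atoms - yn[:, None], axis=0)
        expected = []
        for c in (1, 2, 3):
            idx = np.flatnonzero(toy_dictionary.labels == c)
            expected.extend(idx[np.argsort(dist[idx], kind="stable")[:2]])
        assert sorted(expected) == nd.indices.tolist()

    def test_invalid_m_rejected(self, toy_dictionary, rng):
        with pytest.raises(ValueError, match="m"):
            g.knn_neighbors(rng.normal(size=16), toy_dictionary, m=0)


class TestSolveJoint:
    def test_greedy_interpolates_square_dictionary(self, rng):
        d = g.build_dictionary(
            rng.normal(size=(8, 8)) + 4 * np.eye(8), np.repeat([1, 2], 4), n_sensors=2
        )
        y = rng.normal(size=8)
        coeffs = g.solve_joint(y, d, k=8, method="greedy")
        assert np.linalg.norm(coeffs.residuals) < 1e-8

    def test_greedy_respects_row_sparsity(self, toy_dictionary, rng):
        coeffs = g.solve_joint(rng.normal(size=16), toy_dictionary, k=3)
        assert coeffs.n_active_rows <= 3

    def test_residual_field_is_consistent(self, toy_dictionary, rng):
        y = rng.normal(size=16)
        coeffs = g.solve_joint(y, toy_dictionary, k=4)
        rebuilt = []
        for j, sl in enumerate(toy_dictionary.sensor_slices):
            rebuilt.append(y[sl] - toy_dictionary.atoms[sl] @ coeffs.W[:, j])
        np.testing.assert_allclose(coeffs.residuals, np.concatenate(rebuilt), atol=1e-10)

    def test_mbcs_solver_path(self, rng):
        atoms = rng.normal(size=(24, 10))
        atoms /= np.linalg.norm(atoms, axis=0)
        d = g.TrainingDictionary(atoms=atoms, labels=np.repeat([1, 2], 5), n_sensors=2)
        W_true = np.zeros((10, 2))
        W_true[[1, 6], :] = 5.0
        y = np.concatenate(
            [d.atoms[sl] @ W_true[:, j] for j, sl in enumerate(d.sensor_slices)]
        )
        coeffs = g.solve_joint(y, d, method="mbcs")
        assert coeffs.solver == "mbcs"
        assert set(coeffs.support.tolist()) == {1, 6}
        assert coeffs.alpha is not None and coeffs.beta0 is not None

    def test_unknown_solver_rejected(self, toy_dictionary, rng):
        with pytest.raises(ValueError, match="solver"):
            g.solve_joint(rng.normal(size=16), toy_dictionary, method="ista")


class TestResidualClassify:
    def _exact_instance(self, rng):
        atoms = rng.normal(size=(12, 9))
        atoms /= np.linalg.norm(atoms, axis=0)
        d = g.TrainingDictionary(atoms=atoms, labels=np.repeat([1, 2, 3], 3), n_sensors=2)
        W = np.zeros((9, 2))
        W[3:6] = rng.normal(size=(3, 2))  # class-2 rows only
        y = np.concatenate(
            [d.atoms[sl] @ W[:, j] for j, sl in enumerate(d.sensor_slices)]
        )
        coeffs = g.JointCoefficients(
            W=W, support=np.arange(3, 6), k=3, solver="greedy",
            residuals=np.zeros(12),
        )
        return y, d, coeffs

    def test_exact_class_two_sample_gets_zero_residual(self, rng):
        y, d, coeffs = self._exact_instance(rng)
        result = g.residual_classify(y, d, coeffs)
        assert result.label == 2
        assert result.residuals[list(result.classes).index(2)] < 1e-10

    def test_indicator_masks_partition_coefficients(self, rng):
        y, d, coeffs = self._exact_instance(rng)
        result = g.residual_classify(y, d, coeffs)
        total = sum(result.masked_coefficients.values())
        np.testing.assert_array_equal(total, coeffs.W)

    def test_residuals_match_brute_force_recomputation(self, toy_dictionary, rng):
        y = rng.normal(size=16)
        coeffs = g.solve_joint(y, toy_dictionary, k=4)
        result = g.residual_classify(y, toy_dictionary, coeffs)
        for i, c in enumerate(result.classes):
            mask = toy_dictionary.labels == c
            sq = 0.0
            for j, sl in enumerate(toy_dictionary.sensor_slices):
                approx = toy_dictionary.atoms[sl][:, mask] @ coeffs.W[mask, j]
                sq += np.sum((y[sl] - approx) ** 2)
            assert result.residuals[i] == pytest.approx(np.sqrt(sq), abs=1e-10)

    def test_absent_class_scores_full_norm(self, toy_dictionary, rng):
        y = rng.normal(size=16)
        coeffs = g.solve_joint(y, toy_dictionary, k=4)
        result = g.residual_classify(
            y, toy_dictionary, coeffs, all_classes=np.array([1, 2, 3, 4])
        )
        assert result.residuals[-1] == pytest.approx(np.linalg.norm(y))

    def test_label_invariant_under_class_block_permutation(self, rng):
        # Relabeling classes permutes the residual vector but not the winner.
        X = rng.normal(size=(12, 16))
        labels = np.repeat([1, 2, 3], 4)
        y = X[5] + 0.01 * rng.normal(size=16)
        d1 = g.build_dictionary(X, labels, n_sensors=2)
        r1 = g.residual_classify(y, d1, g.solve_joint(y, d1, k=4))
        perm = {1: 3, 2: 1, 3: 2}
        d2 = g.build_dictionary(X, np.array([perm[v] for v in labels]), n_sensors=2)
        r2 = g.residual_classify(y, d2, g.solve_joint(y, d2, k=4))
        assert perm[r1.label] == r2.label


class TestClassifyPipeline:
    def test_training_sample_classified_correctly(self, rng):
        ds = g.simulate_gait_dataset(1, 4, 1, J=2, window_len=32, seed=2)
        scheme = g.make_measurement_scheme(2, 32, 16, "gaussian", seed=0)
        Z = g.compress_windows(ds.as_array(), scheme)
        d = g.build_dictionary(Z, ds.labels, n_sensors=2)
        model = g.PipelineModel(scheme=scheme, dictionary=d, m=1, k=2)
        for i, sample in enumerate(ds.samples):
            assert g.classify_pipeline(sample, model).label == ds.labels[i]

    def test_neighbor_dictionary_is_smaller_than_full(self, small_dataset):
        scheme = g.make_measurement_scheme(3, 64, 32, "sparse_binary", seed=1)
        Z = g.compress_windows(small_dataset.as_array(), scheme)
        d = g.build_dictionary(Z, small_dataset.labels, n_sensors=3)
        m = 5
        nd = g.srcc_neighbors(Z[0], d, m=m)
        assert nd.n == small_dataset.n_classes * m
        assert nd.n < d.n
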