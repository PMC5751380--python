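import numpy as np
import pytest

import gaitjsrc as g
from gaitjsrc.dcs import measurements_for_ratio


class TestMeasurementScheme:
    def test_sparse_binary_has_two_ones_per_column(self):
        scheme = g.make_measurement_scheme(2, 10, 4, "sparse_binary", seed=5)
        for block in scheme.blocks:
            assert np.all(np.count_nonzero(block, axis=0) == 2)
            assert set(np.unique(block)) <= {0.0, 1.0}

    def test_full_operator_is_block_diagonal(self):
        scheme = g.make_measurement_scheme(3, 8, 4, "gaussian", seed=0)
        full = scheme.full_operator()
        assert full.shape == (12, 24)
        for j, block in enumerate(scheme.blocks):
            np.testing.assert_array_equal(full[4 * j : 4 * (j + 1), 8 * j : 8 * (j + 1)], block)
            off = full[4 * j : 4 * (j + 1)].copy()
            off[:, 8 * j : 8 * (j + 1)] = 0.0
            assert np.all(off == 0.0)

    def test_seeded_determinism(self):
        a = g.make_measurement_scheme(2, 16, 6, "sparse_binary", seed=3)
        b = g.make_measurement_scheme(2, 16, 6, "sparse_binary", seed=3)
        for x, y in zip(a.blocks, b.blocks):
            np.testing.assert_array_equal(x, y)

    @pytest.mark.parametrize("M", [0, 11])
    def test_invalid_measurement_count_rejected(self, M):
        with pytest.raises(ValueError):
            g.make_measurement_scheme(2, 10, M, "gaussian")

    def test_sparse_binary_needs_two_rows(self):
        with pytest.raises(ValueError, match="M >= 2"):
            g.make_measurement_scheme(2, 10, 1, "sparse_binary")


class TestCompress:
    def test_zero_ensemble_maps_to_zero(self):
        scheme = g.make_measurement_scheme(3, 10, 4, "gaussian", seed=1)
        Y = g.compress(g.SensorEnsemble(np.zeros((3, 10))), scheme)
        np.testing.assert_array_equal(Y.stacked, np.zeros(12))

    def test_matches_full_block_diagonal_operator(self, rng):
        # Brute-force oracle: assemble the full operator and multiply.
        scheme = g.make_measurement_scheme(4, 12, 5, "gaussian", seed=2)
        X = g.SensorEnsemble(rng.normal(size=(4, 12)))
        Y = g.compress(X, scheme)
        oracle = scheme.full_operator() @ X.signals.ravel()
        assert np.max(np.abs(Y.stacked - oracle)) < 1e-12

    def test_compression_is_linear(self, rng):
        scheme = g.make_measurement_scheme(3, 16, 8, "sparse_binary", seed=4)
        X1 = rng.normal(size=(3, 16))
        X2 = rng.normal(size=(3, 16))
        lhs = g.compress(g.SensorEnsemble(2.5 * X1 - 1.5 * X2), scheme).stacked
        rhs = 2.5 * g.compress(g.SensorEnsemble(X1), scheme).stacked - 1.5 * g.compress(
            g.SensorEnsemble(X2), scheme
        ).stacked
        assert np.max(np.abs(lhs - rhs)) < 1e-12

    def test_stacked_length_is_j_times_m(self, rng):
        scheme = g.make_measurement_scheme(5, 200, 60, "gaussian", seed=0)
        X = g.SensorEnsemble(rng.normal(size=(5, 200)))
        assert g.compress(X, scheme).stacked.size == 300

    def test_dimension_mismatch_rejected(self, rng):
        scheme = g.make_measurement_scheme(3, 10, 4, "gaussian", seed=1)
        with pytest.raises(ValueError, match="length"):
            g.compress(g.SensorEnsemble(rng.normal(size=(3, 11))), scheme)

    def test_window_compression_matches_per_channel_products(self, rng):
        # Each sensor's channel rows compressed by that sensor's block,
        # concatenated channel-major within sensor.
        scheme = g.make_measurement_scheme(2, 20, 6, "gaussian", seed=7)
        sample = g.GaitWindowSample(rng.normal(size=(10, 20)), n_sensors=2)
        y = g.compress_window(sample, scheme)
        expected = []
        for j in range(2):
            for c in range(5):
                expected.append(scheme.blocks[j] @ sample.data[5 * j + c])
        np.testing.assert_allclose(y, np.concatenate(expected), atol=1e-14)


class TestCompressionRatio:
    @pytest.mark.parametrize(
        "N, M, expected", [(200, 60, 70.0), (100, 100, 0.0), (100, 25, 75.0)]
    )
    def test_known_values(self, N, M, expected):
        assert g.compression_ratio(N, M) == pytest.approx(expected)

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            g.compression_ratio(100, 101)

    def test_strictly_decreasing_in_m(self):
        values = [g.compression_ratio(128, M) for M in range(1, 129)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_ratio_inversion(self):
        assert measurements_for_ratio(200, 70.0) == 60
        assert measurements_for_ratio(200, 50.0) == 100


class TestJointReconstruct:
    def test_k_zero_returns_zero_model(self, rng):
        scheme = g.make_measurement_scheme(2, 16, 8, "gaussian", seed=1)
        X = g.SensorEnsemble(rng.normal(size=(2, 16)))
        model, Xhat = g.joint_reconstruct(
            g.compress(X, scheme), np.eye(16), 0, "somp"
        )
        assert model.sparsity == 0
        np.testing.assert_array_equal(Xhat.signals, np.zeros((2, 16)))

    def test_noiseless_recovery_matches_least_squares_oracle(self):
        X, truth = g.simulate_jsm2_ensemble(J=5, N=64, k=4, noise_sd=0, seed=7)
        scheme = g.make_measurement_scheme(5, 64, 32, "gaussian", seed=1)
        Y = g.compress(X, scheme)
        est, _ = g.joint_reconstruct(Y, truth.basis, 4, "somp")
        np.testing.assert_array_equal(est.support, truth.support)
        # Oracle: per-sensor least squares restricted to the true support.
        for j in range(5):
            D = scheme.blocks[j] @ truth.basis
            w, *_ = np.linalg.lstsq(D[:, truth.support], Y.measurements[j], rcond=None)
            np.testing.assert_allclose(est.coefficients[j, truth.support], w, atol=1e-8)

    def test_first_selected_atom_is_brute_force_argmax(self):
        X, truth = g.simulate_jsm2_ensemble(J=3, N=40, k=5, noise_sd=0.1, seed=13)
        scheme = g.make_measurement_scheme(3, 40, 20, "gaussian", seed=3)
        Y = g.compress(X, scheme)
        est, _ = g.joint_reconstruct(Y, truth.basis, 5, "somp")
        from gaitjsrc import solvers

        Ds = [b @ truth.basis for b in scheme.blocks]
        scores = np.zeros(40)
        for y, D in zip(Y.measurements, Ds):
            for a in range(40):
                col = D[:, a]
                scores[a] += (col @ y / np.linalg.norm(col)) ** 2
        result = solvers.somp(Y.measurements, Ds, 5)
        assert result.selection_order[0] == int(np.argmax(scores))

    def test_somp_residuals_non_increasing_for_every_sensor(self):
        X, truth = g.simulate_jsm2_ensemble(J=4, N=48, k=6, noise_sd=0.3, seed=21)
        scheme = g.make_measurement_scheme(4, 48, 24, "gaussian", seed=5)
        Y = g.compress(X, scheme)
        from gaitjsrc import solvers

        Ds = [b @ truth.basis for b in scheme.blocks]
        res = solvers.somp(Y.measurements, Ds, 6)
        diffs = np.diff(res.residual_norms, axis=0)
        assert np.all(diffs <= 1e-10)

    def test_recovery_rate_high_and_osga_weaker(self):
        # 100 seeded noiseless trials at N=128, k=8, M=4k.
        somp_hits = osga_hits = 0
        for s in range(100):
            X, truth = g.simulate_jsm2_ensemble(J=5, N=128, k=8, noise_sd=0, seed=1000 + s)
            scheme = g.make_measurement_scheme(5, 128, 32, "gaussian", seed=2000 + s)
            Y = g.compress(X, scheme)
            est, _ = g.joint_reconstruct(Y, truth.basis, 8, "somp")
            somp_hits += np.array_equal(est.support, truth.support)
            est2, _ = g.joint_reconstruct(Y, truth.basis, 8, "osga")
            osga_hits += np.array_equal(est2.support, truth.support)
        assert somp_hits >= 95
        assert osga_hits <= somp_hits

    def test_k_beyond_measurement_count_rejected(self, rng):
        scheme = g.make_measurement_scheme(2, 16, 4, "gaussian", seed=1)
        Y = g.compress(g.SensorEnsemble(rng.normal(size=(2, 16))), scheme)
        with pytest.raises(ValueError, match="exceeds"):
            g.joint_reconstruct(Y, np.eye(16), 5, "somp")
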