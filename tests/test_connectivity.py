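"""Directed connectivity estimators: spectra, normalisation, oracle recovery."""

import numpy as np
import pytest

import eegconn as ec
from conftest import MS

FREQS = ec.DEFAULT_FREQS


class TestCoeffFourier:
    def test_limit_at_zero_frequency(self):
        coeffs = np.random.default_rng(0).standard_normal((2, 3, 3)) * 0.1
        # At the formal point f -> 0 all exponentials are 1.
        abar = ec.coeff_fourier(coeffs, [1e-12], 1000.0)[0]
        assert np.allclose(abar, np.eye(3) - coeffs.sum(axis=0), atol=1e-9)

    def test_quarter_sampling_rate(self):
        coeffs = 0.5 * np.eye(2)[None, :, :]
        abar = ec.coeff_fourier(coeffs, [62.5], 250.0)[0]
        # exp(-i pi/2) = -i, so A-bar = I + 0.5i I.
        assert np.allclose(abar, np.eye(2) * (1 + 0.5j), atol=1e-12)

    def test_matches_bruteforce_term_sum(self):
        rng = np.random.default_rng(1)
        coeffs = rng.standard_normal((4, 3, 3)) * 0.15
        freqs = np.array([3.0, 11.0, 19.0])
        fs = 250.0
        got = ec.coeff_fourier(coeffs, freqs, fs)
        for fi, f in enumerate(freqs):
            expected = np.eye(3, dtype=complex)
            for r in range(1, 5):
                expected -= coeffs[r - 1] * np.exp(-2j * np.pi * f * r / fs)
            assert np.allclose(got[fi], expected, atol=1e-12)

    def test_empty_freqs_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ec.coeff_fourier(np.zeros((1, 2, 2)), [], 250.0)


class TestTransferFunction:
    def test_identity_and_diagonal(self):
        eye = np.eye(3, dtype=complex)[None]
        assert np.allclose(ec.transfer_function(eye), eye)
        diag = np.diag([2.0, 4.0, 0.5]).astype(complex)[None]
        assert np.allclose(
            ec.transfer_function(diag)[0], np.diag([0.5, 0.25, 2.0])
        )

    def test_inverse_residual_small(self):
        rng = np.random.default_rng(2)
        abar = rng.standard_normal((5, 6, 6)) + 1j * rng.standard_normal((5, 6, 6))
        h = ec.transfer_function(abar)
        for a, hh in zip(abar, h):
            assert np.linalg.norm(hh @ a - np.eye(6)) < 1e-8

    def test_singular_matrix_names_frequency(self):
        abar = np.stack([np.eye(2, dtype=complex), np.zeros((2, 2), dtype=complex)])
        with pytest.raises(np.linalg.LinAlgError, match="index 1"):
            ec.transfer_function(abar)


class TestSpectralEstimators:
    def test_diagonal_system_dtf(self):
        model = ec.MVARModel(
            order=1, coeffs=0.5 * np.eye(2)[None], resid_cov=np.eye(2), n_obs=100
        )
        t = ec.dtf(model, FREQS, 250.0)
        t.validate()
        assert np.allclose(t.values[0, 1], 0.0) and np.allclose(t.values[1, 0], 0.0)
        assert np.allclose(t.values[0, 0], 1.0) and np.allclose(t.values[1, 1], 1.0)

    def test_diagonal_system_pdc_gpdc(self):
        model = ec.MVARModel(
            order=1,
            coeffs=0.5 * np.eye(2)[None],
            resid_cov=np.diag([1.0, 4.0]),
            n_obs=100,
        )
        for fn in (ec.pdc, ec.gpdc):
            t = fn(model, FREQS, 250.0)
            t.validate()
            off = t.values * (1 - np.eye(2))[:, :, None, None]
            assert np.allclose(off, 0.0)
            assert np.allclose(np.diagonal(t.values, axis1=0, axis2=1), 1.0)

    def test_pdc_direction_on_coupled_model(self, two_channel_system):
        model = ec.MVARModel(
            order=1,
            coeffs=two_channel_system.coeffs,
            resid_cov=np.eye(2),
            n_obs=100,
        )
        t = ec.pdc(model, FREQS, 250.0)
        assert np.all(t.values[0, 1] > 0)
        assert np.allclose(t.values[1, 0], 0.0)

    def test_normalisations_on_fitted_models(self, long_fit):
        _, model = long_fit
        dtf_t = ec.dtf(model, FREQS, 250.0)
        pdc_t = ec.pdc(model, FREQS, 250.0)
        gpdc_t = ec.gpdc(model, FREQS, 250.0)
        assert np.allclose(dtf_t.values.sum(axis=0), 1.0, atol=1e-6)
        assert np.allclose(pdc_t.values.sum(axis=1), 1.0, atol=1e-6)
        assert np.allclose(gpdc_t.values.sum(axis=1), 1.0, atol=1e-6)
        for t in (dtf_t, pdc_t, gpdc_t):
            t.validate()

    def test_gpdc_equals_pdc_under_equal_variances(self, two_channel_system):
        model = ec.MVARModel(
            order=1,
            coeffs=two_channel_system.coeffs,
            resid_cov=2.5 * np.eye(2),
            n_obs=100,
        )
        a = ec.pdc(model, FREQS, 250.0).values
        b = ec.gpdc(model, FREQS, 250.0).values
        assert np.allclose(a, b, atol=1e-10)

    def test_gpdc_matches_bruteforce_loops(self):
        rng = np.random.default_rng(4)
        coeffs = rng.standard_normal((2, 3, 3)) * 0.2
        sigma2 = np.array([0.5, 2.0, 1.3])
        model = ec.MVARModel(
            order=2, coeffs=coeffs, resid_cov=np.diag(sigma2), n_obs=100
        )
        got = ec.gpdc(model, FREQS, 250.0).values
        # Independent per-entry loop evaluation of the weighted ratio.
        abar = ec.coeff_fourier(coeffs, FREQS, 250.0)
        for fi in range(len(FREQS)):
            for j in range(3):  # source column
                denom = sum(
                    abs(abar[fi, m, j]) ** 2 / sigma2[m] for m in range(3)
                )
                for i in range(3):  # target row
                    expected = (abs(abar[fi, i, j]) ** 2 / sigma2[i]) / denom
                    assert got[j, i, fi, 0] == pytest.approx(expected, abs=1e-10)

    def test_nonpositive_residual_variance_rejected(self):
        model = ec.MVARModel(
            order=1, coeffs=0.5 * np.eye(2)[None], resid_cov=np.diag([1.0, 0.0]), n_obs=50
        )
        with pytest.raises(ValueError, match="positive residual"):
            ec.gpdc(model, FREQS, 250.0)


class TestGGC:
    def test_independent_channels_no_causality(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((2, 10_000))
        g = ec.ggc_index(x, 1)
        assert g[0, 1] < 0.01 and g[1, 0] < 0.01

    def test_direction_recovered_and_bruteforce_match(self, two_channel_system):
        eps = ec.simulate_epochs(two_channel_system, 1, MS(10_000), "distracted", seed=9)
        x = eps.data[0]
        g = ec.ggc_index(x, 1)
        assert g[0, 1] > 0.05
        assert g[1, 0] < 0.01
        # Brute-force two-model fit for the 0 -> 1 entry.
        full = ec.fit_mvar(x, 1)
        reduced = ec.fit_mvar(x[1:2], 1)
        expected = np.log(reduced.resid_cov[0, 0] / full.resid_cov[1, 1])
        assert g[0, 1] == pytest.approx(max(0.0, expected), abs=1e-12)

    def test_entries_nonnegative_and_diagonal_zero(self):
        rng = np.random.default_rng(7)
        g = ec.ggc_index(rng.standard_normal((4, 500)), 2)
        assert np.all(g >= 0)
        assert np.allclose(np.diag(g), 0.0)


class TestOracleRecovery:
    def test_estimates_match_true_connectivity(self, long_fit):
        dense, model = long_fit
        for kind in ("dtf", "pdc", "gpdc"):
            est = ec.spectral_measure(model.coeffs, model.resid_cov, FREQS, 250.0, kind)
            tru = ec.true_spectral_connectivity(dense, FREQS, kind).values[..., 0]
            assert np.abs(est - tru).max() < 0.05

    def test_edge_ranking_separates_true_graph(self, condition_systems):
        from sklearn.metrics import roc_auc_score

        _, dense = condition_systems
        eps = ec.simulate_epochs(dense, 1, MS(10_000), "distracted", seed=7)
        model = ec.fit_mvar(eps.data[0], 5)
        score = ec.spectral_measure(
            model.coeffs, model.resid_cov, FREQS, 250.0, "pdc"
        ).mean(axis=2)
        truth, ranks = [], []
        for s in range(6):
            for t in range(6):
                if s != t:
                    truth.append((s, t) in dense.edges)
                    ranks.append(score[s, t])
        assert roc_auc_score(truth, ranks) >= 0.95

    @pytest.mark.parametrize("kind", ["pdc", "dtf", "ggc"])
    def test_null_estimates_shrink_with_sample_size(self, kind):
        null = ec.make_var_system(6, 1, edges=[], diag_strength=0.4)
        p95 = {}
        for n in (500, 5000):
            eps = ec.simulate_epochs(null, 1, MS(n), "distracted", seed=13)
            x = eps.data[0]
            if kind == "ggc":
                vals = ec.ggc_index(x, 1)
            else:
                model = ec.fit_mvar(x, 1)
                vals = ec.spectral_measure(
                    model.coeffs, model.resid_cov, FREQS, 250.0, kind
                ).mean(axis=2)
            off = vals[~np.eye(6, dtype=bool)]
            p95[n] = np.percentile(off, 95)
        assert p95[5000] < p95[500]


class TestFeatureAssembly:
    def test_canonical_feature_counts(self, small_dataset):
        nd = small_dataset.select(
            [i for i, l in enumerate(small_dataset.labels) if l == "non_distracted"]
        )
        table = ec.connectivity_features(nd, "pdc", order=5)
        assert table.values.shape[1] == 6 * 6 * 20 * 17 == 12_240
        d = small_dataset.select(
            [i for i, l in enumerate(small_dataset.labels) if l == "distracted"]
        )
        table_d = ec.connectivity_features(d, "pdc", order=5)
        assert table_d.values.shape[1] == 6 * 6 * 20 * 25

    def test_flattening_roundtrip_identity(self, small_dataset):
        nd = small_dataset.select([0])
        table = ec.connectivity_features(nd, "pdc", order=5)
        tensor = ec.epoch_connectivity(
            nd.data[0], "pdc", 5, FREQS, nd.fs
        ).values
        assert np.array_equal(table.values[0].reshape(6, 6, 20, 17), tensor)

    def test_column_names_follow_scheme(self, small_dataset):
        nd = small_dataset.select([0])
        table = ec.connectivity_features(nd, "pdc", order=5)
        assert table.columns[0] == "frontal_frontal_1Hz_w0"
        assert table.columns[-1] == "right_motor_right_motor_20Hz_w16"
        assert len(table.columns) == table.values.shape[1]

    def test_mixed_lengths_require_alignment(self, small_dataset):
        with pytest.raises(ValueError, match="n_windows"):
            ec.connectivity_features(small_dataset, "pdc", order=5)
        aligned = ec.connectivity_features(small_dataset, "pdc", order=5, n_windows=17)
        assert aligned.values.shape == (len(small_dataset), 12_240)

    def test_ggc_features_constant_across_frequency(self, small_dataset):
        nd = small_dataset.select([0])
        tensor = ec.epoch_connectivity(nd.data[0], "ggc", 5, FREQS, nd.fs)
        tensor.validate()
        assert tensor.values.shape == (6, 6, 20, 17)

    def test_transformer_matches_function_route(self, small_dataset):
        nd = small_dataset.select(
            [i for i, l in enumerate(small_dataset.labels) if l == "non_distracted"]
        )
        table = ec.connectivity_features(nd, "pdc", order=5)
        tf = ec.ConnectivityTransformer(estimator="pdc", order=5, fs=nd.fs)
        out = tf.fit_transform(nd.stack("non_distracted"))
        assert np.array_equal(out, table.values)
        assert tf.get_params()["estimator"] == "pdc"


class TestAverageConnectivity:
    def test_single_subject_single_window_identity(self):
        t = np.random.default_rng(0).random((4, 4, 5, 3))
        out = ec.average_connectivity([t], (1, 2))
        assert np.allclose(out, t[:, :, :, 1])

    def test_linearity_over_subjects(self):
        t = np.random.default_rng(1).random((4, 4, 5, 3))
        out = ec.average_connectivity([t, 3 * t])
        assert np.allclose(out, 2 * t.mean(axis=3))

    def test_commutes_with_subject_reordering(self):
        rng = np.random.default_rng(2)
        ts = [rng.random((3, 3, 4, 2)) for _ in range(4)]
        a = ec.average_connectivity(ts, (0, 2))
        b = ec.average_connectivity(ts[::-1], (0, 2))
        assert np.allclose(a, b)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            ec.average_connectivity([np.zeros((3, 3, 4, 2)), np.zeros((3, 3, 4, 3))])
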