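"""Peak-feature extraction, downsampling, PCA and current normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voltdiff._constants import FARADAY, GAS_CONSTANT
from voltdiff.conditions import Voltammogram, potential_waveform
from voltdiff.cvsim import simulate_cv
from voltdiff.errors import InvalidInputError, NoPeakError, DimensionMismatchError
from voltdiff.pipeline import standard_conditions
from voltdiff.preprocess import (
    PEAK_FEATURE_NAMES,
    downsample,
    extract_peak_features,
    normalize_current,
    pca_fit,
    pca_transform,
)


class TestPeakFeatures:
    def test_constructed_triangle_peak(self, qr_conditions):
        """On a synthetic single-maximum trace the peak is located exactly."""
        wave = potential_waveform(qr_conditions)
        j = 321
        currents = -np.abs(np.arange(len(wave), dtype=float) - j)
        currents -= currents.min() - 1.0
        feats = extract_peak_features(Voltammogram(wave, currents, qr_conditions))
        assert feats.Ep_for == wave[j]
        assert feats.ip_for == currents[j]
        assert feats.ip_half == currents[j] / 2

    def test_reversible_half_peak_separation(self, cv_erev):
        """|Ep_for - E_half| ~ 2.20 RT/nF (about 55.6 mV at 293.15 K)."""
        feats = extract_peak_features(cv_erev)
        expected = 2.20 * GAS_CONSTANT * 293.15 / FARADAY
        assert abs(feats.Ep_for - feats.E_half) * 1e3 == pytest.approx(
            expected * 1e3, abs=2.0
        )

    def test_reversible_peak_separation(self, cv_erev):
        feats = extract_peak_features(cv_erev)
        assert feats.dEp * 1e3 == pytest.approx(56.0, abs=2.0)
        assert feats.dEp == feats.Ep_for - feats.Ep_rev

    def test_reversible_peak_ratio_zero_baseline(self, cv_erev):
        """Measured from the zero-current baseline (no decaying-tail
        correction) the reversible peak ratio |ip_for/ip_rev| is ~1.35: the
        reverse peak rides on the positive forward-diffusion tail, so its
        zero-baseline magnitude is only ~0.74 of the forward peak.  With the
        classical baseline correction the ratio would be 1; that correction
        is deliberately not applied here."""
        feats = extract_peak_features(cv_erev)
        assert feats.peak_ratio < 0  # opposite signs of the two peaks
        assert abs(feats.peak_ratio) == pytest.approx(1.0 / 0.74, rel=0.05)

    def test_feature_vector_order(self, cv_erev):
        feats = extract_peak_features(cv_erev)
        vec = feats.as_vector()
        assert len(vec) == len(PEAK_FEATURE_NAMES) == 7
        assert vec[0] == feats.Ep_for and vec[-1] == feats.peak_ratio

    def test_monotone_forward_branch_rejected(self, qr_conditions):
        wave = potential_waveform(qr_conditions)
        with pytest.raises(NoPeakError):
            extract_peak_features(
                Voltammogram(wave, np.linspace(0, 1, len(wave)), qr_conditions)
            )

    def test_degraded_reverse_flagged(self, ec_conditions):
        """A fast follow-up consumes B, leaving no cathodic return peak."""
        from voltdiff.conditions import Mechanism, MechanismSpec

        cv = simulate_cv(MechanismSpec(Mechanism.EC, e0=0.3, D=1e-5, k1=1000.0),
                         ec_conditions)
        assert extract_peak_features(cv).degraded_reverse


class TestDownsample:
    def test_factor_twenty_on_full_waveform(self):
        assert len(downsample(np.zeros(1401), 20)) == 71  # ceil(1401/20)

    def test_identity_and_endpoint(self):
        x = np.arange(1401.0)
        np.testing.assert_array_equal(downsample(x, 1), x)
        np.testing.assert_array_equal(downsample(x, 1401), [0.0])

    def test_keeps_every_kth_index(self):
        x = np.arange(100.0)
        np.testing.assert_array_equal(downsample(x, 7), x[::7])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(n=st.integers(2, 400), a=st.integers(1, 10), b=st.integers(1, 10))
    def test_composition_property(self, n, a, b):
        """Downsampling by a then b equals downsampling by a*b."""
        x = np.arange(float(n))
        np.testing.assert_array_equal(downsample(downsample(x, a), b), downsample(x, a * b))

    def test_invalid_factor(self):
        with pytest.raises(InvalidInputError):
            downsample(np.zeros(5), 0)


class TestPCA:
    def test_rank_one_data(self, rng):
        direction = rng.normal(size=30)
        X = 5.0 + np.outer(rng.normal(size=12), direction)
        model = pca_fit(X, 1)
        assert model.explained_variance_ratio == pytest.approx(1.0, abs=1e-12)

    def test_orthonormal_loadings(self, rng):
        X = rng.normal(size=(40, 15))
        model = pca_fit(X, 5)
        np.testing.assert_allclose(
            model.loadings.T @ model.loadings, np.eye(5), atol=1e-10
        )
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)

    def test_matches_sklearn(self, rng):
        sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
        X = rng.normal(size=(25, 8))
        model = pca_fit(X, 4)
        ref = sklearn_pca(n_components=4).fit(X)
        np.testing.assert_allclose(model.eigenvalues, ref.explained_variance_, rtol=1e-10)
        assert model.explained_variance_ratio == pytest.approx(
            ref.explained_variance_ratio_.sum(), rel=1e-10
        )
        # loadings agree up to per-component sign
        dots = np.abs(np.sum(model.loadings.T * ref.components_, axis=1))
        np.testing.assert_allclose(dots, 1.0, atol=1e-10)

    def test_score_variances_equal_eigenvalues(self, rng):
        X = rng.normal(size=(30, 10))
        model = pca_fit(X, 3)
        scores = pca_transform(model, X)
        np.testing.assert_allclose(
            scores.var(axis=0, ddof=1), model.eigenvalues, rtol=1e-10
        )

    def test_reconstruction_error_equals_discarded_variance(self, rng):
        X = rng.normal(size=(20, 12))
        k = 4
        model = pca_fit(X, k)
        full = pca_fit(X, min(19, 12))
        scores = pca_transform(model, X)
        recon = model.mean + scores @ model.loadings.T
        sse = np.sum((X - recon) ** 2)
        discarded = full.eigenvalues[k:].sum() * (len(X) - 1)
        assert sse == pytest.approx(discarded, rel=1e-8)

    def test_mean_row_maps_to_origin(self, rng):
        X = rng.normal(size=(15, 6))
        model = pca_fit(X, 2)
        np.testing.assert_allclose(pca_transform(model, model.mean), 0.0, atol=1e-10)

    def test_training_mean_used_for_new_rows(self, rng):
        """A constant test row is centered with the training mean, not its own."""
        X = rng.normal(size=(15, 6))
        model = pca_fit(X, 2)
        row = np.full(6, 3.0)
        expected = (row - model.mean) @ model.loadings
        np.testing.assert_allclose(pca_transform(model, row)[0], expected)

    def test_distances_preserved_in_subspace(self, rng):
        basis = np.linalg.qr(rng.normal(size=(9, 3)))[0]
        scores = rng.normal(size=(12, 3))
        X = scores @ basis.T + 2.0
        model = pca_fit(X, 3)
        Z = pca_transform(model, X)
        for i in (0, 3):
            for j in (5, 9):
                dx = np.linalg.norm(X[i] - X[j])
                dz = np.linalg.norm(Z[i] - Z[j])
                assert dz == pytest.approx(dx, rel=1e-8)

    def test_zero_variance_rejected(self):
        with pytest.raises(InvalidInputError):
            pca_fit(np.ones((5, 4)), 1)

    def test_dimension_mismatch(self, rng):
        model = pca_fit(rng.normal(size=(10, 4)), 2)
        with pytest.raises(DimensionMismatchError):
            pca_transform(model, np.zeros((3, 5)))


class TestNormalizeCurrent:
    def test_divides_by_concentration_times_rate(self, cv_erev):
        cond = cv_erev.conditions
        expected = cv_erev.currents / (cond.bulk_concentration * cond.scan_rate)
        np.testing.assert_allclose(normalize_current(cv_erev), expected)

    def test_collapses_concentration_dependence(self, erev_spec):
        """Current is linear in c0, so normalized traces at c0 and 2*c0 agree."""
        traces = []
        for c0 in (4e-7, 8e-7):
            cond = standard_conditions(0.5, bulk_concentration=c0)
            traces.append(normalize_current(simulate_cv(erev_spec, cond)))
        peak = np.abs(traces[0]).max()
        assert np.abs(traces[0] - traces[1]).max() / peak < 0.005


class TestFeatureMatrixCsv:
    def test_round_trip_with_manifest(self, tmp_path, rng):
        import pandas as pd

        from voltdiff.dataio import read_feature_matrix, write_feature_matrix
        from voltdiff.preprocess import PEAK_FEATURE_NAMES

        X = rng.normal(size=(6, 7))
        manifest = pd.DataFrame({"k1": np.arange(6.0), "D_true": np.full(6, 1e-5)})
        path = tmp_path / "features.csv"
        write_feature_matrix(path, X, PEAK_FEATURE_NAMES, manifest)
        X2, mani2 = read_feature_matrix(path, PEAK_FEATURE_NAMES)
        np.testing.assert_allclose(X2, X)
        assert list(mani2.columns) == ["k1", "D_true"]
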