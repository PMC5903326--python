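"""CSP contracts: covariance estimation, the generalized eigenproblem, and
the log-variance features, checked against analytic 2x2 cases and the
defining equation."""

import numpy as np
import pytest

from mibci.csp import (FeatureTable, compute_spatial_filters,
                       estimate_class_covariances, extract_features,
                       fit_spatial_filters)
from mibci.filterbank import BandedWindows


def _banded(data, labels):
    data = np.asarray(data, dtype=float)
    return BandedWindows(data=data, labels=np.asarray(labels, dtype="U4"),
                         band_edges=((8.0, 12.0),) * data.shape[1],
                         sampling_rate=256.0,
                         channel_names=tuple(f"ch{i}"
                                             for i in range(data.shape[2])),
                         trial_index=np.arange(data.shape[0]))


def _two_channel_toy(rng, n=20, ns=256):
    """Class MI: power on ch1 only; class REST: power on ch2 only."""
    data = np.zeros((2 * n, 1, 2, ns))
    labels = np.array(["MI", "REST"] * n, dtype="U4")
    data[labels == "MI", 0, 0] = rng.standard_normal((n, ns))
    data[labels == "MI", 0, 1] = 0.05 * rng.standard_normal((n, ns))
    data[labels == "REST", 0, 1] = rng.standard_normal((n, ns))
    data[labels == "REST", 0, 0] = 0.05 * rng.standard_normal((n, ns))
    return _banded(data, labels)


class TestClassCovariances:
    def test_identical_signals_give_equal_covariances(self, rng):
        x = rng.standard_normal((1, 3, 256))
        data = np.repeat(x[None], 4, axis=0)
        banded = _banded(data, ["MI", "MI", "REST", "REST"])
        s1, s2 = estimate_class_covariances(banded, 0)
        assert np.allclose(s1, s2)
        assert np.isclose(np.trace(s1), 1.0)  # trace-normalised

    def test_axis_aligned_classes(self, rng):
        s1, s2 = estimate_class_covariances(_two_channel_toy(rng), 0)
        assert s1[0, 0] > 0.95 and s1[1, 1] < 0.05
        assert s2[1, 1] > 0.95 and s2[0, 0] < 0.05

    def test_single_class_rejected(self, rng):
        banded = _banded(rng.standard_normal((4, 1, 2, 64)), ["MI"] * 4)
        with pytest.raises(ValueError, match="REST"):
            estimate_class_covariances(banded, 0)


class TestSpatialFilters:
    def test_equal_covariances_give_half_eigenvalues(self):
        w, lam = compute_spatial_filters(np.eye(3), np.eye(3))
        assert np.allclose(lam, 0.5)

    def test_analytic_2x2_case(self):
        # S1 = diag(3,1), S2 = diag(1,3): lambda = 3/4, 1/4, axis-aligned
        w, lam = compute_spatial_filters(np.diag([3.0, 1.0]),
                                         np.diag([1.0, 3.0]))
        assert np.allclose(lam, [0.75, 0.25])
        directions = np.abs(w / np.linalg.norm(w, axis=0))
        assert np.allclose(directions, np.eye(2), atol=1e-12)

    def test_defining_equation_residual_on_random_spd(self, rng):
        for _ in range(5):
            a = rng.standard_normal((11, 40))
            b = rng.standard_normal((11, 40))
            s1 = a @ a.T / 40
            s2 = b @ b.T / 40
            s1 /= np.trace(s1)
            s2 /= np.trace(s2)
            w, lam = compute_spatial_filters(s1, s2)
            assert np.all(np.diff(lam) <= 1e-12)  # sorted descending
            assert np.all((lam >= 0) & (lam <= 1))
            composite = s1 + s2
            for j in range(11):
                residual = s1 @ w[:, j] - lam[j] * composite @ w[:, j]
                assert np.linalg.norm(residual) < 1e-8
            # columns diagonalise S1 + S2
            off = w.T @ composite @ w - np.diag(np.diag(w.T @ composite @ w))
            assert np.max(np.abs(off)) < 1e-10

    def test_asymmetric_input_rejected(self, rng):
        s = rng.standard_normal((3, 3))
        with pytest.raises(ValueError, match="symmetric"):
            compute_spatial_filters(s, np.eye(3))


class TestFeatures:
    def test_66_features_band_major(self, small_features):
        assert small_features.X.shape[1] == 66
        names = small_features.column_names
        assert names[0] == "band_1_filter_1"
        assert names[11] == "band_2_filter_1"
        assert names[65] == "band_6_filter_11"

    def test_normalized_variances_sum_to_one_per_band(self, small_trials):
        from mibci.filterbank import apply_filter_bank, extract_windows
        banded = apply_filter_bank(extract_windows(small_trials))
        filters = fit_spatial_filters(banded)
        table = extract_features(banded, filters, log_transform=False)
        per_band = table.X.reshape(table.X.shape[0], 6, 11)
        assert np.allclose(per_band.sum(axis=-1), 1.0)

    def test_toy_discrimination(self, rng):
        banded = _two_channel_toy(rng)
        filters = fit_spatial_filters(banded)
        table = extract_features(banded, filters)
        mi_rows = table.labels == "MI"
        # filter 1 (largest eigenvalue) captures MI variance
        assert table.X[mi_rows, 0].mean() > table.X[mi_rows, 1].mean()

    def test_scale_and_sign_invariance(self, rng):
        banded = _two_channel_toy(rng)
        filters = fit_spatial_filters(banded)
        base = extract_features(banded, filters).X

        scaled = _banded(banded.data * 37.5, banded.labels)
        assert np.allclose(extract_features(scaled, filters).X, base,
                           atol=1e-10)

        flipped = fit_spatial_filters(banded)
        flipped.filters[0] = flipped.filters[0] * np.array([-1, 1])
        assert np.allclose(extract_features(banded, flipped).X, base,
                           atol=1e-10)

    def test_eigenvalue_variance_duality(self, small_trials):
        """Filters are (S1+S2)-orthonormal, so the mean MI-class projected
        variance of trace-normalised training windows through filter j
        approximates its generalized eigenvalue lambda_j."""
        from mibci.filterbank import apply_filter_bank, extract_windows
        banded = apply_filter_bank(extract_windows(small_trials))
        filters = fit_spatial_filters(banded)
        mi_rows = banded.labels == "MI"
        for band in range(6):
            x = banded.data[mi_rows, band]
            cov = np.einsum("wcs,wds->wcd", x, x)
            cov /= np.einsum("wcc->w", cov)[:, None, None]
            w = filters.filters[band]
            projected = np.einsum("cj,wcd,dj->wj", w, cov, w).mean(axis=0)
            assert np.max(np.abs(projected
                                 - filters.eigenvalues[band])) < 0.05

    def test_csv_round_trip(self, small_features, tmp_path):
        path = tmp_path / "features.csv"
        small_features.to_csv(path)
        loaded = FeatureTable.from_csv(path, n_bands=6, n_filters=11)
        assert np.allclose(loaded.X, small_features.X)
        assert np.array_equal(loaded.labels, small_features.labels)
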