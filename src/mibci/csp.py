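"""Common spatial patterns per subband and log-variance feature extraction.

For each subband, class covariance matrices S1 (MI) and S2 (REST) are
averaged over trace-normalised per-window covariances, and the spatial
filters are the generalized eigenvectors W of the pencil (S1, S1 + S2):
S1 w = lambda (S1 + S2) w, with eigenvalues in [0, 1] sorted descending.
Columns at the two ends of the spectrum maximise the variance contrast
between the classes.

A window x filtered into band b is projected through all channels' worth of
filters; the feature for filter j is

    f_{b,j} = log( var(w_{b,j}^T x_b) / sum_k var(w_{b,k}^T x_b) )

giving n_bands x n_channels features per window (66 for 6 bands x 11
channels), ordered band-major.  Features are a function of variance ratios,
so they are invariant to a common positive rescaling of the raw data and to
sign flips of any filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .filterbank import BandedWindows
from .synthetic import MI, REST

logger = logging.getLogger(__name__)

#: Relative ridge added to S1+S2 when it is numerically ill-conditioned.
REG_EPS = 1e-8
COND_THRESHOLD = 1e10


@dataclass
class SpatialFilterBank:
    """Per-subband CSP projection matrices.

    ``filters[b]`` is channels x channels; column j is the spatial filter of
    generalized eigenvalue ``eigenvalues[b][j]`` (sorted descending).
    """

    filters: list[np.ndarray]
    eigenvalues: list[np.ndarray]
    s1: list[np.ndarray]
    s2: list[np.ndarray]
    band_edges: tuple[tuple[float, float], ...]

    @property
    def n_bands(self) -> int:
        return len(self.filters)

    @property
    def n_channels(self) -> int:
        return self.filters[0].shape[0]


@dataclass
class FeatureTable:
    """Windows x features matrix with band/filter provenance per column."""

    X: np.ndarray
    labels: np.ndarray
    n_bands: int
    n_filters: int

    def __post_init__(self) -> None:
        if self.X.shape[1] != self.n_bands * self.n_filters:
            raise ValueError("feature count does not match bands x filters")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def column_names(self) -> list[str]:
        return [f"band_{b + 1}_filter_{j + 1}"
                for b in range(self.n_bands) for j in range(self.n_filters)]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.X, columns=self.column_names)
        frame["label"] = self.labels
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_bands: int, n_filters: int) -> "FeatureTable":
        frame = pd.read_csv(path)
        labels = frame.pop("label").to_numpy(dtype="U4")
        return cls(frame.to_numpy(dtype=np.float64), labels, n_bands, n_filters)


def _window_covariances(data: np.ndarray) -> np.ndarray:
    """Trace-normalised spatial covariance of each window (no mean removal:
    inputs are bandpassed, hence zero-mean by construction)."""
    cov = np.einsum("wcs,wds->wcd", data, data)
    trace = np.einsum("wcc->w", cov)
    trace[trace == 0] = 1.0
    return cov / trace[:, None, None]


def estimate_class_covariances(banded: BandedWindows, band: int,
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Average trace-normalised covariances per class for one subband.

    Returns (S1, S2) = (MI, REST) covariance estimates, channels x channels.
    """
    labels = banded.labels
    out = []
    for cls in (MI, REST):
        idx = labels == cls
        if idx.sum() < 2:
            raise ValueError(
                f"need >= 2 windows of class {cls} to estimate its covariance "
                f"(got {int(idx.sum())})")
        out.append(_window_covariances(banded.data[idx, band]).mean(axis=0))
    return out[0], out[1]


def compute_spatial_filters(s1: np.ndarray, s2: np.ndarray,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Solve S1 w = lambda (S1 + S2) w.

    Returns (W, eigenvalues) with eigenvalues sorted descending in [0, 1] and
    W's columns the corresponding filters (they diagonalise S1 + S2).
    """
    for name, s in (("S1", s1), ("S2", s2)):
        if not np.allclose(s, s.T, atol=1e-10):
            raise ValueError(f"{name} is not symmetric")
    s1 = 0.5 * (s1 + s1.T)
    s2 = 0.5 * (s2 + s2.T)
    composite = s1 + s2
    if np.linalg.cond(composite) > COND_THRESHOLD:
        ridge = REG_EPS * np.mean(np.diag(composite))
        logger.info("regularising ill-conditioned S1+S2 with ridge %.3e", ridge)
        composite = composite + ridge * np.eye(composite.shape[0])
    eigvals, eigvecs = linalg.eigh(s1, composite)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, 1.0)
    return eigvecs[:, order], eigvals


def fit_spatial_filters(banded: BandedWindows) -> SpatialFilterBank:
    """CSP filters for every subband, from (training) windows of both classes."""
    filters, eigenvalues, s1s, s2s = [], [], [], []
    for b in range(banded.n_bands):
        s1, s2 = estimate_class_covariances(banded, b)
        w, lam = compute_spatial_filters(s1, s2)
        filters.append(w)
        eigenvalues.append(lam)
        s1s.append(s1)
        s2s.append(s2)
    return SpatialFilterBank(filters=filters, eigenvalues=eigenvalues,
                             s1=s1s, s2=s2s, band_edges=banded.band_edges)


def _normalized_variances(banded_band: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Per-window projected variances through all filters, normalised to sum 1."""
    projected = np.einsum("ck,wcs->wks", w, banded_band)
    variances = projected.var(axis=-1)
    total = variances.sum(axis=1, keepdims=True)
    total[total == 0] = 1.0
    return variances / total


def extract_features(banded: BandedWindows, filter_bank: SpatialFilterBank,
                     log_transform: bool = True) -> FeatureTable:
    """Log-normalised-variance features for every window, band-major order.

    The filters must come from training data only; this function never refits
    them, which is the leakage guard for held-out evaluation windows.
    """
    if banded.n_bands != filter_bank.n_bands:
        raise ValueError("band count mismatch between windows and filters")
    blocks = []
    tiny = np.finfo(np.float64).tiny
    for b in range(banded.n_bands):
        ratios = _normalized_variances(banded.data[:, b], filter_bank.filters[b])
        if log_transform:
            if np.any(ratios <= 0):
                logger.warning("zero-variance projection floored at machine tiny")
            blocks.append(np.log(np.maximum(ratios, tiny)))
        else:
            blocks.append(ratios)
    X = np.concatenate(blocks, axis=1)
    return FeatureTable(X=X, labels=banded.labels.copy(),
                        n_bands=banded.n_bands,
                        n_filters=filter_bank.n_channels)


def extract_csp_pair_features(banded: BandedWindows,
                              filter_bank: SpatialFilterBank,
                              m: int = 2, band: int = 0,
                              log_transform: bool = True) -> FeatureTable:
    """Classic CSP feature vector: first and last ``m`` filters of one band.

    Variances are normalised over the 2m retained projections (the original
    CSP convention), then log-transformed.  Used by the single-band baseline.
    """
    w = filter_bank.filters[band]
    keep = list(range(m)) + list(range(w.shape[1] - m, w.shape[1]))
    projected = np.einsum("ck,wcs->wks", w[:, keep], banded.data[:, band])
    variances = projected.var(axis=-1)
    total = variances.sum(axis=1, keepdims=True)
    total[total == 0] = 1.0
    ratios = variances / total
    tiny = np.finfo(np.float64).tiny
    X = np.log(np.maximum(ratios, tiny)) if log_transform else ratios
    return FeatureTable(X=X, labels=banded.labels.copy(), n_bands=1,
                        n_filters=2 * m)
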