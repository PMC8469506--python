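"""Principal-component reduction of 401-band spectra.

Spectra are mean-centered (never variance-scaled: all bands share reflectance
units) and projected onto the top-k eigenvectors of the 1/(n-1) sample
covariance.  The default k is 3; scatter plots conventionally show the first
two scores.  Loadings follow a fixed sign convention — the largest-magnitude
element of each loading is positive — so bases are reproducible across runs
and input orderings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA as _SkPCA

from .errors import ConfigurationError, DimensionError, GridError
from .grid import N_BANDS


@dataclass(frozen=True)
class PCABasis:
    mean_spectrum: np.ndarray        # (401,)
    loadings: np.ndarray             # (k, 401), rows orthonormal
    explained_variance: np.ndarray   # (k,), descending
    k: int

    def __post_init__(self):
        if self.loadings.shape != (self.k, N_BANDS):
            raise DimensionError(f"loadings must be ({self.k}, {N_BANDS})")
        if self.mean_spectrum.shape != (N_BANDS,):
            raise DimensionError(f"mean spectrum must have {N_BANDS} bands")
        gram = self.loadings @ self.loadings.T
        if not np.allclose(gram, np.eye(self.k), atol=1e-8):
            raise ConfigurationError("loadings are not orthonormal")
        ev = self.explained_variance
        if np.any(ev < -1e-12) or np.any(np.diff(ev) > 1e-12):
            raise ConfigurationError("explained variance must be nonnegative and descending")


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude element of each loading positive (ties: first)."""
    out = loadings.copy()
    for i, row in enumerate(out):
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            out[i] = -row
    return out


def fit_pca(spectra: np.ndarray, k: int = 3) -> PCABasis:
    """Fit a k-component basis to an (n, 401) collection of spectra."""
    X = np.asarray(spectra, dtype=float)
    if X.ndim != 2 or X.shape[1] != N_BANDS:
        raise DimensionError(f"expected (n, {N_BANDS}) spectra, got {X.shape}")
    n = X.shape[0]
    if k < 1 or k > min(n - 1, N_BANDS):
        raise ConfigurationError(f"k={k} requires at least k+1 spectra (have {n})")
    model = _SkPCA(n_components=k, svd_solver="full")
    model.fit(X)
    loadings = _fix_signs(model.components_)
    return PCABasis(mean_spectrum=model.mean_.copy(), loadings=loadings,
                    explained_variance=model.explained_variance_.copy(), k=k)


def transform(basis: PCABasis, spectra: np.ndarray) -> np.ndarray:
    """Project one spectrum (401,) or a batch (n, 401) onto the basis scores."""
    X = np.asarray(spectra, dtype=float)
    if X.shape[-1] != N_BANDS:
        raise GridError(f"spectrum grid mismatch: expected {N_BANDS} bands, got {X.shape[-1]}")
    return (X - basis.mean_spectrum) @ basis.loadings.T


def inverse_transform(basis: PCABasis, scores: np.ndarray) -> np.ndarray:
    """Reconstruct spectra from scores: mean + sum_i score_i * loading_i (no clipping)."""
    s = np.asarray(scores, dtype=float)
    if s.shape[-1] != basis.k:
        raise DimensionError(f"expected {basis.k} scores, got {s.shape[-1]}")
    return basis.mean_spectrum + s @ basis.loadings


def separability_ratio(scores: np.ndarray, labels: np.ndarray) -> float:
    """Between-group / within-group variance ratio of score vectors.

    Used to quantify how well stage labels separate in the reduced space
    (compared against the same statistic under a label permutation).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    overall = scores.mean(axis=0)
    between = 0.0
    within = 0.0
    for lab in np.unique(labels):
        grp = scores[labels == lab]
        between += len(grp) * float(np.sum((grp.mean(axis=0) - overall) ** 2))
        within += float(np.sum((grp - grp.mean(axis=0)) ** 2))
    if within == 0:
        return np.inf
    return between / within
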