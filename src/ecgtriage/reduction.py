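"""Train-set-fitted dimensionality reduction for the 156 ECG measurements.

Features are standardized (the raw measures mix mV, ms and mV*ms scales),
projected onto the leading 20 principal components, and the component
scores are Z-scored with parameters estimated on the training projections.
Application to new data is a pure function of the stored parameters: no
test-set statistics ever enter the reducer.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA


@dataclass(frozen=True)
class Reducer:
    """Standardization + PCA loadings + score Z-score parameters."""

    feature_means: np.ndarray       # (156,)
    feature_sds: np.ndarray         # (156,), all > 0
    loadings: np.ndarray            # (156, k), orthonormal columns
    eigenvalues: np.ndarray         # (k,), non-increasing
    explained_variance_ratio: np.ndarray
    score_means: np.ndarray         # (k,)
    score_sds: np.ndarray           # (k,), all > 0

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def to_json(self, path: str | Path) -> None:
        payload = {k: np.asarray(getattr(self, k)).tolist()
                   for k in ("feature_means", "feature_sds", "loadings",
                             "eigenvalues", "explained_variance_ratio",
                             "score_means", "score_sds")}
        Path(path).write_text(json.dumps(payload, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "Reducer":
        payload = json.loads(Path(path).read_text())
        return cls(**{k: np.asarray(v, dtype=float) for k, v in payload.items()})


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Flip each component so its largest-magnitude loading is positive."""
    flips = np.sign(loadings[np.argmax(np.abs(loadings), axis=0),
                             np.arange(loadings.shape[1])])
    flips[flips == 0] = 1.0
    return loadings * flips


def fit_reducer(train_matrix: np.ndarray, n_components: int = 20) -> Reducer:
    """Fit standardization, PCA and score Z-scoring on training data only.

    Constant feature columns get sd 1 (with a warning) so they contribute
    nothing after centering. Component signs are fixed deterministically.
    """
    X = np.asarray(train_matrix, dtype=float)
    n, p = X.shape
    if n < n_components + 1:
        raise ValueError(f"need at least {n_components + 1} training rows, got {n}")
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    constant = sds < 1e-12
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant feature column(s); "
                      "sd set to 1", stacklevel=2)
        sds = np.where(constant, 1.0, sds)
    Xs = (X - means) / sds

    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(Xs)
    loadings = _fix_signs(pca.components_.T)
    scores = Xs @ loadings
    score_means = scores.mean(axis=0)
    score_sds = scores.std(axis=0)
    degenerate = score_sds < 1e-12
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance component score(s); "
                      "sd set to 1", stacklevel=2)
        score_sds = np.where(degenerate, 1.0, score_sds)
    return Reducer(feature_means=means, feature_sds=sds, loadings=loadings,
                   eigenvalues=pca.explained_variance_.copy(),
                   explained_variance_ratio=pca.explained_variance_ratio_.copy(),
                   score_means=score_means, score_sds=score_sds)


def apply_reducer(reducer: Reducer, matrix: np.ndarray) -> np.ndarray:
    """Project rows onto the stored components and Z-score; pure function."""
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    if X.shape[1] != reducer.feature_means.shape[0]:
        raise ValueError(f"expected {reducer.feature_means.shape[0]} columns, "
                         f"got {X.shape[1]}")
    scores = ((X - reducer.feature_means) / reducer.feature_sds) @ reducer.loadings
    return (scores - reducer.score_means) / reducer.score_sds


def reconstruct(reducer: Reducer, z_scores: np.ndarray) -> np.ndarray:
    """Map Z-scored component scores back to standardized feature space."""
    Z = np.atleast_2d(np.asarray(z_scores, dtype=float))
    scores = Z * reducer.score_sds + reducer.score_means
    return scores @ reducer.loadings.T
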