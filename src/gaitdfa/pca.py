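"""Covariance PCA of the spectral feature matrix.

The decomposition is computed by singular value decomposition of the
mean-centred matrix, which is mathematically identical to an
eigendecomposition of the (n-1)-normalised covariance matrix but avoids
forming the 1500 x 1500 covariance explicitly. No variable standardisation is
applied: covariance, not correlation, so variable scales influence the
components, by design. Eigenvector sign is arbitrary; for reproducibility each
loading's largest-magnitude coefficient is made positive.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError
from .preprocess import FeatureMatrix

ORTHONORMALITY_TOL = 1e-8


@dataclasses.dataclass
class PCAModel:
    """Fitted principal-component basis.

    ``loadings`` is ``(n_features, k)`` with orthonormal columns sorted by
    non-increasing ``variances`` (covariance eigenvalues, n-1 normalisation).
    ``total_variance`` is the trace of the training covariance, for scree and
    residual-variance bookkeeping.
    """

    mean: np.ndarray
    loadings: np.ndarray
    variances: np.ndarray
    k: int
    n_train: int
    total_variance: float

    @property
    def n_features(self) -> int:
        return self.loadings.shape[0]

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            mean=self.mean,
            loadings=self.loadings,
            variances=self.variances,
            k=self.k,
            n_train=self.n_train,
            total_variance=self.total_variance,
        )

    @classmethod
    def load(cls, path: str | Path) -> "PCAModel":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                mean=z["mean"],
                loadings=z["loadings"],
                variances=z["variances"],
                k=int(z["k"]),
                n_train=int(z["n_train"]),
                total_variance=float(z["total_variance"]),
            )


@dataclasses.dataclass
class ScoreMatrix:
    """PC scores for a set of trials, with labels and subject ids carried through."""

    scores: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    @property
    def n_trials(self) -> int:
        return self.scores.shape[0]

    def rows(self, mask: np.ndarray) -> "ScoreMatrix":
        return ScoreMatrix(self.scores[mask], self.labels[mask], self.subject_ids[mask])


def _as_array(matrix) -> np.ndarray:
    if isinstance(matrix, FeatureMatrix):
        return matrix.features
    return np.asarray(matrix, dtype=float)


def fit_pca(matrix: FeatureMatrix | np.ndarray, k: int) -> PCAModel:
    """Fit a k-component covariance PCA to the rows of ``matrix``.

    Requires ``n_trials >= 2`` and ``1 <= k <= min(n_trials - 1, n_features)``;
    a matrix with zero total variance is rejected.
    """
    X = _as_array(matrix)
    n, p = X.shape
    if n < 2:
        raise ParameterError("PCA needs at least 2 rows")
    k_max = min(n - 1, p)
    if not 1 <= k <= k_max:
        raise ParameterError(f"k must be in [1, {k_max}]; got {k}")
    mean = X.mean(axis=0)
    Xc = X - mean
    total_variance = float(np.sum(Xc**2)) / (n - 1)
    if total_variance == 0.0:
        raise DataError("zero-variance matrix: PCA undefined")
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    variances = s**2 / (n - 1)
    loadings = Vt[:k].T.copy()
    # deterministic sign: largest-magnitude coefficient of each loading positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    loadings *= flip
    return PCAModel(
        mean=mean,
        loadings=loadings,
        variances=variances[:k].copy(),
        k=k,
        n_train=n,
        total_variance=total_variance,
    )


def project(model: PCAModel, matrix: FeatureMatrix | np.ndarray) -> ScoreMatrix:
    """Project (possibly unseen) trials onto the fitted components.

    Pure function of the model: scores = (rows - mean) @ loadings, row by row,
    so projecting training and test rows together or separately is identical.
    """
    X = _as_array(matrix)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ParameterError(
            f"feature width {X.shape[1]} does not match model ({model.n_features})"
        )
    scores = (X - model.mean) @ model.loadings
    if isinstance(matrix, FeatureMatrix):
        labels, subjects = matrix.labels, matrix.subject_ids
    else:
        labels = np.array([""] * X.shape[0])
        subjects = np.array([""] * X.shape[0])
    return ScoreMatrix(scores=scores, labels=labels, subject_ids=subjects)


def scree(model: PCAModel) -> pd.DataFrame:
    """Eigenvalue, variance fraction and cumulative fraction per retained rank.

    Lets the analyst verify that the highest rank in use sits well below the
    last rank still carrying structure before trusting the reduction.
    """
    frac = model.variances / model.total_variance
    return pd.DataFrame(
        {
            "rank": np.arange(1, model.k + 1),
            "eigenvalue": model.variances,
            "variance_fraction": frac,
            "cumulative_fraction": np.cumsum(frac),
        }
    )
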