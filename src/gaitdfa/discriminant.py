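"""Two-class discriminant function analysis (DFA/LDA) on PC scores.

The discriminant axes maximise the ratio of between-class to within-class
variance, i.e. they solve the generalized eigenproblem S_B w = lambda S_W w in
PC-score space. With two classes S_B has rank 1, so only the first axis
carries discrimination; a second axis (the next generalized eigenvector, with
a near-zero eigenvalue) is nevertheless kept so trials live in a 2-D DF plane,
and its eigenvalue is reported so the imbalance is visible.

Because PC scores are themselves linear in the (centred) spectral features,
each DF weight vector back-projects through the PCA loadings into a
variable x frequency "DF spectrum": the inner product of a centred trial
feature row with a DF spectrum reproduces that trial's DF score exactly.
Integrating |DF spectrum| over frequency per variable yields each variable's
contribution to the discrimination, and a ranking of the 30 variables.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .catalog import N_VARIABLES, POSITIVE_CONDITION, VARIABLE_NAMES
from .errors import DataError, ParameterError
from .pca import PCAModel, ScoreMatrix

#: Within-class scatter condition number above which ridge regularisation kicks in.
RIDGE_CONDITION_LIMIT = 1e10
RIDGE_SCALE = 1e-8


@dataclasses.dataclass
class DFModel:
    """Fitted discriminant: two weight vectors in PC space plus derived artefacts.

    ``weights`` is ``(k, 2)`` (unit-norm columns); ``eigenvalues`` the two
    between/within variance ratios (non-increasing, second ~0 for two classes);
    ``centroid_pos``/``centroid_neg`` the training-class centres in DF space.
    ``df_spectra``/``contributions``/``ranking`` are filled by
    :func:`df_spectra` and :func:`variable_contributions`.
    """

    weights: np.ndarray
    eigenvalues: np.ndarray
    centroid_pos: np.ndarray
    centroid_neg: np.ndarray
    positive_label: str
    negative_label: str
    spectra: np.ndarray | None = None  # (2, 30, n_bins)
    contributions: np.ndarray | None = None  # (2, 30)
    ranking: list[str] | None = None

    @property
    def k(self) -> int:
        return self.weights.shape[0]


def _scatter_matrices(scores: np.ndarray, pos_mask: np.ndarray):
    X0, X1 = scores[pos_mask], scores[~pos_mask]
    m0, m1 = X0.mean(axis=0), X1.mean(axis=0)
    Sw = (X0 - m0).T @ (X0 - m0) + (X1 - m1).T @ (X1 - m1)
    d = m0 - m1
    n0, n1 = len(X0), len(X1)
    Sb = (n0 * n1 / (n0 + n1)) * np.outer(d, d)
    return Sw, Sb, m0, m1


def fit_dfa(
    scores: ScoreMatrix,
    positive_label: str = POSITIVE_CONDITION,
    ridge: str | float = "auto",
) -> DFModel:
    """Fit the two-axis discriminant to labelled training scores.

    Both classes need at least 2 trials. Axis 1 attains the maximal
    between/within variance ratio; its sign is fixed so the positive class
    (shod) centroid has a positive DF-1 coordinate. ``ridge`` adds
    ``eps * I`` to the within-class scatter when it is ill-conditioned
    ("auto"), always (a float eps), or never (``ridge=None`` raises instead).
    """
    labels = np.asarray(scores.labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise DataError(f"DFA needs exactly two classes; got {classes}")
    if positive_label not in classes:
        raise ParameterError(f"positive label {positive_label!r} not among {classes}")
    negative_label = next(c for c in classes if c != positive_label)
    pos_mask = labels == positive_label
    if pos_mask.sum() < 2 or (~pos_mask).sum() < 2:
        raise DataError("each class needs at least 2 trials")

    S = np.asarray(scores.scores, dtype=float)
    k = S.shape[1]
    Sw, Sb, m_pos, m_neg = _scatter_matrices(S, pos_mask)

    cond = np.linalg.cond(Sw)
    if ridge == "auto":
        if cond > RIDGE_CONDITION_LIMIT:
            Sw = Sw + (RIDGE_SCALE * np.trace(Sw) / k) * np.eye(k)
    elif isinstance(ridge, (int, float)):
        Sw = Sw + float(ridge) * np.eye(k)
    elif cond > RIDGE_CONDITION_LIMIT:
        raise DataError(
            f"within-class scatter ill-conditioned (cond={cond:.2e}); enable ridge"
        )

    eigvals, eigvecs = sla.eigh(Sb, Sw)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order[:2]], eigvecs[:, order[:2]]
    if k == 1:  # degenerate: duplicate the single axis slot with a zero eigenvalue
        eigvals = np.array([eigvals[0], 0.0])
        eigvecs = np.column_stack([eigvecs[:, 0], eigvecs[:, 0]])
    eigvals = np.maximum(eigvals, 0.0)
    W = eigvecs / np.linalg.norm(eigvecs, axis=0)

    # sign conventions: positive-class centroid positive on DF1; axis 2 by
    # largest-magnitude coefficient (its eigenvalue ~0 leaves no class cue)
    if (m_pos - m_neg) @ W[:, 0] < 0:
        W[:, 0] = -W[:, 0]
    s2 = np.sign(W[np.abs(W[:, 1]).argmax(), 1])
    if s2 < 0:
        W[:, 1] = -W[:, 1]

    model = DFModel(
        weights=W,
        eigenvalues=eigvals,
        centroid_pos=m_pos @ W,
        centroid_neg=m_neg @ W,
        positive_label=positive_label,
        negative_label=negative_label,
    )
    return model


def df_scores(model: DFModel, scores: ScoreMatrix | np.ndarray) -> np.ndarray:
    """Project PC scores (training or unseen) onto the two DF axes -> ``(n, 2)``."""
    S = scores.scores if isinstance(scores, ScoreMatrix) else np.asarray(scores, float)
    if S.ndim == 1:
        S = S[None, :]
    if S.shape[1] != model.k:
        raise ParameterError(f"score width {S.shape[1]} does not match k={model.k}")
    return S @ model.weights


def df_spectra(model: DFModel, pca: PCAModel, n_variables: int = N_VARIABLES) -> np.ndarray:
    """Back-project the DF weights into variable x frequency space.

    Returns ``(2, n_variables, n_bins)`` and caches it on the model. By
    construction, ``(feature_row - pca.mean) . spectrum(axis)`` equals the
    trial's DF score on that axis.
    """
    if pca.k != model.k:
        raise ParameterError(f"PCA rank {pca.k} does not match DF weight length {model.k}")
    if pca.n_features % n_variables:
        raise ParameterError(
            f"feature width {pca.n_features} not divisible by {n_variables} variables"
        )
    n_bins = pca.n_features // n_variables
    flat = pca.loadings @ model.weights  # (n_features, 2)
    model.spectra = flat.T.reshape(2, n_variables, n_bins)
    return model.spectra


def variable_contributions(model: DFModel) -> pd.DataFrame:
    """Per-variable discrimination weight: integral of |DF spectrum| over frequency.

    Returns a table (variable, axis-1, axis-2, combined, rank), decreasing by
    the ranking key; ties broken by catalog order. Also caches
    ``model.contributions`` (2 x 30) and ``model.ranking``.

    The ranking key sums the per-axis contributions weighted by each axis's
    discrimination eigenvalue (normalised). With two classes the second axis
    has a near-zero eigenvalue and an essentially arbitrary direction, so an
    unweighted sum would let that direction inject noise into the ranking;
    the eigenvalue weights make the ranking follow the axes in proportion to
    the discrimination they actually carry. ``combined`` in the table stays
    the plain axis sum, so per-axis contribution mass is conserved.
    """
    if model.spectra is None:
        raise DataError("call df_spectra() before variable_contributions()")
    contrib = np.abs(model.spectra).sum(axis=2)  # (2, n_variables)
    combined = contrib.sum(axis=0)
    ev = model.eigenvalues
    weights = ev / ev.sum() if ev.sum() > 0 else np.array([0.5, 0.5])
    key = weights @ contrib
    # stable sort keeps catalog order among ties
    order = np.argsort(-key, kind="stable")
    names = [VARIABLE_NAMES[i] for i in range(len(combined))]
    table = pd.DataFrame(
        {
            "variable": names,
            "df1_contribution": contrib[0],
            "df2_contribution": contrib[1],
            "combined": combined,
            "ranking_key": key,
        }
    )
    table["rank"] = np.empty(len(combined), dtype=int)
    table.loc[order, "rank"] = np.arange(1, len(combined) + 1)
    table = table.sort_values("rank").reset_index(drop=True)
    model.contributions = contrib
    model.ranking = table["variable"].tolist()
    return table
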