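"""Model/results interface tying the PCA -> DFA -> centroid-rule stages together.

`GaitDiscriminant` is constructed from a feature matrix plus the choice of
training subjects and PCA rank; `fit()` runs the composite pipeline — PCA on
the training rows (or on everything, in pooled mode), projection of all
trials, DFA on the training scores, DF projection of all trials, and the
centroid distance-ratio assignment — and returns a `GaitDiscriminantResults`
carrying the fitted sub-models, the per-trial evaluation, the back-projected
DF spectra and the variable contribution ranking, with a `summary()` table.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import classify, discriminant, pca
from .classify import EvalReport
from .discriminant import DFModel
from .errors import ParameterError
from .pca import PCAModel, ScoreMatrix
from .preprocess import FeatureMatrix, PreprocessConfig, build_feature_matrix

DEFAULT_K = 10


class GaitDiscriminant:
    """Two-condition discriminant pipeline over spectral gait features.

    Parameters
    ----------
    features
        The trials x (30 * n_bins) feature matrix with labels and subject ids.
    training_subjects
        Subjects whose trials train the PCA and DFA; the rest are predicted.
        ``None`` selects every subject (pooled discrimination, no held-out
        prediction stage).
    k
        Number of principal components fed to the discriminant (default 10;
        8 and 12 are the other customary choices).
    pca_mode
        "refit": PCA fitted on the training rows only (the honest predictive
        protocol). "pooled": PCA fitted on all trials regardless of the
        training split.
    n_df_axes
        2 (default) evaluates centroid distances in the full DF plane; 1
        restricts them to DF axis 1, side-stepping the near-zero-eigenvalue
        second axis of a two-class discriminant.
    """

    def __init__(
        self,
        features: FeatureMatrix,
        training_subjects=None,
        k: int = DEFAULT_K,
        pca_mode: str = "refit",
        n_df_axes: int = 2,
    ):
        if pca_mode not in ("refit", "pooled"):
            raise ParameterError(f"unknown pca_mode {pca_mode!r}")
        if n_df_axes not in (1, 2):
            raise ParameterError("n_df_axes must be 1 or 2")
        self.features = features
        all_subjects = features.subjects
        if training_subjects is None:
            training_subjects = all_subjects
        training_subjects = sorted(str(s) for s in training_subjects)
        unknown = set(training_subjects) - set(all_subjects)
        if unknown:
            raise ParameterError(f"training subjects not in cohort: {sorted(unknown)}")
        self.training_subjects = training_subjects
        self.k = int(k)
        self.pca_mode = pca_mode
        self.n_df_axes = n_df_axes

    @classmethod
    def from_cohort(
        cls,
        cohort,
        config: PreprocessConfig | None = None,
        training_subjects=None,
        k: int = DEFAULT_K,
        pca_mode: str = "refit",
    ) -> "GaitDiscriminant":
        """Build straight from a cohort, running preprocessing internally."""
        return cls(build_feature_matrix(cohort, config), training_subjects, k, pca_mode)

    def fit(self) -> "GaitDiscriminantResults":
        feats = self.features
        train_mask = feats.rows_for_subjects(self.training_subjects)
        fit_rows = feats.features if self.pca_mode == "pooled" else feats.features[train_mask]
        pca_model = pca.fit_pca(fit_rows, self.k)
        scores = pca.project(pca_model, feats)
        dfa_model = discriminant.fit_dfa(scores.rows(train_mask))
        coords = discriminant.df_scores(dfa_model, scores)
        d = self.n_df_axes
        report = classify.evaluate_assignment(
            coords[:, :d],
            feats.labels,
            feats.subject_ids,
            train_mask,
            dfa_model.centroid_pos[:d],
            dfa_model.centroid_neg[:d],
        )
        discriminant.df_spectra(dfa_model, pca_model)
        contributions = discriminant.variable_contributions(dfa_model)
        return GaitDiscriminantResults(
            model=self,
            pca=pca_model,
            scores=scores,
            dfa=dfa_model,
            df_coords=coords,
            report=report,
            contributions=contributions,
        )


@dataclasses.dataclass
class GaitDiscriminantResults:
    """Everything the fitted pipeline produced for one training split."""

    model: GaitDiscriminant
    pca: PCAModel
    scores: ScoreMatrix
    dfa: DFModel
    df_coords: np.ndarray
    report: EvalReport
    contributions: pd.DataFrame

    @property
    def ranking(self) -> list[str]:
        """The 30 variables in decreasing order of discrimination contribution."""
        return list(self.contributions["variable"])

    def summary(self) -> str:
        r = self.report
        lines = [
            "Gait discriminant pipeline (spectral PCA + two-class DFA)",
            "=" * 60,
            f"trials: {self.model.features.n_trials}   "
            f"subjects: {len(self.model.features.subjects)}   "
            f"PC rank k: {self.model.k}   PCA mode: {self.model.pca_mode}",
            f"training subjects ({len(self.model.training_subjects)}): "
            + ", ".join(self.model.training_subjects),
            f"DF eigenvalues (between/within ratio): "
            f"{self.dfa.eigenvalues[0]:.4g}, {self.dfa.eigenvalues[1]:.4g}",
            "-" * 60,
            f"overall error:    {r.overall_error_pct:6.2f} %",
            f"training error:   {r.train_error_pct:6.2f} %",
            f"prediction error: {r.test_error_pct:6.2f} %",
            f"sensitivity (shod as positive): {r.sensitivity:.3f}",
            f"specificity:                    {r.specificity:.3f}",
            f"confusion: TP={r.confusion.TP} FN={r.confusion.FN} "
            f"TN={r.confusion.TN} FP={r.confusion.FP}",
            "-" * 60,
            "top discriminating variables: " + ", ".join(self.ranking[:4]),
        ]
        return "\n".join(lines)

    # -- plotting (optional matplotlib) --------------------------------------

    def plot_df_scatter(self, ax=None):
        """DF-plane scatter of all trials, coloured by condition, marked by partition."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pt = self.report.per_trial
        for cond, colour in ((self.dfa.positive_label, "C3"), (self.dfa.negative_label, "C0")):
            for part, marker in (("training", "o"), ("predicted", "^")):
                sel = (pt["condition"] == cond) & (pt["partition"] == part)
                ax.scatter(
                    pt.loc[sel, "df1"], pt.loc[sel, "df2"],
                    c=colour, marker=marker, s=18, alpha=0.7,
                    label=f"{cond} ({part})",
                )
        for c, colour in ((self.dfa.centroid_pos, "C3"), (self.dfa.centroid_neg, "C0")):
            ax.scatter(*c, c=colour, marker="X", s=120, edgecolor="k", zorder=5)
        ax.set_xlabel("DF score 1")
        ax.set_ylabel("DF score 2")
        ax.legend(fontsize=7)
        return ax

    def plot_contributions(self, ax=None):
        """Per-variable integrated |DF spectrum| bars for both axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        from .catalog import VARIABLE_NAMES

        t = (
            self.contributions.set_index("variable")
            .loc[list(VARIABLE_NAMES)]
            .reset_index()
        )
        x = np.arange(len(t))
        ax.bar(x - 0.2, t["df1_contribution"], width=0.4, label="DF 1")
        ax.bar(x + 0.2, t["df2_contribution"], width=0.4, label="DF 2")
        ax.set_xticks(x)
        ax.set_xticklabels(t["variable"], rotation=90, fontsize=6)
        ax.set_ylabel("integrated |DF spectrum|")
        ax.legend()
        return ax
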