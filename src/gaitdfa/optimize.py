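"""Exhaustive training-subset optimisation.

Every choice of r training subjects out of n defines one iteration: PCA is
fitted on the training trials, all trials are projected, a two-class DFA is
fitted on the training scores, and every trial is assigned by the centroid
distance-ratio rule. The iteration's overall / training-only / prediction-only
error rates are recorded; the subset with the lowest overall error is the
optimised training database. For the reference cohort (10 of 20 subjects)
there are C(20,10) = 184,756 iterations.

The enumeration loop uses a Gram-matrix formulation of the PCA: the top-k
eigenvectors of the doubly centred training Gram matrix give the PC scores of
all trials directly through the cross Gram block, without touching the
1500-dimensional feature space per iteration. This is algebraically identical
to the SVD route in :mod:`gaitdfa.pca` up to per-component sign, which the
centroid-ratio classifier is invariant to; the test suite asserts the error
rates agree with the reference path. A subset and its complement are distinct
iterations (training on S is not training on its complement).

Results are reproducible bitwise regardless of worker count or evaluation
order, and can be checkpointed to a CSV so long runs are resumable.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .catalog import POSITIVE_CONDITION
from .discriminant import RIDGE_CONDITION_LIMIT, RIDGE_SCALE
from .errors import DataError, ParameterError
from .pipeline import GaitDiscriminant
from .preprocess import FeatureMatrix

SUBSET_JOIN = "+"


def enumerate_subsets(n: int, r: int) -> list[tuple[int, ...]]:
    """All C(n, r) index subsets in lexicographic order, duplicate-free."""
    if not 0 < r < n:
        raise ParameterError(f"need 0 < r < n; got r={r}, n={n}")
    return list(itertools.combinations(range(n), r))


@dataclasses.dataclass
class IterationResult:
    """Outcome of one training-subset choice."""

    training_subjects: tuple[str, ...]
    overall_error_pct: float
    train_error_pct: float
    test_error_pct: float
    k: int
    flag: str | None = None


# ---------------------------------------------------------------------------
# fast per-iteration engine


class _Engine:
    """Precomputed state for evaluating many subsets of one feature matrix."""

    def __init__(self, features: FeatureMatrix, k: int, pca_mode: str):
        X = np.ascontiguousarray(features.features, dtype=float)
        self.n_rows = X.shape[0]
        self.k = k
        self.pca_mode = pca_mode
        self.labels_pos = features.labels == POSITIVE_CONDITION
        if not (self.labels_pos.any() and (~self.labels_pos).any()):
            raise DataError("feature matrix must contain both conditions")
        self.subjects = features.subjects
        sid = features.subject_ids
        self.subject_rows = [np.flatnonzero(sid == s) for s in self.subjects]
        if pca_mode == "pooled":
            from .pca import fit_pca, project

            model = fit_pca(X, k)
            self.pooled_scores = project(model, X).scores
            self.G = None
        elif pca_mode == "refit":
            self.pooled_scores = None
            self.G = X @ X.T
        else:
            raise ParameterError(f"unknown pca_mode {pca_mode!r}")

    def train_rows(self, subset: tuple[int, ...]) -> np.ndarray:
        return np.concatenate([self.subject_rows[i] for i in subset])

    def scores_for(self, idx: np.ndarray) -> np.ndarray:
        """PC scores of ALL trials for a PCA fitted on training rows ``idx``."""
        if self.pooled_scores is not None:
            return self.pooled_scores
        G, k, m = self.G, self.k, len(idx)
        if k > m - 1:
            raise DataError(f"k={k} exceeds training rank {m - 1}")
        Gt = G[np.ix_(idx, idx)]
        rm = Gt.mean(axis=0)
        gm = rm.mean()
        Gc = Gt - rm[None, :] - rm[:, None] + gm
        w, V = sla.eigh(Gc, subset_by_index=[m - k, m - 1], driver="evr")
        w = w[::-1]
        V = V[:, ::-1]
        s = np.sqrt(np.maximum(w, 0.0))
        if s[0] == 0.0:
            raise DataError("zero-variance training matrix")
        # cross block (X_all - mu) (X_train - mu)^T, from G alone
        C = G[:, idx] - rm[None, :] - G[:, idx].mean(axis=1)[:, None] + gm
        return C @ (V / s)

    def evaluate(self, subset: tuple[int, ...]) -> tuple[float, float, float]:
        """Overall / train / test error percentages for one subset choice."""
        idx = self.train_rows(subset)
        S = self.scores_for(idx)
        train_mask = np.zeros(self.n_rows, dtype=bool)
        train_mask[idx] = True
        pos = self.labels_pos

        St = S[idx]
        pt = pos[idx]
        if pt.sum() < 2 or (~pt).sum() < 2:
            raise DataError("degenerate training class (fewer than 2 trials)")
        m_pos = St[pt].mean(axis=0)
        m_neg = St[~pt].mean(axis=0)
        Xc0 = St[pt] - m_pos
        Xc1 = St[~pt] - m_neg
        Sw = Xc0.T @ Xc0 + Xc1.T @ Xc1
        if np.linalg.cond(Sw) > RIDGE_CONDITION_LIMIT:
            Sw = Sw + (RIDGE_SCALE * np.trace(Sw) / self.k) * np.eye(self.k)
        d = m_pos - m_neg
        n0, n1 = int(pt.sum()), int((~pt).sum())
        Sb = (n0 * n1 / (n0 + n1)) * np.outer(d, d)
        _, EV = sla.eigh(Sb, Sw)
        W = EV[:, [-1, -2]] if self.k > 1 else EV[:, [0, 0]]

        D = S @ W
        c_pos = D[idx][pt].mean(axis=0)
        c_neg = D[idx][~pt].mean(axis=0)
        d_pos = np.linalg.norm(D - c_pos, axis=1)
        d_neg = np.linalg.norm(D - c_neg, axis=1)
        # ratio rule: < 1 -> positive, > 1 -> negative, tie -> error
        pred_pos = d_pos < d_neg
        wrong = pred_pos != pos
        wrong |= d_pos == d_neg
        return (
            100.0 * wrong.mean(),
            100.0 * wrong[train_mask].mean(),
            100.0 * wrong[~train_mask].mean(),
        )

    def evaluate_safe(self, subset: tuple[int, ...]) -> tuple[float, float, float]:
        try:
            return self.evaluate(subset)
        except (DataError, np.linalg.LinAlgError):
            return (math.nan, math.nan, math.nan)


def _eval_chunk(engine: _Engine, subsets: list[tuple[int, ...]]) -> np.ndarray:
    out = np.empty((len(subsets), 3))
    for i, subset in enumerate(subsets):
        out[i] = engine.evaluate_safe(subset)
    return out


# ---------------------------------------------------------------------------
# public operations


def evaluate_iteration(
    features: FeatureMatrix,
    training_subjects,
    k: int = 10,
    pca_mode: str = "refit",
) -> IterationResult:
    """Evaluate one training-subset choice through the reference pipeline.

    A degenerate iteration (e.g. a training class with fewer than 2 trials)
    is flagged and returns NaN errors instead of raising, so bulk callers can
    continue.
    """
    subjects = tuple(sorted(str(s) for s in training_subjects))
    try:
        res = GaitDiscriminant(features, subjects, k=k, pca_mode=pca_mode).fit()
    except DataError as exc:
        return IterationResult(subjects, math.nan, math.nan, math.nan, k, flag=str(exc))
    rep = res.report
    return IterationResult(
        subjects,
        rep.overall_error_pct,
        rep.train_error_pct,
        rep.test_error_pct,
        k,
    )


@dataclasses.dataclass
class OptimisationRun:
    """All iterations of one exhaustive enumeration, in lexicographic order."""

    subject_ids: list[str]
    r: int
    k: int
    pca_mode: str
    subsets: np.ndarray  # (n_iterations, r) indices into subject_ids
    errors: np.ndarray  # (n_iterations, 3): overall, train, test (%)
    config: dict

    @property
    def n_iterations(self) -> int:
        return self.subsets.shape[0]

    def subset_ids(self, i: int) -> tuple[str, ...]:
        return tuple(self.subject_ids[j] for j in self.subsets[i])

    @property
    def best_index(self) -> int:
        """Arg-min of overall error; the first minimum is the lexicographically
        smallest subject subset because enumeration order is lexicographic."""
        return int(np.nanargmin(self.errors[:, 0]))

    @property
    def best(self) -> IterationResult:
        return self.result(self.best_index)

    def ties_with_best(self) -> list[tuple[str, ...]]:
        best = self.errors[self.best_index, 0]
        return [self.subset_ids(i) for i in np.flatnonzero(self.errors[:, 0] == best)]

    def result(self, i: int) -> IterationResult:
        e = self.errors[i]
        flag = "degenerate iteration" if np.isnan(e[0]) else None
        return IterationResult(self.subset_ids(i), e[0], e[1], e[2], self.k, flag)

    def iter_results(self):
        for i in range(self.n_iterations):
            yield self.result(i)

    @property
    def results(self) -> list[IterationResult]:
        """Materialised list of every IterationResult (memory-heavy at full scale)."""
        return list(self.iter_results())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "training_subjects": [
                    SUBSET_JOIN.join(self.subset_ids(i)) for i in range(self.n_iterations)
                ],
                "overall_error_pct": self.errors[:, 0],
                "train_error_pct": self.errors[:, 1],
                "test_error_pct": self.errors[:, 2],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    def summary(self) -> dict:
        counts, edges = error_histogram(self)
        best = self.best
        overall = self.errors[:, 0]
        values, value_counts = np.unique(overall[~np.isnan(overall)], return_counts=True)
        modal = float(values[np.argmax(value_counts)])
        return {
            "n_iterations": self.n_iterations,
            "r": self.r,
            "k": self.k,
            "pca_mode": self.pca_mode,
            "best_subset": list(best.training_subjects),
            "best_overall_error_pct": best.overall_error_pct,
            "best_train_error_pct": best.train_error_pct,
            "best_test_error_pct": best.test_error_pct,
            "worst_overall_error_pct": float(np.nanmax(overall)),
            "modal_error_pct": modal,
            "n_ties_with_best": len(self.ties_with_best()),
            "histogram_counts": counts.tolist(),
            "histogram_bin_width": float(edges[1] - edges[0]),
            "config": self.config,
        }


def run_optimisation(
    features: FeatureMatrix,
    r: int,
    k: int = 10,
    workers: int = 1,
    pca_mode: str = "refit",
    checkpoint_path: str | Path | None = None,
    checkpoint_batch: int = 5000,
    progress: bool = False,
) -> OptimisationRun:
    """Evaluate every r-of-n training-subject subset.

    The result is independent of ``workers`` and of evaluation order: subsets
    are enumerated lexicographically and each iteration's arithmetic is
    self-contained. With ``checkpoint_path`` the per-iteration CSV is appended
    every ``checkpoint_batch`` iterations and a rerun resumes after the last
    completed row.
    """
    subjects = features.subjects
    n = len(subjects)
    if not 0 < r < n:
        raise ParameterError(f"training size r={r} must satisfy 0 < r < {n}")
    subsets = enumerate_subsets(n, r)
    engine = _Engine(features, k, pca_mode)
    errors = np.empty((len(subsets), 3))

    done = 0
    ckpt = Path(checkpoint_path) if checkpoint_path else None
    if ckpt is not None and ckpt.exists():
        prev = pd.read_csv(ckpt)
        done = min(len(prev), len(subsets))
        errors[:done, 0] = prev["overall_error_pct"].to_numpy()[:done]
        errors[:done, 1] = prev["train_error_pct"].to_numpy()[:done]
        errors[:done, 2] = prev["test_error_pct"].to_numpy()[:done]

    todo = subsets[done:]
    iterator = range(0, len(todo), checkpoint_batch)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, unit_scale=checkpoint_batch, unit="it")

    for lo in iterator:
        batch = todo[lo : lo + checkpoint_batch]
        if workers > 1:
            from joblib import Parallel, delayed

            chunk = max(1, len(batch) // (workers * 4))
            parts = [batch[i : i + chunk] for i in range(0, len(batch), chunk)]
            out = Parallel(n_jobs=workers)(delayed(_eval_chunk)(engine, p) for p in parts)
            block = np.vstack(out)
        else:
            block = _eval_chunk(engine, batch)
        errors[done + lo : done + lo + len(batch)] = block
        if ckpt is not None:
            _append_checkpoint(ckpt, subjects, batch, block, header=(done + lo == 0))

    run = OptimisationRun(
        subject_ids=subjects,
        r=r,
        k=k,
        pca_mode=pca_mode,
        subsets=np.asarray(subsets, dtype=np.int32),
        errors=errors,
        config={"r": r, "k": k, "pca_mode": pca_mode, "n_subjects": n},
    )
    return run


def _append_checkpoint(path, subjects, subsets, errors, header):
    df = pd.DataFrame(
        {
            "training_subjects": [
                SUBSET_JOIN.join(subjects[j] for j in s) for s in subsets
            ],
            "overall_error_pct": errors[:, 0],
            "train_error_pct": errors[:, 1],
            "test_error_pct": errors[:, 2],
        }
    )
    df.to_csv(path, mode="w" if header else "a", header=header, index=False,
              float_format="%.17g")


def refine_by_swap(
    features: FeatureMatrix,
    current_subjects,
    k: int = 10,
    pca_mode: str = "refit",
) -> tuple[tuple[str, ...], IterationResult, list[IterationResult]]:
    """Greedy single-subject swap refinement of a training subset.

    Each pass evaluates every (member, non-member) swap and accepts the best
    strictly improving one; passes repeat until no swap improves. The returned
    subset is never worse than the starting one. Intended as the cheap upgrade
    path when full enumeration is out of reach.
    """
    subjects = features.subjects
    index = {s: i for i, s in enumerate(subjects)}
    current = tuple(sorted(str(s) for s in current_subjects))
    engine = _Engine(features, k, pca_mode)

    def ev(subset_ids: tuple[str, ...]) -> tuple[float, float, float]:
        return engine.evaluate_safe(tuple(index[s] for s in subset_ids))

    cur_err = ev(current)
    history = [IterationResult(current, *cur_err, k)]
    while True:
        best_swap, best_err = None, cur_err
        outside = [s for s in subjects if s not in current]
        for member in current:
            for candidate in outside:
                trial_subset = tuple(sorted(set(current) - {member} | {candidate}))
                e = ev(trial_subset)
                if e[0] < best_err[0]:
                    best_swap, best_err = trial_subset, e
        if best_swap is None:
            break
        current, cur_err = best_swap, best_err
        history.append(IterationResult(current, *cur_err, k))
    return current, history[-1], history


def error_histogram(
    run: OptimisationRun | np.ndarray, bin_width: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Half-open-binned counts of per-iteration overall errors over [0, 100].

    Returns ``(counts, edges)`` with ``edges[i] <= err < edges[i+1]``; counts
    sum to the number of (non-degenerate) iterations. Bin width defaults to
    0.5 percentage points, the error granularity of a 200-trial cohort.
    """
    if bin_width <= 0:
        raise ParameterError("bin width must be positive")
    overall = run.errors[:, 0] if isinstance(run, OptimisationRun) else np.asarray(run)
    if overall.size == 0:
        raise ParameterError("empty run: nothing to bin")
    overall = overall[~np.isnan(overall)]
    n_bins = int(math.ceil((100.0 + bin_width) / bin_width))
    idx = np.floor(overall / bin_width).astype(int)
    counts = np.bincount(idx, minlength=n_bins)[:n_bins]
    edges = np.arange(n_bins + 1) * bin_width
    return counts, edges
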