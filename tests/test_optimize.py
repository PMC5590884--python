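"""Exhaustive subset enumeration, the fast evaluation engine, and refinement."""

import math

import numpy as np
import pytest

from gaitdfa import (
    GaitDiscriminant,
    ParameterError,
    SimConfig,
    build_feature_matrix,
    enumerate_subsets,
    error_histogram,
    evaluate_iteration,
    generate_cohort,
    planted_truth,
    refine_by_swap,
    run_optimisation,
)


def recursive_combinations(n, r, start=0):
    """Independent brute-force generator (recursion, not itertools)."""
    if r == 0:
        yield ()
        return
    for i in range(start, n - r + 1):
        for rest in recursive_combinations(n, r - 1, i + 1):
            yield (i,) + rest


class TestEnumeration:
    def test_small_count(self):
        assert len(enumerate_subsets(4, 2)) == 6

    def test_matches_recursive_oracle(self):
        assert enumerate_subsets(8, 4) == list(recursive_combinations(8, 4))

    def test_complement_is_a_distinct_iteration(self):
        subsets = enumerate_subsets(6, 3)
        assert (0, 1, 2) in subsets and (3, 4, 5) in subsets
        assert len(subsets) == len(set(subsets)) == math.comb(6, 3)

    def test_range_validation(self):
        for bad in (0, 5, 7):
            with pytest.raises(ParameterError):
                enumerate_subsets(5, bad)


@pytest.fixture(scope="module")
def run8(features8):
    return run_optimisation(features8, r=4, k=4)


class TestEvaluation:
    def test_iteration_is_deterministic(self, features8):
        subset = features8.subjects[:4]
        a = evaluate_iteration(features8, subset, k=4)
        b = evaluate_iteration(features8, subset, k=4)
        assert a == b

    def test_fast_engine_matches_reference_pipeline(self, features8, run8):
        for i in (0, 17, 42, 69):
            ref = evaluate_iteration(features8, run8.subset_ids(i), k=4)
            np.testing.assert_allclose(
                run8.errors[i],
                [ref.overall_error_pct, ref.train_error_pct, ref.test_error_pct],
                atol=1e-9,
            )

    def test_exhaustiveness(self, run8):
        assert run8.n_iterations == math.comb(8, 4) == 70

    def test_worker_count_does_not_change_results(self, features8, run8):
        run2 = run_optimisation(features8, r=4, k=4, workers=2)
        np.testing.assert_array_equal(run8.errors, run2.errors)
        np.testing.assert_array_equal(run8.subsets, run2.subsets)

    def test_best_is_no_worse_than_median(self, run8):
        assert run8.best.overall_error_pct <= np.median(run8.errors[:, 0])

    def test_best_tie_break_is_lexicographic(self, run8):
        ties = run8.ties_with_best()
        assert run8.best.training_subjects == min(ties)
        assert run8.best.overall_error_pct == np.nanmin(run8.errors[:, 0])

    def test_pooled_pca_mode_runs(self, features8):
        run = run_optimisation(features8, r=4, k=4, pca_mode="pooled")
        assert run.n_iterations == 70
        assert np.isfinite(run.errors).all()

    def test_checkpoint_resume_reproduces_the_full_run(self, features8, run8, tmp_path):
        ckpt = tmp_path / "iterations.csv"
        run_optimisation(features8, r=4, k=4, checkpoint_path=ckpt, checkpoint_batch=25)
        full_bytes = ckpt.read_bytes()
        # truncate to simulate an interrupted run, then resume
        lines = full_bytes.decode().splitlines(keepends=True)
        ckpt.write_text("".join(lines[:31]))  # header + 30 rows
        resumed = run_optimisation(
            features8, r=4, k=4, checkpoint_path=ckpt, checkpoint_batch=25
        )
        assert ckpt.read_bytes() == full_bytes
        np.testing.assert_array_equal(resumed.errors, run8.errors)


class TestOptimisationBehaviour:
    def test_null_effect_errors_hover_near_chance(self):
        cfg = SimConfig(
            n_subjects=6, trials_per_condition=3, n_singular_subjects=0,
            condition_effect_size=0.0, rng_seed=11,
        )
        fm = build_feature_matrix(generate_cohort(cfg))
        run = run_optimisation(fm, r=3, k=3)
        assert 40.0 < np.nanmean(run.errors[:, 0]) < 60.0

    def test_strong_effect_without_singular_subjects_is_separable(self):
        cfg = SimConfig(
            n_subjects=6, trials_per_condition=3, n_singular_subjects=0,
            condition_effect_size=1.0, rng_seed=12,
        )
        fm = build_feature_matrix(generate_cohort(cfg))
        run = run_optimisation(fm, r=3, k=3)
        assert run.best.overall_error_pct == 0.0

    def test_opposite_sign_singular_subjects_are_avoided_in_training(self):
        picked = []
        for seed in range(10):
            cfg = SimConfig(
                n_subjects=8, n_singular_subjects=2,
                singular_mode="opposite-sign", rng_seed=300 + seed,
            )
            fm = build_feature_matrix(generate_cohort(cfg))
            run = run_optimisation(fm, r=4, k=4)
            singular = set(planted_truth(cfg)["singular_subjects"])
            picked.append(len(set(run.best.training_subjects) & singular) / 2)
        assert np.mean(picked) < 0.5  # below the chance rate r/n

    def test_training_on_opposite_sign_subjects_costs_test_error(self):
        diffs = []
        for seed in range(10):
            cfg = SimConfig(
                n_subjects=8, n_singular_subjects=2,
                singular_mode="opposite-sign", rng_seed=300 + seed,
            )
            fm = build_feature_matrix(generate_cohort(cfg))
            run = run_optimisation(fm, r=4, k=4)
            singular = set(planted_truth(cfg)["singular_subjects"])
            has = np.array(
                [bool(set(run.subset_ids(i)) & singular) for i in range(run.n_iterations)]
            )
            diffs.append(np.nanmean(run.errors[has, 2]) - np.nanmean(run.errors[~has, 2]))
        assert np.mean(diffs) > 0


@pytest.fixture(scope="module")
def cohort6():
    cfg = SimConfig(n_subjects=6, trials_per_condition=3, n_singular_subjects=1,
                    rng_seed=21)
    return build_feature_matrix(generate_cohort(cfg))


class TestRefineBySwap:
    def test_global_optimum_is_a_fixed_point(self, cohort6):
        run = run_optimisation(cohort6, r=3, k=3)
        refined, result, history = refine_by_swap(
            cohort6, run.best.training_subjects, k=3
        )
        assert refined == run.best.training_subjects
        assert len(history) == 1

    def test_descent_is_monotone_from_the_worst_subset(self, cohort6):
        run = run_optimisation(cohort6, r=3, k=3)
        worst = run.subset_ids(int(np.nanargmax(run.errors[:, 0])))
        refined, result, history = refine_by_swap(cohort6, worst, k=3)
        errs = [h.overall_error_pct for h in history]
        assert all(b < a for a, b in zip(errs, errs[1:]))
        assert result.overall_error_pct <= errs[0]
        # greedy can stall above the exhaustive optimum, never below it
        assert result.overall_error_pct >= run.best.overall_error_pct


class TestHistogram:
    def test_single_value_occupies_one_bin(self):
        counts, edges = error_histogram(np.full(12, 22.5))
        assert counts.sum() == 12
        assert (counts > 0).sum() == 1
        lo = np.flatnonzero(counts)[0]
        assert edges[lo] <= 22.5 < edges[lo + 1]

    def test_counts_conserve_iterations(self, run8):
        counts, _ = error_histogram(run8)
        assert counts.sum() == run8.n_iterations

    def test_half_open_bins(self):
        counts, edges = error_histogram(np.array([0.0, 0.5, 100.0]), bin_width=0.5)
        assert counts[0] == 1 and counts[1] == 1
        assert counts[int(100 / 0.5)] == 1

    def test_bad_bin_width_rejected(self, run8):
        with pytest.raises(ParameterError, match="bin width"):
            error_histogram(run8, bin_width=0.0)


def test_degenerate_iteration_is_flagged_not_fatal(features8):
    import pandas as pd

    from gaitdfa import FeatureMatrix

    # strip one subject's barefoot trials: training on it alone is degenerate
    keep = ~((features8.index["subject_id"] == "S01")
             & (features8.index["condition"] == "barefoot"))
    crippled = FeatureMatrix(
        features8.features[keep.to_numpy()],
        features8.index[keep].reset_index(drop=True),
        features8.n_bins,
        features8.config,
    )
    result = evaluate_iteration(crippled, ["S01"], k=2)
    assert result.flag is not None
    assert np.isnan(result.overall_error_pct)
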