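"""Weight bins, the patient-weighted log-RMSE, and the summary metrics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from oracles import (
    naive_concordance,
    naive_patient_weight,
    naive_reader_cv,
    naive_spearman,
    naive_weighted_rmse,
)
from svhbench.metrics import (
    SUBCHALLENGES,
    WEIGHT_BINS,
    assign_bin,
    bin_threshold,
    concordance_index,
    flag_outliers,
    outlier_rate,
    patient_weight,
    reader_cv,
    spearman_metric,
    weighted_rmse,
)
from svhbench.svh_model import SchemeError, ScoreSheet, SubmissionSet, cohort_joint_frame
from svhbench.synthetic_data import CohortConfig, TeamNoiseConfig, generate_cohort, generate_submission


def submission_from_arrays(registry, truth, joints, overall, team_id="t"):
    ids = [s.patient_id for s in truth]
    return SubmissionSet(
        team_id,
        pd.DataFrame(joints, index=ids, columns=registry.column_keys()),
        pd.Series(overall, index=ids),
    )


def exact_submission(registry, truth, team_id="t"):
    joints = cohort_joint_frame(truth, registry).to_numpy(dtype=float)
    overall = [s.overall_total for s in truth]
    return submission_from_arrays(registry, truth, joints, overall, team_id)


class TestWeightBins:
    def test_thresholds_match_published_list(self):
        # published as 0, 1, 1.1, 1.95, 3, 4, 5, 6 (natural logs of the bin
        # upper limits, exceptions for the first two bins and the open bin)
        thrs = [bin_threshold(i) for i in range(8)]
        assert thrs[0] == 0.0
        assert thrs[1] == 1.0
        assert round(thrs[2], 1) == 1.1
        assert round(thrs[3], 2) == 1.95
        assert round(thrs[4]) == 3
        assert round(thrs[5]) == 4
        assert round(thrs[6]) == 5
        assert thrs[7] == 6.0
        assert thrs[2] == math.log(3) and thrs[6] == math.log(148)

    def test_threshold_index_bounds(self):
        with pytest.raises(SchemeError):
            bin_threshold(8)

    @pytest.mark.parametrize("total,index", [
        (0, 0), (1, 1), (2, 2), (3, 2), (4, 3), (7, 3), (8, 4), (20, 4),
        (21, 5), (55, 5), (56, 6), (148, 6), (149, 7), (448, 7),
    ])
    def test_assign_bin_integer_ranges(self, total, index):
        assert assign_bin(total).index == index

    def test_assign_bin_reals_bucket_by_floor(self):
        assert assign_bin(3.7).index == 2
        assert assign_bin(7.999).index == 3
        assert assign_bin(0.4).index == 0

    def test_assign_bin_rejects_negative(self):
        with pytest.raises(SchemeError):
            assign_bin(-0.1)

    @given(total=st.floats(min_value=0, max_value=1000, allow_nan=False))
    def test_partition_is_total_and_unique(self, total):
        hits = [b for b in WEIGHT_BINS if b.contains(math.floor(total))]
        assert len(hits) == 1
        assert hits[0] is assign_bin(total)

    def test_weights_and_thresholds_nondecreasing(self):
        thrs = [b.threshold for b in WEIGHT_BINS]
        weights = [b.weight for b in WEIGHT_BINS]
        assert thrs == sorted(thrs)
        assert weights == sorted(weights)

    @pytest.mark.parametrize("total,expected", [
        (0, 1.0), (5, 2 ** math.log(7)), (300, 64.0),
    ])
    def test_patient_weight_examples(self, total, expected):
        assert patient_weight(total) == pytest.approx(expected, rel=1e-12)

    @given(total=st.integers(min_value=0, max_value=448))
    def test_patient_weight_matches_naive_chain(self, total):
        assert patient_weight(total) == pytest.approx(
            naive_patient_weight(total), rel=1e-12)


class TestWeightedRmse:
    @pytest.mark.parametrize("sc", SUBCHALLENGES)
    def test_identical_submission_scores_zero(self, registry, small_cohort, sc):
        sub = exact_submission(registry, small_cohort)
        result = weighted_rmse(small_cohort, sub, sc, registry)
        assert float(result) == 0.0
        assert result.n_patients == len(small_cohort)

    def test_single_patient_closed_form(self, registry, sheet_factory):
        # s = 0, y = e - 1, weight 1: |ln(e) - ln(1)| = 1 exactly
        truth = [sheet_factory(0)]
        sub = submission_from_arrays(
            registry, truth, np.zeros((1, len(registry))), [math.e - 1])
        assert float(weighted_rmse(truth, sub, "sc1", registry)) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("sc", SUBCHALLENGES)
    def test_matches_loop_oracle_on_toy_cohorts(self, registry, sc, make_submission):
        for seed in range(10):
            truth = generate_cohort(CohortConfig(n_patients=3, seed=100 + seed), registry)
            sub = make_submission(truth, error_sd=0.5, seed=seed)
            value = float(weighted_rmse(truth, sub, sc, registry))
            totals = [s.overall_total for s in truth]
            if sc == "sc1":
                s_terms = totals
                y_terms = list(sub.overall)
                t_terms = totals
            else:
                dt = "jsn" if sc == "sc2" else "erosion"
                cols = registry.column_keys(dt)
                s_terms, y_terms, t_terms = [], [], []
                for sheet, total in zip(truth, totals):
                    for c in cols:
                        s_terms.append(sheet.scores[registry.area_for_column(c)])
                        y_terms.append(sub.joint_scores.loc[sheet.patient_id, c])
                        t_terms.append(total)
            assert value == pytest.approx(
                naive_weighted_rmse(s_terms, y_terms, t_terms), rel=1e-12)

    def test_invariant_under_patient_reordering(self, registry, small_cohort, make_submission):
        sub = make_submission(small_cohort, error_sd=0.4, seed=5)
        direct = float(weighted_rmse(small_cohort, sub, "sc2", registry))
        shuffled = list(reversed(small_cohort))
        assert float(weighted_rmse(shuffled, sub, "sc2", registry)) == pytest.approx(
            direct, rel=1e-12)

    def test_weight_normalisation_duplicating_cohort(self, registry, small_cohort, make_submission):
        # duplicating every patient doubles every weight's contribution and
        # must leave the normalised metric unchanged
        sub = make_submission(small_cohort, error_sd=0.4, seed=6)
        base = float(weighted_rmse(small_cohort, sub, "sc3", registry))
        dup_truth = small_cohort + [
            ScoreSheet(s.patient_id + "_dup", dict(s.scores)) for s in small_cohort]
        joints = np.vstack([sub.joint_scores.to_numpy()] * 2)
        overall = np.concatenate([sub.overall.to_numpy()] * 2)
        dup_sub = submission_from_arrays(registry, dup_truth, joints, overall)
        assert float(weighted_rmse(dup_truth, dup_sub, "sc3", registry)) == pytest.approx(
            base, rel=1e-12)

    def test_monotone_in_single_term_discrepancy(self, registry, small_cohort, make_submission):
        sub = make_submission(small_cohort, error_sd=0.2, seed=7)
        base = float(weighted_rmse(small_cohort, sub, "sc2", registry))
        col = registry.column_keys("jsn")[0]
        pid = small_cohort[0].patient_id
        truth_val = small_cohort[0].scores[registry.area_for_column(col)]
        worse = sub.joint_scores.copy()
        # push the prediction further from the truth on the log scale
        worse.loc[pid, col] = truth_val + 4.0 + abs(worse.loc[pid, col] - truth_val)
        worse_sub = SubmissionSet("t", worse, sub.overall.copy())
        assert float(weighted_rmse(small_cohort, worse_sub, "sc2", registry)) >= base

    def test_misaligned_grid_rejected(self, registry, small_cohort, make_submission):
        sub = make_submission(small_cohort[:-1], error_sd=0.2, seed=8)
        with pytest.raises(SchemeError):
            weighted_rmse(small_cohort, sub, "sc1", registry)


class TestSpearman:
    def test_identical_predictions_give_one(self, registry, small_cohort):
        sub = exact_submission(registry, small_cohort)
        assert spearman_metric(small_cohort, sub, "sc1", registry) == pytest.approx(1.0)

    def test_order_reversal_gives_minus_one(self, registry, small_cohort):
        totals = np.array([s.overall_total for s in small_cohort], dtype=float)
        ranks = totals.argsort().argsort()
        # map each total to the value of opposite rank
        opposite = np.sort(totals)[::-1][ranks]
        sub = submission_from_arrays(
            registry, small_cohort, np.zeros((len(small_cohort), len(registry))), opposite)
        rho = spearman_metric(small_cohort, sub, "sc1", registry)
        if len(set(totals)) == len(totals):
            assert rho == pytest.approx(-1.0)
        else:
            assert rho < 0

    def test_tied_heavy_vector_matches_midrank_oracle(self, registry, sheet_factory):
        truth = [sheet_factory(v, f"P{i}") for i, v in enumerate([0, 0, 1, 1, 2, 3, 3, 3])]
        preds = [0.5, 0.5, 0.5, 2.0, 2.0, 1.0, 4.0, 4.0]
        totals = [s.overall_total for s in truth]
        sub = submission_from_arrays(
            registry, truth, np.zeros((len(truth), len(registry))), preds)
        rho = spearman_metric(truth, sub, "sc1", registry)
        assert rho == pytest.approx(naive_spearman(totals, preds), rel=1e-12)

    def test_constant_vector_returns_nan(self, registry, sheet_factory):
        truth = [sheet_factory(0, f"P{i}") for i in range(5)]
        sub = submission_from_arrays(
            registry, truth, np.zeros((5, len(registry))), [1, 2, 3, 4, 5])
        assert math.isnan(spearman_metric(truth, sub, "sc1", registry))


class TestConcordanceIndex:
    def test_identical_ordering_is_one(self):
        assert concordance_index([1, 2, 3, 4], [10, 20, 30, 40]) == 1.0

    def test_reversed_ordering_is_zero(self):
        assert concordance_index([1, 2, 3, 4], [40, 30, 20, 10]) == 0.0

    def test_one_discordant_pair_of_three(self):
        # orderings (1,2,3) vs (1,3,2): pairs (1,2),(1,3) concordant, (2,3) not
        assert concordance_index([1, 2, 3], [1, 3, 2]) == pytest.approx(2 / 3)

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.normal(size=8)
            b = rng.normal(size=8)
            assert concordance_index(a, b) == pytest.approx(
                naive_concordance(list(a), list(b)), rel=1e-12)

    def test_random_orderings_average_half(self):
        rng = np.random.default_rng(1)
        vals = [concordance_index(rng.permutation(10), rng.permutation(10))
                for _ in range(1000)]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)

    def test_needs_two_teams(self):
        with pytest.raises(SchemeError):
            concordance_index([1.0], [2.0])


class TestOutliers:
    def test_identical_submission_flags_nothing(self, registry, small_cohort):
        sub = exact_submission(registry, small_cohort)
        assert flag_outliers(small_cohort, sub, "sc2", registry=registry).empty

    def test_joint_off_by_cap_always_flagged(self, registry, small_cohort):
        sub = exact_submission(registry, small_cohort)
        col = registry.column_keys("jsn")[3]
        pid = small_cohort[0].patient_id
        truth_val = small_cohort[0].scores[registry.area_for_column(col)]
        sub.joint_scores.loc[pid, col] = abs(truth_val - 4)  # off by the cap
        for cutoff in (1.0, 2.0, 4.0):
            flagged = flag_outliers(small_cohort, sub, "sc2", cutoff, registry)
            assert list(flagged["unit"]) == [col]

    def test_flag_count_nonincreasing_in_cutoff(self, registry, medium_cohort, make_submission):
        sub = make_submission(medium_cohort, error_sd=0.8, seed=11)
        counts = [len(flag_outliers(medium_cohort, sub, "sc3", c, registry))
                  for c in (0.5, 1, 2, 3, 5, 8)]
        assert counts == sorted(counts, reverse=True)

    def test_invalid_cutoff_rejected(self, registry, small_cohort):
        sub = exact_submission(registry, small_cohort)
        with pytest.raises(SchemeError):
            flag_outliers(small_cohort, sub, "sc2", cutoff=0.0, registry=registry)

    @pytest.mark.parametrize("flagged,total,expected", [
        (201, 7896, 2.5),
        (462, 8272, 5.6),
        (97, 7896, 1.2),
        (192, 8272, 2.3),
        (0, 7896, 0.0),
    ])
    def test_outlier_rate_rounding(self, flagged, total, expected):
        assert outlier_rate(flagged, total) == expected

    def test_outlier_rate_rejects_zero_total(self):
        with pytest.raises(SchemeError):
            outlier_rate(0, 0)


class TestReaderCV:
    def test_identical_readers_give_zero(self):
        assert float(reader_cv([3, 10, 50], [3, 10, 50])) == 0.0

    def test_three_to_one_ratio_closed_form(self):
        # pair (a, 3a): SD = a*sqrt(2), mean = 2a, CV = sqrt(2)/2
        result = reader_cv([2, 10, 40], [6, 30, 120])
        assert float(result) == pytest.approx(math.sqrt(2) / 2, rel=1e-12)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 100, size=30).astype(float)
        b = np.clip(a + rng.integers(-5, 6, size=30), 0, None).astype(float)
        assert float(reader_cv(a, b)) == pytest.approx(naive_reader_cv(a, b), rel=1e-12)

    def test_zero_mean_pairs_excluded_and_counted(self):
        result = reader_cv([0, 4], [0, 4])
        assert result.n_zero_excluded == 1
        assert result.n_used == 1

    def test_empty_pairing_rejected(self):
        with pytest.raises(SchemeError):
            reader_cv([], [])
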