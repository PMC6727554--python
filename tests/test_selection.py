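"""Metrics, threshold selection and the α recommendation."""

import math

import numpy as np
import pandas as pd
import pytest

from samplertune.assessment import ConfusionMatrix, build_grid
from samplertune.selection import (
    DEFAULT_RELAXATION_GRID,
    VACUOUS,
    Recommendation,
    accuracy,
    curation_ratio,
    mean_accuracy,
    npv,
    precision,
    rank_alpha_candidates,
    recommend,
    select_thresholds,
)

WORKED = ConfusionMatrix(ca=29, ia=4, ir=12, cr=5)


class TestMetrics:
    def test_accuracy_of_the_worked_matrix(self):
        assert accuracy(WORKED) == pytest.approx(34 / 50)

    def test_precision_and_npv_of_the_worked_matrix(self):
        assert precision(WORKED) == pytest.approx(29 / 33)
        assert npv(WORKED) == pytest.approx(5 / 17)

    def test_perfect_and_allwrong_matrices(self):
        assert accuracy(ConfusionMatrix(10, 0, 0, 10)) == 1.0
        assert accuracy(ConfusionMatrix(0, 7, 3, 0)) == 0.0
        assert precision(ConfusionMatrix(5, 0, 3, 1)) == 1.0
        assert npv(ConfusionMatrix(5, 1, 0, 3)) == 1.0

    def test_vacuous_when_denominator_is_zero(self):
        assert precision(ConfusionMatrix(0, 0, 3, 2)) is VACUOUS
        assert npv(ConfusionMatrix(3, 2, 0, 0)) is VACUOUS
        with pytest.raises(ValueError):
            accuracy(ConfusionMatrix(0, 0, 0, 0))

    def test_mean_accuracy_is_the_column_mean(self, rng):
        cms = [
            ConfusionMatrix(*(int(x) for x in rng.integers(0, 20, size=4) + 1))
            for _ in range(11)
        ]
        assert mean_accuracy(cms) == pytest.approx(
            sum(accuracy(c) for c in cms) / len(cms)
        )
        const = [ConfusionMatrix(3, 1, 1, 5)] * 7
        assert mean_accuracy(const) == pytest.approx(0.8)


def column_from_metric_rows(rows):
    """rows: list of (ca, ia, ir, cr) from low t to high t."""
    return [ConfusionMatrix(*r) for r in rows]


class TestSelectThresholds:
    def test_upper_lowest_precise_t_lower_highest_npv_t(self):
        ts = [0.0, 0.5, 1.0]
        col = column_from_metric_rows(
            [(10, 2, 0, 0), (6, 1, 5, 2), (3, 0, 8, 3)]
        )  # precision: 10/12, 6/7, 1 ; npv: vacuous, 2/7, 3/11
        choice = select_thresholds(ts, col, 1.0, 1.0)
        assert choice.upper == 1.0
        assert choice.lower == 0.0  # only the vacuous row reaches NPV 1
        assert not choice.crossed

    def test_precision_one_everywhere_gives_the_lowest_t(self):
        ts = [0.0, 0.5, 1.0]
        col = column_from_metric_rows([(12, 0, 0, 0), (8, 0, 2, 2), (4, 0, 5, 3)])
        assert select_thresholds(ts, col).upper == 0.0

    def test_unreachable_targets_are_flagged(self):
        ts = [0.0, 0.5, 1.0]
        col = column_from_metric_rows([(5, 5, 1, 1), (4, 4, 2, 2), (2, 2, 4, 4)])
        choice = select_thresholds(ts, col, 1.0, 1.0)
        assert not choice.upper_reachable and choice.upper == pytest.approx(1.5)
        assert not choice.lower_reachable and choice.lower == 0.0

    def test_relaxing_precision_never_raises_the_upper_threshold(self, rng):
        ts = [round(0.1 * i, 1) for i in range(11)]
        for _ in range(25):
            counts = rng.integers(0, 15, size=(11, 4)) + 1
            col = column_from_metric_rows([tuple(int(x) for x in r) for r in counts])
            uppers = [
                select_thresholds(ts, col, p, 1.0).upper
                for p in DEFAULT_RELAXATION_GRID
            ]
            assert uppers == sorted(uppers, reverse=True)
            lowers = [
                select_thresholds(ts, col, 1.0, q).lower
                for q in DEFAULT_RELAXATION_GRID
            ]
            assert lowers == sorted(lowers)

    def test_targets_must_lie_in_the_allowed_band(self):
        col = column_from_metric_rows([(1, 1, 1, 1)])
        with pytest.raises(ValueError):
            select_thresholds([0.5], col, precision_target=0.5)
        with pytest.raises(ValueError):
            select_thresholds([0.5], col, npv_target=1.2)


class TestCurationRatio:
    @pytest.mark.parametrize(
        "acc,n_cur,n_pot,expected",
        [
            (0.691, 331, 862, 1.80),
            (0.753, 264, 741, 2.11),
            (0.591, 624, 1114, 1.05),
            (0.5, 50, 100, 1.0),
        ],
    )
    def test_accuracy_over_curation_fraction(self, acc, n_cur, n_pot, expected):
        assert curation_ratio(acc, n_cur, n_pot) == pytest.approx(expected, abs=0.01)

    def test_empty_curation_band_ranks_best(self):
        assert math.isinf(curation_ratio(0.9, 0, 100))
        with pytest.raises(ValueError):
            curation_ratio(0.9, 10, 0)


def perfect_tables(n_genes=20, alphas=(0.2, 0.5)):
    truth = pd.DataFrame(
        {"gene_id": [f"g{i}" for i in range(n_genes)], "curated_ec": "1.1.1.1"}
    )
    rows = [(f"g{i}", a, "1.1.1.1", 1.0) for a in alphas for i in range(n_genes)]
    ann = pd.DataFrame(rows, columns=["gene_id", "alpha", "ec", "score"])
    return truth, ann


class TestRecommend:
    def test_perfect_annotations_leave_nothing_to_curate(self):
        truth, ann = perfect_tables()
        grid = build_grid(truth, ann)
        rec, report = recommend(grid, ann)
        assert rec.upper_threshold == 0.0  # precision 1 from the lowest t on
        assert rec.n_curate == 0 and math.isinf(rec.curation_ratio)
        assert rec.n_accepted == 20

    def test_counts_partition_the_potentially_metabolic_genes(self, rng):
        from conftest import random_truth_and_annotations

        truth, ann = random_truth_and_annotations(rng, n_genes=60)
        truth_df = pd.DataFrame(
            {
                "gene_id": list(truth),
                "curated_ec": [
                    "NONE" if not isinstance(v, frozenset) else ",".join(sorted(v))
                    for v in truth.values()
                ],
            }
        )
        grid = build_grid(truth_df, ann)
        for p in DEFAULT_RELAXATION_GRID:
            rec, report = recommend(grid, ann, p, p)
            for row in report.itertuples(index=False):
                assert row.n_accepted + row.n_rejected + row.n_curate == 60

    def test_relaxation_monotonicity_of_accepted_and_rejected(self, worked_example_tables):
        truth, sample, genome = worked_example_tables
        grid = build_grid(truth, sample)
        acc_counts, rej_counts = [], []
        for target in DEFAULT_RELAXATION_GRID:
            rec_p, rep_p = recommend(grid, genome, precision_target=target)
            acc_counts.append(rep_p.set_index("alpha")["n_accepted"].to_dict())
            rec_n, rep_n = recommend(grid, genome, npv_target=target)
            rej_counts.append(rep_n.set_index("alpha")["n_rejected"].to_dict())
        for a in grid.alphas:
            per_alpha_acc = [d[a] for d in acc_counts]
            assert per_alpha_acc == sorted(per_alpha_acc)
            per_alpha_rej = [d[a] for d in rej_counts]
            assert per_alpha_rej == sorted(per_alpha_rej)

    def test_selection_maximises_the_curation_ratio(self, worked_example_tables):
        truth, sample, genome = worked_example_tables
        grid = build_grid(truth, sample)
        rec, report = recommend(grid, genome)
        best = report.loc[report["selected"]].iloc[0]
        assert best["curation_ratio"] == report["curation_ratio"].max()
        assert rec.alpha == best["alpha"]

    def test_crossed_thresholds_flagged_with_empty_curation_band(self):
        # NPV stays 1 up to t=0.8 (the only rejections are true non-enzymes
        # at 0.5) while precision reaches 1 already at t=0.6: lower > upper.
        truth = pd.DataFrame(
            {"gene_id": ["g1", "g2", "g3", "g4", "n1"],
             "curated_ec": ["1.1.1.1"] * 4 + ["NONE"]}
        )
        ann = pd.DataFrame(
            [(f"g{i}", 0.5, "1.1.1.1", 0.8) for i in range(1, 5)]
            + [("n1", 0.5, "2.2.2.2", 0.5)],
            columns=["gene_id", "alpha", "ec", "score"],
        )
        grid = build_grid(truth, ann)
        rec, report = recommend(grid, ann)
        assert rec.lower_threshold > rec.upper_threshold
        assert rec.thresholds_crossed
        assert rec.n_curate == 0  # acceptance takes precedence in the overlap
        assert (rec.n_accepted, rec.n_rejected) == (4, 1)

    def test_recommendation_invariant_enforced(self):
        with pytest.raises(ValueError):
            Recommendation(
                alpha=0.5, upper_threshold=0.8, lower_threshold=0.2,
                precision_target=1.0, npv_target=1.0,
                n_accepted=5, n_rejected=5, n_curate=5,
                n_potentially_metabolic=10, mean_accuracy=0.5, curation_ratio=1.0,
            )


class TestRankAlphaCandidates:
    def test_ranks_by_ratio_then_accuracy_then_lower_alpha(self):
        best, ratios = rank_alpha_candidates(
            {0.2: (0.6, 0.30), 0.4: (0.6, 0.30), 0.6: (0.7, 0.50)}
        )
        assert best == 0.2  # equal ratio and accuracy at 0.2/0.4 -> lower α
        assert ratios[0.2] == pytest.approx(2.0)

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            rank_alpha_candidates({})
        with pytest.raises(ValueError):
            rank_alpha_candidates({0.5: (0.5, 0.0)})
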