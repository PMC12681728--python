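"""Precision/recall counts, AUROC rank statistic, stratified grid."""

import numpy as np
import pandas as pd
import pytest

from g6pdscreen import (
    TASKS,
    auroc,
    classify_table,
    evaluate_stratified,
    precision_recall,
)


def brute_force_auroc(scores, truth):
    """Oracle: fraction of positive-negative pairs won, ties half credit."""
    s = np.asarray(scores, float)
    t = np.asarray(truth, bool)
    wins = total = 0.0
    for sp in s[t]:
        for sn in s[~t]:
            total += 1
            wins += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return wins / total


class TestPrecisionRecall:
    def test_toy_confusion_table(self):
        screen = np.zeros(40, bool)
        truth = np.zeros(40, bool)
        screen[:10] = True
        truth[2:18] = True  # TP = 8 (indices 2..9), TestPos = 10, GenoPos = 16
        pr = precision_recall(screen, truth)
        assert (pr.tp, pr.test_positive, pr.genotype_positive) == (8, 10, 16)
        assert pr.precision == pytest.approx(0.80)
        assert pr.recall == pytest.approx(0.50)

    def test_empty_denominators_flagged_not_coerced(self):
        pr = precision_recall([False, False], [True, True])
        assert not pr.precision_defined and np.isnan(pr.precision)
        assert pr.recall == 0.0
        pr2 = precision_recall([True, True], [False, False])
        assert not pr2.recall_defined and np.isnan(pr2.recall)

    def test_all_positive_agreement(self):
        pr = precision_recall([True] * 5, [True] * 5)
        assert pr.precision == 1.0 and pr.recall == 1.0

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            precision_recall([True, False], [True])


class TestAuroc:
    def test_perfect_separation(self):
        a, _ = auroc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], n_boot=50)
        assert a == 1.0

    def test_worked_example(self):
        a, _ = auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1], n_boot=50)
        assert a == pytest.approx(0.75)  # wins 3 of 4 pairs

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        scores = np.round(rng.random(n), 2)  # ties likely
        truth = rng.random(n) < 0.4
        if truth.all() or not truth.any():
            truth[0] = ~truth[0]
        a, _ = auroc(scores, truth, n_boot=10)
        assert a == pytest.approx(brute_force_auroc(scores, truth))

    def test_permuted_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(4000)
        truth = rng.random(4000) < 0.3
        a, sd = auroc(scores, truth, n_boot=300, seed=0)
        assert abs(a - 0.5) < 3 * sd

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])

    def test_bootstrap_sd_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        scores, truth = rng.random(200), rng.random(200) < 0.3
        assert auroc(scores, truth, seed=5) == auroc(scores, truth, seed=5)


def _hand_grid():
    """20 hand-built rows in one cohort; expected values done by hand."""
    rows = pd.DataFrame(
        {
            "participant_id": [f"p{i}" for i in range(20)],
            "sex": ["male"] * 10 + ["female"] * 10,
            "zygosity": (
                ["var_hemizygote"] * 3 + ["ref_hemizygote"] * 7
                + ["var_homozygote"] * 2 + ["heterozygote"] * 3 + ["ref_homozygote"] * 5
            ),
            "cohort_label": ["c1"] * 20,
        }
    )
    screen = pd.DataFrame(
        {
            "participant_id": rows["participant_id"],
            # males: screen positive = first 4 (3 carriers + 1 non-carrier)
            # females: positive = both homozygotes + 1 ref
            "possible": [True] * 4 + [False] * 6 + [True, True] + [False] * 3
            + [True] + [False] * 4,
            "likely": [True, True] + [False] * 8 + [True] + [False] * 9,
        }
    )
    return rows, screen


class TestStratifiedGrid:
    def test_hand_computed_cell_values(self):
        rows, screen = _hand_grid()
        grid = evaluate_stratified(rows, screen)

        def cell(task, cohort, criterion):
            m = grid[
                (grid.task == task) & (grid.cohort == cohort) & (grid.criterion == criterion)
            ]
            return m.iloc[0]

        male_pos = cell("male_hemizygote", "c1", "possible")
        assert male_pos["tp"] == 3 and male_pos["test_positive"] == 4
        assert male_pos["recall_pct"] == pytest.approx(100.0)
        assert male_pos["precision_pct"] == pytest.approx(75.0)
        male_lik = cell("male_hemizygote", "c1", "likely")
        assert male_lik["recall_pct"] == pytest.approx(200 / 3)
        assert male_lik["precision_pct"] == pytest.approx(100.0)
        fhom = cell("female_hom", "c1", "possible")
        assert fhom["recall_pct"] == pytest.approx(100.0)
        assert fhom["precision_pct"] == pytest.approx(200 / 3)
        assert fhom["prevalence_pct"] == pytest.approx(20.0)

    def test_overall_pools_counts_additively(self, analysis_rows, screen_results):
        grid = evaluate_stratified(analysis_rows, screen_results)
        for task in grid.task.unique():
            for crit in ("possible", "likely"):
                sub = grid[(grid.task == task) & (grid.criterion == crit)]
                overall = sub[sub.cohort == "Overall"].iloc[0]
                per = sub[sub.cohort != "Overall"]
                for col in ("tp", "test_positive", "genotype_positive", "n"):
                    assert overall[col] == per[col].sum()

    def test_recall_hierarchy_in_every_populated_row(self, analysis_rows, screen_results):
        """recall(possible) >= recall(likely) wherever both are defined."""
        grid = evaluate_stratified(analysis_rows, screen_results)
        piv = grid.pivot_table(
            index=["task", "cohort"], columns="criterion", values="recall_pct"
        ).dropna()
        assert (piv["possible"] >= piv["likely"] - 1e-12).all()

    def test_zero_genotype_positive_cohort_flagged(self):
        rows, screen = _hand_grid()
        rows = rows.copy()
        rows.loc[rows.sex == "female", "zygosity"] = "ref_homozygote"
        grid = evaluate_stratified(rows, screen)
        cell = grid[
            (grid.task == "female_hom") & (grid.cohort == "c1") & (grid.criterion == "possible")
        ].iloc[0]
        assert not cell["recall_defined"] and np.isnan(cell["recall_pct"])

    def test_duplicated_cohorts_pool_to_same_rates(self):
        rows, screen = _hand_grid()
        rows2 = rows.copy()
        rows2["participant_id"] = rows2["participant_id"] + "_b"
        rows2["cohort_label"] = "c2"
        screen2 = screen.copy()
        screen2["participant_id"] = screen2["participant_id"] + "_b"
        grid = evaluate_stratified(
            pd.concat([rows, rows2], ignore_index=True),
            pd.concat([screen, screen2], ignore_index=True),
        )
        sub = grid[(grid.task == "male_hemizygote") & (grid.criterion == "possible")]
        vals = sub.set_index("cohort")["precision_pct"]
        assert vals["Overall"] == pytest.approx(vals["c1"]) == pytest.approx(vals["c2"])

    def test_unknown_cohort_label_rejected(self):
        rows, screen = _hand_grid()
        with pytest.raises(ValueError, match="unknown cohort"):
            evaluate_stratified(rows, screen, known_cohorts=["other"])

    def test_tasks_cover_the_three_target_populations(self):
        names = {t.name for t in TASKS}
        assert names == {"male_hemizygote", "female_hom", "female_het_or_hom"}
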