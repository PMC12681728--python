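"""Stratified screening evaluation: prevalence, precision, recall, AUROC.

Three detection tasks are evaluated, mirroring the zygosity classes a
screen could target on chromosome X: male hemizygotes, female homozygotes,
and females with at least one variant allele.  For each (task, cohort,
criterion) cell: precision = TP / test-positives and recall =
TP / genotype-positives, where TP are test-positive participants carrying
the relevant genotype.  Undefined ratios (empty denominators) are reported
as explicit NaN-with-flag, never coerced to 0 or 1.  Pooled "Overall" rows
add counts across cohorts, not rates.

AUROC is the Mann-Whitney rank statistic (midrank ties); its uncertainty
is a seeded nonparametric bootstrap standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .genotypes import Sex, ZygosityLabel

__all__ = [
    "TaskDefinition",
    "TASKS",
    "PrecisionRecall",
    "precision_recall",
    "auroc",
    "evaluate_stratified",
]


@dataclass(frozen=True)
class TaskDefinition:
    """One detection target: which sex stratum and which zygosity classes
    count as genotype-positive."""

    name: str
    sex_filter: Sex
    positive_zygosities: frozenset


TASKS = (
    TaskDefinition(
        "male_hemizygote",
        Sex.MALE,
        frozenset({ZygosityLabel.VAR_HEMIZYGOTE.value}),
    ),
    TaskDefinition(
        "female_hom",
        Sex.FEMALE,
        frozenset({ZygosityLabel.VAR_HOMOZYGOTE.value}),
    ),
    TaskDefinition(
        "female_het_or_hom",
        Sex.FEMALE,
        frozenset({ZygosityLabel.HETEROZYGOTE.value, ZygosityLabel.VAR_HOMOZYGOTE.value}),
    ),
)


@dataclass(frozen=True)
class PrecisionRecall:
    tp: int
    test_positive: int
    genotype_positive: int
    n: int

    @property
    def precision(self) -> float:
        return self.tp / self.test_positive if self.test_positive else float("nan")

    @property
    def precision_defined(self) -> bool:
        return self.test_positive > 0

    @property
    def recall(self) -> float:
        return self.tp / self.genotype_positive if self.genotype_positive else float("nan")

    @property
    def recall_defined(self) -> bool:
        return self.genotype_positive > 0

    @property
    def prevalence(self) -> float:
        return self.genotype_positive / self.n if self.n else float("nan")


def precision_recall(screen_positive, genotype_positive) -> PrecisionRecall:
    """Confusion counts for one criterion against genotype truth.

    Inputs are aligned boolean arrays (same participants, same order);
    alignment by id is the caller's responsibility (see
    :func:`evaluate_stratified`).
    """
    s = np.asarray(screen_positive, dtype=bool)
    t = np.asarray(genotype_positive, dtype=bool)
    if s.shape != t.shape:
        raise ValueError("screen and truth are misaligned")
    return PrecisionRecall(
        tp=int((s & t).sum()),
        test_positive=int(s.sum()),
        genotype_positive=int(t.sum()),
        n=int(s.size),
    )


def auroc(scores, truth, n_boot: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Rank-based AUROC with a seeded bootstrap SD.

    The point estimate is the Mann-Whitney statistic with midrank tie
    handling.  Uncertainty is the standard deviation of the statistic over
    ``n_boot`` nonparametric resamples (resamples with a single class are
    redrawn implicitly by being skipped).
    """
    y = np.asarray(truth, dtype=bool)
    x = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("AUROC needs both classes present")
    point = float(roc_auc_score(y, x))
    rng = np.random.default_rng(seed)
    n = y.size
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if yb.all() or not yb.any():
            continue
        boots.append(roc_auc_score(yb, x[idx]))
    sd = float(np.std(boots)) if boots else float("nan")
    return point, sd


def evaluate_stratified(
    analysis_rows: pd.DataFrame,
    screen_results: pd.DataFrame,
    tasks: tuple[TaskDefinition, ...] = TASKS,
    cohort_col: str = "cohort_label",
    known_cohorts: list[str] | None = None,
) -> pd.DataFrame:
    """The full evaluation grid: (task x cohort x criterion) plus pooled
    "Overall" rows per task.

    ``analysis_rows`` must carry sex, zygosity and a cohort label;
    ``screen_results`` the possible/likely flags.  Tables are joined on
    participant_id.  Unknown cohort labels (when ``known_cohorts`` is
    given) raise a config error.
    """
    merged = analysis_rows.merge(
        screen_results, on="participant_id", how="inner", validate="one_to_one"
    )
    if len(merged) != len(analysis_rows):
        raise ValueError("screen results do not align with analysis rows")
    if cohort_col not in merged.columns:
        raise KeyError(f"missing cohort label column {cohort_col!r}")
    labels = merged[cohort_col].unique().tolist()
    if known_cohorts is not None:
        unknown = set(labels) - set(known_cohorts)
        if unknown:
            raise ValueError(f"unknown cohort labels: {sorted(unknown)}")

    records = []
    for task in tasks:
        sex_value = task.sex_filter.value
        stratum = merged[merged["sex"].astype(str) == sex_value]
        truth_all = stratum["zygosity"].isin(task.positive_zygosities)
        for cohort in ["Overall"] + sorted(labels):
            sel = slice(None) if cohort == "Overall" else (stratum[cohort_col] == cohort)
            sub = stratum if cohort == "Overall" else stratum[sel]
            truth = truth_all if cohort == "Overall" else truth_all[sel]
            for criterion in ("possible", "likely"):
                pr = precision_recall(sub[criterion], truth)
                records.append(
                    {
                        "task": task.name,
                        "sex": sex_value,
                        "cohort": cohort,
                        "criterion": criterion,
                        "n": pr.n,
                        "genotype_positive": pr.genotype_positive,
                        "test_positive": pr.test_positive,
                        "tp": pr.tp,
                        "prevalence_pct": 100.0 * pr.prevalence,
                        "recall_pct": 100.0 * pr.recall,
                        "precision_pct": 100.0 * pr.precision,
                        "recall_defined": pr.recall_defined,
                        "precision_defined": pr.precision_defined,
                    }
                )
    return pd.DataFrame.from_records(records)
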