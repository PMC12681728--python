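"""Cohort construction: draw-eligibility filtering and index-draw selection.

Each participant may have several laboratory draws with concurrent blood
glucose, HbA1c and RDW.  When fasting is not assured (routine clinical
draws), glucose outside [70, 200] mg/dL is excluded — below 70 suggests
error or hypoglycemia, above 200 a post-prandial or uncontrolled-diabetes
reading; the bounds themselves are retained (exclusion is strict < 70 or
> 200).  Among eligible draws the one with the lowest glucose (most likely
fasting) becomes the participant's index draw, ties broken by earliest
draw date then input order.  Cohorts where fasting was requested at
collection bypass the range filter.

An exclusion ledger (counts by reason) accompanies every built cohort so
that retained + excluded always reconciles to the input size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import Sex, zygosity_from_allele_count
from .glycemic import chang_ratio, glucose_gap

__all__ = [
    "GLUCOSE_MIN",
    "GLUCOSE_MAX",
    "ExclusionLedger",
    "filter_eligible_draws",
    "select_index_draw",
    "build_cohort",
]

GLUCOSE_MIN = 70.0  # mg/dL, inclusive
GLUCOSE_MAX = 200.0  # mg/dL, inclusive

_LAB_COLS = ["glucose", "hba1c", "rdw"]


@dataclass
class ExclusionLedger:
    """Bookkeeping for cohort construction; reasons partition the input."""

    n_input: int = 0
    no_genotype: int = 0
    missing_labs: int = 0
    no_eligible_draw: int = 0
    retained: int = 0
    draws_dropped_missing: int = 0
    draws_dropped_glucose_range: int = 0
    extra: dict = field(default_factory=dict)

    def check(self) -> None:
        total = self.no_genotype + self.missing_labs + self.no_eligible_draw + self.retained
        if total != self.n_input:
            raise AssertionError(
                f"exclusion ledger does not reconcile: {total} != {self.n_input}"
            )

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "no_genotype": self.no_genotype,
            "missing_labs": self.missing_labs,
            "no_eligible_draw": self.no_eligible_draw,
            "retained": self.retained,
            "draws_dropped_missing": self.draws_dropped_missing,
            "draws_dropped_glucose_range": self.draws_dropped_glucose_range,
            **self.extra,
        }


def filter_eligible_draws(
    draws: pd.DataFrame, fasting_assured: bool = False
) -> tuple[pd.DataFrame, dict]:
    """Drop draws with missing analytes, then apply the glucose range filter.

    Returns the eligible draws and counts of rows dropped at each step.
    With ``fasting_assured`` the 70-200 mg/dL filter is bypassed (fasting
    was requested at collection, so low values are informative).
    """
    complete = draws.dropna(subset=[c for c in _LAB_COLS if c in draws.columns])
    n_missing = len(draws) - len(complete)
    if fasting_assured or complete.empty:
        eligible = complete
        n_range = 0
    else:
        in_range = (complete["glucose"] >= GLUCOSE_MIN) & (
            complete["glucose"] <= GLUCOSE_MAX
        )
        eligible = complete[in_range]
        n_range = int((~in_range).sum())
    return eligible, {
        "draws_dropped_missing": n_missing,
        "draws_dropped_glucose_range": n_range,
    }


def select_index_draw(eligible: pd.DataFrame) -> pd.Series:
    """Index draw for one participant: minimum glucose, ties to earliest date.

    Remaining ties go to the first row in input order, so selection is
    deterministic.  Raises ``ValueError`` on empty input (the caller counts
    such participants as excluded).
    """
    if eligible.empty:
        raise ValueError("no eligible draw to select from")
    if eligible["participant_id"].nunique() > 1:
        raise ValueError("select_index_draw expects draws from a single participant")
    order = eligible.sort_values(
        ["glucose", "draw_date"], kind="stable"
    )  # stable sort preserves input order among full ties
    return order.iloc[0]


def _index_draws(eligible: pd.DataFrame) -> pd.DataFrame:
    """Vectorised per-participant index-draw selection (same rule as above)."""
    order = eligible.sort_values(
        ["participant_id", "glucose", "draw_date"], kind="stable"
    )
    return order.groupby("participant_id", sort=False).head(1)


def build_cohort(
    participants: pd.DataFrame,
    draws: pd.DataFrame,
    genotypes: pd.DataFrame,
    fasting_assured: bool = False,
) -> tuple[pd.DataFrame, ExclusionLedger]:
    """One analysis row per genotyped participant with an eligible draw.

    ``participants`` carries one row per participant (id, sex, phenotype
    flags such as ``diabetes`` / ``g6pd_dx``, optional ``cohort_label``);
    ``draws`` the laboratory events; ``genotypes`` the allele counts.
    Returns the analysis table and an :class:`ExclusionLedger` whose reason
    counts partition the participant input.
    """
    if participants["participant_id"].duplicated().any():
        dupes = participants.loc[
            participants["participant_id"].duplicated(), "participant_id"
        ].tolist()
        raise ValueError(f"duplicate participant ids in participant table: {dupes[:5]}")

    ledger = ExclusionLedger(n_input=len(participants))
    parts = participants.copy()
    parts["participant_id"] = parts["participant_id"].astype(str)
    geno = genotypes.copy()
    geno["participant_id"] = geno["participant_id"].astype(str)
    draws = draws.copy()
    draws["participant_id"] = draws["participant_id"].astype(str)

    genotyped = parts["participant_id"].isin(set(geno["participant_id"]))
    ledger.no_genotype = int((~genotyped).sum())
    parts = parts[genotyped]

    eligible, drop_counts = filter_eligible_draws(
        draws[draws["participant_id"].isin(set(parts["participant_id"]))],
        fasting_assured=fasting_assured,
    )
    ledger.draws_dropped_missing = drop_counts["draws_dropped_missing"]
    ledger.draws_dropped_glucose_range = drop_counts["draws_dropped_glucose_range"]

    complete_ids = set(
        draws.dropna(subset=[c for c in _LAB_COLS if c in draws.columns])[
            "participant_id"
        ]
    )
    has_any_complete = parts["participant_id"].isin(complete_ids)
    ledger.missing_labs = int((~has_any_complete).sum())
    parts = parts[has_any_complete]

    index = _index_draws(eligible)
    has_eligible = parts["participant_id"].isin(set(index["participant_id"]))
    ledger.no_eligible_draw = int((~has_eligible).sum())
    parts = parts[has_eligible]
    ledger.retained = len(parts)
    ledger.check()

    rows = parts.merge(
        index[["participant_id", "draw_date"] + _LAB_COLS],
        on="participant_id",
        how="left",
    )
    geno_cols = ["participant_id", "allele_count"]
    rows = rows.merge(geno[geno_cols], on="participant_id", how="left")
    rows["sex"] = rows["sex"].map(Sex.parse)
    rows["zygosity"] = [
        zygosity_from_allele_count(s, c).label.value
        for s, c in zip(rows["sex"], rows["allele_count"])
    ]
    rows["glucose_gap"] = glucose_gap(
        rows["glucose"].to_numpy(), rows["hba1c"].to_numpy()
    )
    rows["chang_ratio"] = chang_ratio(
        rows["glucose"].to_numpy(), rows["hba1c"].to_numpy()
    )
    rows["sex"] = rows["sex"].map(lambda s: s.value)
    return rows.reset_index(drop=True), ledger
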