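"""The possible/likely G6PD-deficiency decision rules.

Two routine labs drive the screen: a low red cell distribution width
(RDW <= 12) and a glucose gap that is not deeply negative (GG >= -15
mg/dL), both signatures of shortened erythrocyte lifespan.  "Possible"
deficiency is the inclusive OR of the two criteria (screening-oriented,
high recall); "likely" is the AND (confirmation-oriented, high precision).
Likely therefore always implies possible.  Thresholds are parameters with
the published operating points as defaults; both comparisons are inclusive
at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DecisionCriteria", "ScreenResult", "classify", "classify_table"]


@dataclass(frozen=True)
class DecisionCriteria:
    """Thresholds for the two-lab decision rule.

    ``possible`` = (rdw <= rdw_threshold) OR (gg >= gg_threshold);
    ``likely``   = (rdw <= rdw_threshold) AND (gg >= gg_threshold).
    """

    rdw_threshold: float = 12.0
    gg_threshold: float = -15.0


@dataclass(frozen=True)
class ScreenResult:
    participant_id: str
    possible: bool
    likely: bool

    def __post_init__(self):
        if self.likely and not self.possible:
            raise AssertionError("likely implies possible; rule hierarchy violated")


def classify(rdw, gg, criteria: DecisionCriteria = DecisionCriteria()):
    """Evaluate the decision rules; returns (possible, likely).

    Accepts scalars or arrays; boundary values satisfy their comparison.
    Non-finite inputs raise ``ValueError``.
    """
    r = np.asarray(rdw, dtype=float)
    g = np.asarray(gg, dtype=float)
    if not (np.all(np.isfinite(r)) and np.all(np.isfinite(g))):
        raise ValueError("rdw and glucose gap must be finite")
    low_rdw = r <= criteria.rdw_threshold
    high_gg = g >= criteria.gg_threshold
    possible = low_rdw | high_gg
    likely = low_rdw & high_gg
    if np.isscalar(rdw) and np.isscalar(gg):
        return bool(possible), bool(likely)
    return possible, likely


def classify_table(
    rows: pd.DataFrame, criteria: DecisionCriteria = DecisionCriteria()
) -> pd.DataFrame:
    """Screen an analysis table; returns participant_id, possible, likely."""
    possible, likely = classify(
        rows["rdw"].to_numpy(), rows["glucose_gap"].to_numpy(), criteria
    )
    return pd.DataFrame(
        {
            "participant_id": rows["participant_id"].astype(str),
            "possible": possible,
            "likely": likely,
        }
    )
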