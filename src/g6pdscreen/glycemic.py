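"""Glycemic discordance metrics.

HbA1c reflects average glycemia over the preceding ~3 months, but only for
red cells of normal lifespan.  In G6PD deficiency erythrocytes turn over
faster, so HbA1c under-reports true glycemia.  The *glucose gap* quantifies
this discordance as the measured blood glucose minus the estimated average
glucose (eAG) implied by HbA1c under the standard ADAG linear glycation
relationship

    eAG (mg/dL) = 28.7 x HbA1c (%) - 46.7 .

A markedly positive-shifted gap (glucose well above what HbA1c predicts)
suggests shortened red-cell lifespan.  The simple glucose/HbA1c ratio is
retained as a published comparator.

Units are fixed: glucose and eAG in mg/dL, HbA1c in NGSP % units.  No
mmol/L or IFCC conversion is performed; the glycation constants are
mg/dL-specific.  Values are never rounded here — rounding belongs to
report formatting so that conservation identities stay exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EAG_SLOPE",
    "EAG_INTERCEPT",
    "GlycemicIndices",
    "estimated_average_glucose",
    "glucose_gap",
    "chang_ratio",
]

#: ADAG glycation line, mg/dL per % and mg/dL.
EAG_SLOPE = 28.7
EAG_INTERCEPT = -46.7


def _check_hba1c(hba1c):
    arr = np.asarray(hba1c, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("hba1c must be finite and > 0 (NGSP % units)")
    return arr


def _check_glucose(glucose):
    arr = np.asarray(glucose, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise ValueError("glucose must be finite and >= 0 (mg/dL)")
    return arr


def estimated_average_glucose(hba1c):
    """Estimated average glucose in mg/dL from HbA1c in % units.

    Applies ``28.7 * hba1c - 46.7`` with no clamping; accepts scalars or
    array-likes and broadcasts.  Raises ``ValueError`` for non-finite or
    nonpositive HbA1c.
    """
    arr = _check_hba1c(hba1c)
    out = EAG_SLOPE * arr + EAG_INTERCEPT
    return float(out) if np.isscalar(hba1c) else out


def glucose_gap(glucose, hba1c):
    """Glucose gap (mg/dL): measured glucose minus estimated average glucose.

    Positive-shifted gaps indicate HbA1c under-reporting glycemia, as seen
    with shortened erythrocyte lifespan.
    """
    g = _check_glucose(glucose)
    eag = EAG_SLOPE * _check_hba1c(hba1c) + EAG_INTERCEPT
    out = g - eag
    if np.isscalar(glucose) and np.isscalar(hba1c):
        return float(out)
    return out


def chang_ratio(glucose, hba1c):
    """Glucose / HbA1c ratio (mg/dL per %), a published screening comparator."""
    g = _check_glucose(glucose)
    a = _check_hba1c(hba1c)
    out = g / a
    if np.isscalar(glucose) and np.isscalar(hba1c):
        return float(out)
    return out


@dataclass(frozen=True)
class GlycemicIndices:
    """All glycemic discordance metrics for one measurement event."""

    glucose: float
    hba1c: float
    eag: float
    glucose_gap: float
    chang_ratio: float

    @classmethod
    def from_measurements(cls, glucose: float, hba1c: float) -> "GlycemicIndices":
        eag = estimated_average_glucose(hba1c)
        return cls(
            glucose=float(glucose),
            hba1c=float(hba1c),
            eag=eag,
            glucose_gap=glucose_gap(glucose, hba1c),
            chang_ratio=chang_ratio(glucose, hba1c),
        )
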