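"""LMS anthropometric z-scores and the nutritional-status exclusion filter.

Norming samples must consist of well-nourished children, so children are
screened with weight-for-age (WAZ) and MUAC-for-age (MUACZ) z-scores under
the LMS construction: z = ((x/M)^L - 1)/(L*S), with the L -> 0 limit
z = ln(x/M)/S. A child is *malnourished* when WAZ <= -2, or — only when WAZ
is unavailable — when MUACZ <= -2; a child with neither z-score computable
has *unknown* status. Malnourished and unknown-status children are excluded
from the analysis set.

No extreme-value restricted adjustment is applied: the z-scores are plain
LMS transforms of the supplied reference tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .instrument import ChildRecord, LmsReference, ValidationError
from .scoring import compute_age

NUTRITION_STATUSES = ("normal", "malnourished", "unknown")

#: exclusion threshold on either z-score (inclusive)
Z_CUTOFF = -2.0


@dataclass(frozen=True)
class AnthroRecord:
    child_id: str
    waz: float | None
    muacz: float | None

    @property
    def nutrition_status(self) -> str:
        """WAZ rules when present; MUACZ consulted only when WAZ is missing."""
        if self.waz is not None:
            return "malnourished" if self.waz <= Z_CUTOFF else "normal"
        if self.muacz is not None:
            return "malnourished" if self.muacz <= Z_CUTOFF else "normal"
        return "unknown"


def lms_zscore(x: float, L: float, M: float, S: float) -> float:
    """LMS z-score of measurement x against Box-Cox parameters (L, M, S)."""
    if x <= 0 or M <= 0 or S <= 0:
        raise ValidationError("lms_zscore requires positive x, M and S")
    if abs(L) < 1e-7:
        return math.log(x / M) / S
    return ((x / M) ** L - 1.0) / (L * S)


def lms_inverse(z: float, L: float, M: float, S: float) -> float:
    """Measurement value whose z-score is z (used by the cohort simulator)."""
    if abs(L) < 1e-7:
        return M * math.exp(S * z)
    return M * (1.0 + L * S * z) ** (1.0 / L)


def interpolate_reference(
    reference: LmsReference, indicator: str, sex: str, age_days: float
):
    """(L, M, S) linearly interpolated at age_days; None outside the grid."""
    return reference.lookup(indicator, sex, age_days)


def compute_anthro(
    roster: list[ChildRecord], reference: LmsReference
) -> list[AnthroRecord]:
    """WAZ/MUACZ for every rostered child (None where not computable)."""
    out = []
    for child in roster:
        age = compute_age(child.birth_date, child.test_date).age_days
        waz = muacz = None
        if child.weight_kg is not None and child.weight_kg > 0:
            lms = reference.lookup("weight_for_age", child.sex, age)
            if lms is not None:
                waz = lms_zscore(child.weight_kg, *lms)
        if child.muac_cm is not None and child.muac_cm > 0:
            lms = reference.lookup("muac_for_age", child.sex, age)
            if lms is not None:
                muacz = lms_zscore(child.muac_cm, *lms)
        out.append(AnthroRecord(child_id=child.child_id, waz=waz, muacz=muacz))
    return out


def apply_exclusions(
    roster: list[ChildRecord], anthro: list[AnthroRecord]
) -> tuple[list[ChildRecord], dict]:
    """Drop malnourished and unknown-status children.

    Returns the retained roster and an accounting report with counts by reason.
    """
    by_id = {a.child_id: a for a in anthro}
    missing = [c.child_id for c in roster if c.child_id not in by_id]
    if missing:
        raise ValidationError(f"no anthropometry for children {missing[:5]}")
    kept, n_mal, n_unknown = [], 0, 0
    for child in roster:
        status = by_id[child.child_id].nutrition_status
        if status == "malnourished":
            n_mal += 1
        elif status == "unknown":
            n_unknown += 1
        else:
            kept.append(child)
    report = {
        "n_input": len(roster),
        "n_retained": len(kept),
        "excluded": {"malnourished": n_mal, "unknown_status": n_unknown},
    }
    return kept, report
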