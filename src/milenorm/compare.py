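"""Comparison of local milestone norms against a reference standard.

Attainment is compared item by item on the 90% milestone age. A relative
difference of more than 10% of the reference age — in either direction — is
treated as clinically significant: the item is flagged *later* (local age
higher) or *earlier* (local age lower); otherwise *similar*. Exactly 10% is
not "more than 10%" and counts as similar. The denominator is the reference
age; when the reference age is birth (0) and the local age is not, no
relative difference exists and the item is flagged *incomparable*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .instrument import Instrument, NormsTable, ValidationError

#: relative-difference threshold for a clinically significant norm difference
SIGNIFICANT_REL_DIFF = 0.10


@dataclass(frozen=True)
class ComparisonResult:
    item_code: str
    local_p90: float
    reference_p90: float
    relative_diff: float  # NaN when incomparable
    flag: str             # similar / earlier / later / incomparable


def classify_item(
    local_p90: float,
    reference_p90: float,
    item_code: str = "",
    threshold: float = SIGNIFICANT_REL_DIFF,
) -> ComparisonResult:
    """Classify one item's 90% milestone age against the reference."""
    if local_p90 < 0 or reference_p90 < 0:
        raise ValidationError("milestone ages must be nonnegative")
    if math.isnan(local_p90) or math.isnan(reference_p90):
        return ComparisonResult(item_code, local_p90, reference_p90, float("nan"), "incomparable")
    if reference_p90 == 0:
        flag = "similar" if local_p90 == 0 else "incomparable"
        rel = 0.0 if local_p90 == 0 else float("nan")
        return ComparisonResult(item_code, local_p90, reference_p90, rel, flag)
    rel = (local_p90 - reference_p90) / reference_p90
    if rel > threshold:
        flag = "later"
    elif rel < -threshold:
        flag = "earlier"
    else:
        flag = "similar"
    return ComparisonResult(item_code, local_p90, reference_p90, rel, flag)


def compare_norms(
    local: NormsTable,
    reference: NormsTable,
    threshold: float = SIGNIFICANT_REL_DIFF,
) -> pd.DataFrame:
    """Item-by-item comparison on the 90% age over the shared item set."""
    rows = []
    for code in local.item_codes:
        if code not in reference:
            continue
        res = classify_item(
            local.percentile_months(code, 90),
            reference.percentile_months(code, 90),
            item_code=code,
            threshold=threshold,
        )
        rows.append({
            "item_code": res.item_code,
            "local_p90_months": res.local_p90,
            "reference_p90_months": res.reference_p90,
            "relative_diff": res.relative_diff,
            "flag": res.flag,
        })
    return pd.DataFrame(
        rows,
        columns=["item_code", "local_p90_months", "reference_p90_months",
                 "relative_diff", "flag"],
    )


def summarize_comparison(
    flags: pd.Series | dict[str, str], instrument: Instrument | None = None
) -> dict:
    """Counts (and percentages) of similar/earlier/later/incomparable flags.

    `flags` maps item_code -> flag. With an instrument, per-domain counts of
    differing items are added. Percentages use classified (non-incomparable)
    items as the denominator.
    """
    if isinstance(flags, pd.Series):
        flags = flags.to_dict()
    counts = {k: 0 for k in ("similar", "earlier", "later", "incomparable")}
    for flag in flags.values():
        if flag not in counts:
            raise ValidationError(f"unknown comparison flag {flag!r}")
        counts[flag] += 1
    classified = counts["similar"] + counts["earlier"] + counts["later"]
    differing = counts["earlier"] + counts["later"]
    summary = {
        **counts,
        "differing": differing,
        "n_classified": classified,
        "pct_differing": 100.0 * differing / classified if classified else 0.0,
        "pct_similar": 100.0 * counts["similar"] / classified if classified else 0.0,
    }
    if instrument is not None:
        by_domain = {}
        for dom in ("PS", "FM", "LA", "GM"):
            codes = {it.item_code for it in instrument.domain_items(dom)}
            by_domain[dom] = sum(
                1 for c, f in flags.items() if c in codes and f in ("earlier", "later")
            )
        summary["differing_by_domain"] = by_domain
    return summary
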