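"""Chart scoring: age line, implied pass/fail resolution, categorical and
performance-ratio scores.

Scoring follows the Denver II chart conventions. A child's exact age in days
fixes the age line. Within each domain (items in chart order):

* items to the left of the leftmost run of three consecutive *tested* passes
  are *implied passes* (achieved at a lower age, assumed mastered);
* items to the right of the rightmost run of three consecutive *tested*
  fails are *implied fails*;
* a tested result always beats an implied one (conflicts are logged).

The categorical pass/fail score used for model fitting keeps only tested
information: pass = tested pass; fail = tested fail or refusal; implied
results and "no opportunity" are missing. The numerical score is the
performance ratio: actual passes (tested + implied) over expected passes
(items whose 75% milestone age lies at or below the child's age).
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import pandas as pd

from .instrument import (
    DAYS_PER_MONTH,
    DOMAINS,
    ChildAge,
    ChildRecord,
    Instrument,
    ItemDefinition,
    NormsTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: resolved per-item statuses
STATUSES = (
    "tested_pass", "tested_fail", "implied_pass", "implied_fail",
    "refusal", "no_opportunity", "not_reached",
)

_CATEGORICAL = {
    "tested_pass": "pass",
    "tested_fail": "fail",
    "refusal": "fail",
}


@dataclass(frozen=True)
class ScoredRecord:
    child_id: str
    item_code: str
    status: str

    @property
    def categorical(self) -> str:
        """pass / fail / missing — the binary outcome used for model fitting."""
        return _CATEGORICAL.get(self.status, "missing")


@dataclass(frozen=True)
class DomainScore:
    child_id: str
    domain: str
    actual_passes: int
    expected_passes: int

    @property
    def performance_ratio(self) -> float | None:
        """actual/expected, or None (undefined) when nothing is expected yet."""
        if self.expected_passes == 0:
            return None
        return self.actual_passes / self.expected_passes


def compute_age(birth_date: dt.date, test_date: dt.date) -> ChildAge:
    """Exact calendar-day age at testing (the age-line position)."""
    days = (test_date - birth_date).days
    if days < 0:
        raise ValidationError("test_date precedes birth_date")
    return ChildAge(age_days=days)


def _find_run(flags: list[bool], run: int, *, leftmost: bool) -> int | None:
    """Start index of the leftmost/rightmost run of `run` consecutive True."""
    indices = range(len(flags) - run + 1)
    if not leftmost:
        indices = reversed(indices)
    for i in indices:
        if all(flags[i:i + run]):
            return i
    return None


def resolve_implied(
    domain_items: tuple[ItemDefinition, ...] | list[ItemDefinition],
    tested: dict[str, str],
    child_id: str = "",
) -> list[ScoredRecord]:
    """Resolve implied passes/fails for one domain of one child.

    `tested` maps item_code -> raw result for administered items;
    ``not_administered`` entries are treated as absent.
    """
    items = sorted(domain_items, key=lambda it: it.chart_order)
    raw = [tested.get(it.item_code) for it in items]
    raw = [None if r == "not_administered" else r for r in raw]

    passed = [r == "tested_pass" for r in raw]
    failed = [r == "tested_fail" for r in raw]
    pass_run = _find_run(passed, 3, leftmost=True)
    fail_run = _find_run(failed, 3, leftmost=False)

    statuses: list[str] = []
    for i, r in enumerate(raw):
        if r is not None:
            statuses.append(r)
            in_pass_region = pass_run is not None and i < pass_run
            in_fail_region = fail_run is not None and i > fail_run + 2
            if (in_pass_region and r != "tested_pass") or (in_fail_region and r != "tested_fail"):
                logger.debug(
                    "tested result %s for %s kept inside implied region (child %s)",
                    r, items[i].item_code, child_id,
                )
            continue
        if pass_run is not None and i < pass_run:
            statuses.append("implied_pass")
        elif fail_run is not None and i > fail_run + 2:
            statuses.append("implied_fail")
        else:
            statuses.append("not_reached")
    return [
        ScoredRecord(child_id=child_id, item_code=it.item_code, status=s)
        for it, s in zip(items, statuses)
    ]


def expected_items(age: ChildAge, norms: NormsTable) -> set[str]:
    """Items whose 75% milestone age lies at or below the child's age."""
    return {
        code for code in norms.item_codes
        if norms.percentile_days(code, 75) <= age.age_days + 1e-9
    }


def actual_passes(records: list[ScoredRecord]) -> int:
    """Tested plus implied passes."""
    return sum(r.status in ("tested_pass", "implied_pass") for r in records)


def performance_ratio(actual: int, expected: int) -> float | None:
    """Ratio of actual to expected passes; None (undefined) when expected = 0."""
    if expected < 0:
        raise ValidationError("expected passes must be nonnegative")
    if expected == 0:
        return None
    return actual / expected


def score_child_domain(
    child: ChildRecord,
    domain: str,
    instrument: Instrument,
    norms: NormsTable,
    tested: dict[str, str],
    *,
    age: ChildAge | None = None,
) -> tuple[list[ScoredRecord], DomainScore]:
    """Resolve statuses and the domain score for one child in one domain."""
    if age is None:
        age = compute_age(child.birth_date, child.test_date)
    items = instrument.domain_items(domain)
    records = resolve_implied(items, tested, child_id=child.child_id)
    expected = {
        c for c in expected_items(age, norms) if c in {it.item_code for it in items}
    }
    score = DomainScore(
        child_id=child.child_id,
        domain=domain,
        actual_passes=actual_passes(records),
        expected_passes=len(expected),
    )
    return records, score


def score_cohort(
    instrument: Instrument,
    norms: NormsTable,
    roster: list[ChildRecord],
    responses: pd.DataFrame,
    occasion: str = "test",
    rater_role: str = "tester",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every child on one (occasion, rater_role) pass over the chart.

    Returns a long scored frame (child_id, item_code, domain, status,
    categorical, age_days) and a per-(child, domain) score frame with the
    performance ratio (NaN where undefined).
    """
    sel = responses[
        (responses["occasion"] == occasion) & (responses["rater_role"] == rater_role)
    ]
    by_child: dict[str, dict[str, str]] = {}
    for row in sel.itertuples(index=False):
        by_child.setdefault(row.child_id, {})[row.item_code] = row.raw_result

    domain_of = {it.item_code: it.domain for it in instrument.items}
    scored_rows = []
    score_rows = []
    for child in roster:
        tested_all = by_child.get(child.child_id, {})
        unknown = set(tested_all) - set(domain_of)
        if unknown:
            raise ValidationError(
                f"responses for {child.child_id} reference unknown items {sorted(unknown)}"
            )
        age = compute_age(
            child.birth_date,
            child.test_date if occasion == "test" else (child.retest_date or child.test_date),
        )
        for dom in DOMAINS:
            items = instrument.domain_items(dom)
            if not items:
                continue
            codes = {it.item_code for it in items}
            tested = {c: r for c, r in tested_all.items() if c in codes}
            records, score = score_child_domain(
                child, dom, instrument, norms, tested, age=age
            )
            for rec in records:
                scored_rows.append({
                    "child_id": rec.child_id,
                    "item_code": rec.item_code,
                    "domain": dom,
                    "status": rec.status,
                    "categorical": rec.categorical,
                    "age_days": age.age_days,
                })
            ratio = score.performance_ratio
            score_rows.append({
                "child_id": child.child_id,
                "domain": dom,
                "actual_passes": score.actual_passes,
                "expected_passes": score.expected_passes,
                "performance_ratio": float("nan") if ratio is None else ratio,
                "ratio_defined": ratio is not None,
            })
    scored = pd.DataFrame(
        scored_rows,
        columns=["child_id", "item_code", "domain", "status", "categorical", "age_days"],
    )
    scores = pd.DataFrame(
        score_rows,
        columns=["child_id", "domain", "actual_passes", "expected_passes",
                 "performance_ratio", "ratio_defined"],
    )
    return scored, scores
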