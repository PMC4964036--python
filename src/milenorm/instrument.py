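"""Domain types and file formats for chart-based developmental screening data.

The instrument is a Denver-style chart: items grouped into four developmental
domains — personal-social (PS), fine motor (FM), language (LA), gross motor
(GM) — each laid out in a fixed chart order by typical age of attainment.
This module defines the typed containers (instrument, child roster, item
responses, milestone norms, LMS growth references) and the CSV readers/writers
the rest of the pipeline uses.

All ages are handled internally in days; months appear only at reporting
boundaries, converted with ``DAYS_PER_MONTH``.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: days per month used everywhere days <-> months convert (365.25 / 12)
DAYS_PER_MONTH = 30.4375

DOMAINS = ("PS", "FM", "LA", "GM")

DOMAIN_NAMES = {
    "PS": "Personal social",
    "FM": "Fine motor",
    "LA": "Language",
    "GM": "Gross motor",
}

#: raw result codes a response file may carry
RAW_RESULTS = (
    "tested_pass",
    "tested_fail",
    "refusal",
    "no_opportunity",
    "not_administered",
)

#: accepted aliases for raw result codes (case-insensitive)
RAW_RESULT_ALIASES = {
    "pass": "tested_pass",
    "p": "tested_pass",
    "fail": "tested_fail",
    "f": "tested_fail",
    "r": "refusal",
    "no": "no_opportunity",
    "no_opp": "no_opportunity",
    "na": "not_administered",
}

PERCENTILE_COLUMNS = ("p25_months", "p50_months", "p75_months", "p90_months")
COMPARISON_FLAGS = ("similar", "earlier", "later", "unfitted", "incomparable")

OCCASIONS = ("test", "retest")
RATER_ROLES = ("tester", "observer")


class ValidationError(ValueError):
    """A file or record violated one of the documented schema invariants."""


# ---------------------------------------------------------------------------
# core types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ItemDefinition:
    item_code: str
    label: str
    domain: str
    chart_order: int
    adapted: bool = False
    culture_specific: bool = False

    def __post_init__(self):
        if self.domain not in DOMAINS:
            raise ValidationError(f"unknown domain {self.domain!r} for {self.item_code}")
        if not self.item_code.startswith(self.domain):
            raise ValidationError(
                f"item code {self.item_code!r} does not carry its domain prefix {self.domain}"
            )
        if self.chart_order < 1:
            raise ValidationError(f"chart_order must be positive ({self.item_code})")


@dataclass(frozen=True)
class Instrument:
    """An ordered collection of items, validated for dense per-domain ordering."""

    name: str
    items: tuple[ItemDefinition, ...]

    def __post_init__(self):
        if not self.items:
            raise ValidationError("no items")
        codes = [it.item_code for it in self.items]
        if len(set(codes)) != len(codes):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise ValidationError(f"duplicate item codes: {', '.join(dupes)}")
        for dom in DOMAINS:
            orders = sorted(it.chart_order for it in self.items if it.domain == dom)
            if orders and orders != list(range(1, len(orders) + 1)):
                raise ValidationError(
                    f"chart_order not dense 1..n in domain {dom} (got {orders})"
                )

    def __len__(self) -> int:
        return len(self.items)

    def domain_items(self, domain: str) -> tuple[ItemDefinition, ...]:
        """Items of one domain in chart order."""
        return tuple(sorted(
            (it for it in self.items if it.domain == domain),
            key=lambda it: it.chart_order,
        ))

    def item(self, item_code: str) -> ItemDefinition:
        for it in self.items:
            if it.item_code == item_code:
                return it
        raise KeyError(item_code)

    @property
    def item_codes(self) -> tuple[str, ...]:
        return tuple(it.item_code for it in self.items)

    def n_adapted(self) -> int:
        return sum(it.adapted for it in self.items)


@dataclass(frozen=True)
class ChildAge:
    """Exact age at testing; the age-line position on the chart."""

    age_days: int

    def __post_init__(self):
        if self.age_days < 0:
            raise ValidationError("age_days must be nonnegative")

    @property
    def age_months(self) -> float:
        return self.age_days / DAYS_PER_MONTH


@dataclass(frozen=True)
class ChildRecord:
    child_id: str
    sex: str
    birth_date: dt.date
    test_date: dt.date
    weight_kg: float | None = None
    muac_cm: float | None = None
    tester_id: str | None = None
    observer_id: str | None = None
    retest_date: dt.date | None = None

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be male/female ({self.child_id})")
        if self.test_date < self.birth_date:
            raise ValidationError(f"test_date before birth_date for {self.child_id}")
        if self.retest_date is not None and self.retest_date <= self.test_date:
            raise ValidationError(f"retest_date must be after test_date for {self.child_id}")
        for name in ("weight_kg", "muac_cm"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be nonnegative ({self.child_id})")


@dataclass(frozen=True)
class ItemResponse:
    child_id: str
    item_code: str
    raw_result: str
    occasion: str = "test"
    rater_role: str = "tester"

    def __post_init__(self):
        if self.raw_result not in RAW_RESULTS:
            raise ValidationError(f"unknown raw_result {self.raw_result!r}")
        if self.occasion not in OCCASIONS or self.rater_role not in RATER_ROLES:
            raise ValidationError("occasion must be test/retest, rater_role tester/observer")


@dataclass
class NormsTable:
    """Milestone ages (25/50/75/90% passing, in months) per item.

    Backed by a DataFrame indexed by item_code with the four percentile columns
    and a ``flag`` column (similar/earlier/later/unfitted vs a reference).
    A value of 0 encodes attainment at birth.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        f = self.frame
        missing = [c for c in PERCENTILE_COLUMNS if c not in f.columns]
        if missing:
            raise ValidationError(f"norms table missing columns {missing}")
        if "flag" not in f.columns:
            f = f.assign(flag="similar")
        f = f[list(PERCENTILE_COLUMNS) + ["flag"]].copy()
        f[list(PERCENTILE_COLUMNS)] = f[list(PERCENTILE_COLUMNS)].astype(float)
        if f.index.has_duplicates:
            raise ValidationError("duplicate item codes in norms table")
        vals = f[list(PERCENTILE_COLUMNS)].to_numpy()
        if np.any(vals < 0):
            bad = f.index[(vals < 0).any(axis=1)]
            raise ValidationError(f"negative percentile age for {list(bad)}")
        nondec = np.diff(vals, axis=1) >= -1e-9
        if not nondec.all():
            bad = f.index[~nondec.all(axis=1)][0]
            raise ValidationError(f"non-monotone percentile ages for item {bad}")
        self.frame = f

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, item_code: str) -> bool:
        return item_code in self.frame.index

    @property
    def item_codes(self) -> tuple[str, ...]:
        return tuple(self.frame.index)

    def percentile_months(self, item_code: str, p: int) -> float:
        return float(self.frame.at[item_code, f"p{p}_months"])

    def percentile_days(self, item_code: str, p: int) -> float:
        return self.percentile_months(item_code, p) * DAYS_PER_MONTH

    def flag(self, item_code: str) -> str:
        return str(self.frame.at[item_code, "flag"])

    def subset(self, item_codes: Iterable[str]) -> "NormsTable":
        codes = [c for c in item_codes if c in self.frame.index]
        return NormsTable(self.frame.loc[codes].copy())


@dataclass
class LmsReference:
    """LMS growth-reference tables keyed by (indicator, sex).

    Each table is a strictly-increasing age grid (days) with Box-Cox power L,
    median M and coefficient of variation S; parameters are linearly
    interpolated between grid rows, and ages outside the grid yield None.
    """

    tables: Mapping[tuple[str, str], pd.DataFrame]

    def __post_init__(self):
        for key, tab in self.tables.items():
            if (tab["M"] <= 0).any() or (tab["S"] <= 0).any():
                raise ValidationError(f"LMS table {key}: M and S must be positive")
            ages = tab["age_days"].to_numpy()
            if not np.all(np.diff(ages) > 0):
                raise ValidationError(f"LMS table {key}: age grid not strictly increasing")

    def lookup(self, indicator: str, sex: str, age_days: float):
        """Interpolated (L, M, S) at age_days, or None outside the grid."""
        tab = self.tables.get((indicator, sex))
        if tab is None:
            return None
        ages = tab["age_days"].to_numpy()
        if age_days < ages[0] or age_days > ages[-1]:
            return None
        return tuple(
            float(np.interp(age_days, ages, tab[c].to_numpy())) for c in ("L", "M", "S")
        )


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------

def parse_decimal(value) -> float:
    """Parse a decimal that may use either '.' or ',' as the decimal mark."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    s = str(value).strip()
    if not s:
        raise ValidationError("empty numeric field")
    # tolerate stray duplicated marks such as '1.,8'
    s = s.replace(",", ".")
    while ".." in s:
        s = s.replace("..", ".")
    try:
        return float(s)
    except ValueError as exc:
        raise ValidationError(f"cannot parse number {value!r}") from exc


def _parse_date(value, *, context: str) -> dt.date:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise ValidationError(f"missing date in {context}")
    if isinstance(value, dt.date):
        return value
    try:
        return dt.date.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise ValidationError(f"bad ISO date {value!r} in {context}") from exc


def _opt(value):
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    s = str(value).strip()
    return s if s else None


def normalize_raw_result(code) -> str:
    s = str(code).strip().lower()
    s = RAW_RESULT_ALIASES.get(s, s)
    if s not in RAW_RESULTS:
        raise ValidationError(f"unknown raw_result code {code!r}")
    return s


def _require_columns(frame: pd.DataFrame, cols: Iterable[str], what: str):
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise ValidationError(f"{what}: missing columns {missing}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_instrument(path, name: str | None = None) -> Instrument:
    """Read an instrument definition CSV.

    Columns: item_code,label,domain,chart_order,adapted,culture_specific.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(
        frame,
        ("item_code", "label", "domain", "chart_order", "adapted", "culture_specific"),
        "instrument file",
    )
    if frame.empty:
        raise ValidationError("no items")
    items = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            items.append(ItemDefinition(
                item_code=row.item_code.strip(),
                label=row.label.strip(),
                domain=row.domain.strip(),
                chart_order=int(row.chart_order),
                adapted=_parse_bool(row.adapted),
                culture_specific=_parse_bool(row.culture_specific),
            ))
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"instrument row {i}: {exc}") from exc
    return Instrument(name=name or str(path), items=tuple(items))


def _parse_bool(value) -> bool:
    s = str(value).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no", ""):
        return False
    raise ValidationError(f"cannot parse boolean {value!r}")


def write_instrument(instrument: Instrument, path) -> None:
    rows = [
        {
            "item_code": it.item_code,
            "label": it.label,
            "domain": it.domain,
            "chart_order": it.chart_order,
            "adapted": str(it.adapted).lower(),
            "culture_specific": str(it.culture_specific).lower(),
        }
        for it in instrument.items
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_norms(path) -> NormsTable:
    """Read a norms CSV; decimal-comma and decimal-point dialects both accepted."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(frame, ("item_code",) + PERCENTILE_COLUMNS, "norms file")
    out = {}
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        code = row.item_code.strip()
        try:
            vals = {c: parse_decimal(getattr(row, c)) for c in PERCENTILE_COLUMNS}
        except ValidationError as exc:
            raise ValidationError(f"norms row {i} ({code}): {exc}") from exc
        flag = getattr(row, "flag", "similar") if "flag" in frame.columns else "similar"
        flag = str(flag).strip() or "similar"
        if flag not in COMPARISON_FLAGS:
            raise ValidationError(f"norms row {i} ({code}): unknown flag {flag!r}")
        out[code] = {**vals, "flag": flag}
    table = pd.DataFrame.from_dict(out, orient="index")
    table.index.name = "item_code"
    return NormsTable(table)


def write_norms(norms: NormsTable, path) -> None:
    """Write a norms CSV (decimal point, months to 1 decimal)."""
    f = norms.frame.copy()
    for c in PERCENTILE_COLUMNS:
        f[c] = f[c].map(lambda v: f"{v:.1f}")
    f.to_csv(path, index=True, index_label="item_code")


def read_roster(path) -> list[ChildRecord]:
    """Read a child roster CSV into validated records (ISO-8601 dates)."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(
        frame,
        ("child_id", "sex", "birth_date", "test_date", "weight_kg", "muac_cm",
         "tester_id", "observer_id", "retest_date"),
        "roster file",
    )
    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        cid = row.child_id.strip()
        try:
            records.append(ChildRecord(
                child_id=cid,
                sex=row.sex.strip().lower(),
                birth_date=_parse_date(row.birth_date, context=f"roster row {i}"),
                test_date=_parse_date(row.test_date, context=f"roster row {i}"),
                weight_kg=parse_decimal(row.weight_kg) if _opt(row.weight_kg) else None,
                muac_cm=parse_decimal(row.muac_cm) if _opt(row.muac_cm) else None,
                tester_id=_opt(row.tester_id),
                observer_id=_opt(row.observer_id),
                retest_date=(
                    _parse_date(row.retest_date, context=f"roster row {i}")
                    if _opt(row.retest_date) else None
                ),
            ))
        except ValidationError as exc:
            raise ValidationError(f"roster row {i} ({cid}): {exc}") from exc
    ids = [r.child_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate child_id in roster")
    return records


def roster_frame(records: Iterable[ChildRecord]) -> pd.DataFrame:
    """Roster records as a DataFrame (dates kept as datetime.date objects)."""
    return pd.DataFrame([
        {
            "child_id": r.child_id, "sex": r.sex, "birth_date": r.birth_date,
            "test_date": r.test_date, "weight_kg": r.weight_kg, "muac_cm": r.muac_cm,
            "tester_id": r.tester_id, "observer_id": r.observer_id,
            "retest_date": r.retest_date,
        }
        for r in records
    ])


def write_roster(records: Iterable[ChildRecord], path) -> None:
    frame = roster_frame(records)
    for c in ("birth_date", "test_date", "retest_date"):
        frame[c] = frame[c].map(lambda d: d.isoformat() if d is not None else "")
    for c in ("weight_kg", "muac_cm"):
        frame[c] = frame[c].map(lambda v: "" if v is None or pd.isna(v) else f"{v:.3f}")
    frame = frame.fillna("")
    frame.to_csv(path, index=False)


def read_responses(path) -> pd.DataFrame:
    """Read an item-response CSV into a validated long DataFrame.

    Columns: child_id,occasion,rater_role,item_code,raw_result. Raw result
    aliases (pass/fail/P/F/...) are normalized to the canonical codes.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(
        frame, ("child_id", "occasion", "rater_role", "item_code", "raw_result"),
        "responses file",
    )
    frame = frame.copy()
    frame["raw_result"] = frame["raw_result"].map(normalize_raw_result)
    for col, allowed in (("occasion", OCCASIONS), ("rater_role", RATER_ROLES)):
        bad = set(frame[col]) - set(allowed)
        if bad:
            raise ValidationError(f"responses file: unknown {col} values {sorted(bad)}")
    dupes = frame.duplicated(["child_id", "occasion", "rater_role", "item_code"])
    if dupes.any():
        first = frame.loc[dupes.idxmax()]
        raise ValidationError(
            "duplicate response for child "
            f"{first['child_id']} item {first['item_code']} ({first['occasion']}/{first['rater_role']})"
        )
    return frame


def write_responses(frame: pd.DataFrame, path) -> None:
    cols = ["child_id", "occasion", "rater_role", "item_code", "raw_result"]
    frame[cols].to_csv(path, index=False)


def read_lms_reference(path) -> LmsReference:
    """Read an LMS reference CSV (indicator,sex,age_days,L,M,S)."""
    frame = pd.read_csv(path)
    _require_columns(frame, ("indicator", "sex", "age_days", "L", "M", "S"), "LMS file")
    tables = {}
    for (indicator, sex), grp in frame.groupby(["indicator", "sex"]):
        tab = grp[["age_days", "L", "M", "S"]].astype(float).sort_values("age_days")
        tables[(str(indicator), str(sex))] = tab.reset_index(drop=True)
    return LmsReference(tables)
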