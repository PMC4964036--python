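"""Tool reliability: item-level agreement and domain-level intraclass correlation.

Item level: tester-vs-observer (inter-rater, first test occasion only) and
test-vs-retest categorical pass/fail outcomes are cross-tabulated per item;
chance-corrected agreement is Cohen's kappa, read against the Landis-Koch
verbal bands. When a margin is degenerate (all observations in one row or
column of the table) kappa is undefined and the raw percent agreement is
reported instead, with 70% as the acceptability floor.

Domain level: per-child performance-ratio scores are correlated across
raters (one-way random-effects ICC(1,1)) and across occasions (two-way
random-effects, absolute-agreement ICC(2,1)), with 95% confidence intervals
from the standard F-based constructions. Single measures are used because
one score per child enters any downstream decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .instrument import Instrument, ValidationError

#: percent-agreement acceptability floor
AGREEMENT_FLOOR = 70.0

#: Landis-Koch cutpoints: (upper bound, band), evaluated left to right
LANDIS_KOCH_BANDS = (
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "excellent"),
)


@dataclass(frozen=True)
class AgreementTable:
    """2x2 pass/fail counts: a = both pass, b = A pass/B fail, c = A fail/B pass, d = both fail."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("agreement counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class KappaResult:
    item_code: str
    po: float
    pe: float
    kappa: float | None
    band: str
    pct_agreement: float
    n_pairs: int

    @property
    def acceptable_agreement(self) -> bool:
        return self.pct_agreement >= AGREEMENT_FLOOR


@dataclass
class IccResult:
    domain: str
    icc_type: str  # oneway_random | twoway_random
    icc: float
    ci95: tuple[float, float]
    n_subjects: int
    k_measurements: int
    notes: list[str] = field(default_factory=list)


def percent_agreement(table: AgreementTable) -> float:
    """100 * (diagonal sum) / total."""
    if table.total == 0:
        raise ValidationError("empty agreement table")
    return 100.0 * (table.a + table.d) / table.total


def landis_koch_band(kappa: float | None) -> str:
    """Verbal band for a kappa value; 'undefined' when kappa is None."""
    if kappa is None:
        return "undefined"
    if kappa > 1.0:
        raise ValidationError("kappa cannot exceed 1")
    for upper, band in LANDIS_KOCH_BANDS:
        if kappa <= upper:
            return band
    return "excellent"


def cohen_kappa(table: AgreementTable, item_code: str = "") -> KappaResult:
    """Chance-corrected 2x2 agreement; undefined under degenerate margins."""
    n = table.total
    if n == 0:
        raise ValidationError("empty agreement table")
    a, b, c, d = table.a, table.b, table.c, table.d
    po = (a + d) / n
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / (n * n)
    if pe >= 1.0 - 1e-12:
        kappa = None
    else:
        kappa = (po - pe) / (1.0 - pe)
    return KappaResult(
        item_code=item_code, po=po, pe=pe, kappa=kappa,
        band=landis_koch_band(kappa), pct_agreement=100.0 * po, n_pairs=n,
    )


# ---------------------------------------------------------------------------
# intraclass correlation
# ---------------------------------------------------------------------------

def _anova_mean_squares(x: np.ndarray):
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    bms = ss_rows / (n - 1)                      # between subjects
    wms = (ss_total - ss_rows) / (n * (k - 1))   # within subjects (one-way)
    jms = ss_cols / (k - 1)                      # between measurements
    ems = ss_err / ((n - 1) * (k - 1))           # residual (two-way)
    return bms, wms, jms, ems


def icc(matrix, icc_type: str, domain: str = "", alpha: float = 0.05) -> IccResult:
    """Single-measure ICC from a subjects x measurements matrix.

    ``oneway_random``: ICC(1,1) = (BMS - WMS) / (BMS + (k-1) WMS).
    ``twoway_random``: absolute-agreement ICC(2,1) =
    (BMS - EMS) / (BMS + (k-1) EMS + k (JMS - EMS)/n).
    Rows containing missing values are dropped (noted). 95% CIs follow the
    standard F-based constructions (Satterthwaite df for ICC(2,1)).
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValidationError("ICC needs a 2-D subjects x measurements matrix")
    notes = []
    keep = ~np.isnan(x).any(axis=1)
    if not keep.all():
        notes.append(f"dropped {int((~keep).sum())} rows with missing measurements")
        x = x[keep]
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValidationError("ICC needs at least 2 subjects and 2 measurements")
    bms, wms, jms, ems = _anova_mean_squares(x)

    if bms <= 1e-300 and (wms > 0 or ems > 0):
        notes.append("zero between-subject variance")
        return IccResult(domain, icc_type, 0.0, (0.0, 0.0), n, k, notes)

    if icc_type == "oneway_random":
        if bms + (k - 1) * wms == 0:
            value = 1.0  # all measurements identical
        else:
            value = (bms - wms) / (bms + (k - 1) * wms)
        if wms <= 0:
            lo = hi = 1.0
        else:
            f_obs = bms / wms
            fl = f_obs / f_dist.ppf(1 - alpha / 2, n - 1, n * (k - 1))
            fu = f_obs * f_dist.ppf(1 - alpha / 2, n * (k - 1), n - 1)
            lo = (fl - 1) / (fl + k - 1)
            hi = (fu - 1) / (fu + k - 1)
    elif icc_type == "twoway_random":
        denom = bms + (k - 1) * ems + k * (jms - ems) / n
        value = 1.0 if denom == 0 else (bms - ems) / denom
        if ems <= 0 and jms <= 0:
            lo = hi = 1.0
        else:
            r = value
            a = k * r / (n * (1 - r)) if r < 1 else np.inf
            b = 1 + k * r * (n - 1) / (n * (1 - r)) if r < 1 else np.inf
            if np.isfinite(a) and np.isfinite(b):
                num = (a * jms + b * ems) ** 2
                den = (a * jms) ** 2 / (k - 1) + (b * ems) ** 2 / ((n - 1) * (k - 1))
                v = num / den if den > 0 else (n - 1) * (k - 1)
                f_star_l = f_dist.ppf(1 - alpha / 2, n - 1, v)
                f_star_u = f_dist.ppf(1 - alpha / 2, v, n - 1)
                lo = n * (bms - f_star_l * ems) / (
                    f_star_l * (k * jms + (k * n - k - n) * ems) + n * bms
                )
                hi = n * (f_star_u * bms - ems) / (
                    k * jms + (k * n - k - n) * ems + n * f_star_u * bms
                )
            else:
                lo = hi = 1.0
    else:
        raise ValidationError(f"unknown icc_type {icc_type!r}")

    lo, hi = float(np.clip(lo, -1, 1)), float(np.clip(hi, -1, 1))
    return IccResult(domain, icc_type, float(np.clip(value, -1, 1)), (lo, hi), n, k, notes)


# ---------------------------------------------------------------------------
# full reliability report
# ---------------------------------------------------------------------------

def agreement_table_from_pairs(cat_a: pd.Series, cat_b: pd.Series) -> AgreementTable:
    """Cross-tabulate two aligned pass/fail series (missing pairs dropped)."""
    frame = pd.DataFrame({"a": cat_a, "b": cat_b}).dropna()
    frame = frame[frame["a"].isin(["pass", "fail"]) & frame["b"].isin(["pass", "fail"])]
    return AgreementTable(
        a=int(((frame["a"] == "pass") & (frame["b"] == "pass")).sum()),
        b=int(((frame["a"] == "pass") & (frame["b"] == "fail")).sum()),
        c=int(((frame["a"] == "fail") & (frame["b"] == "pass")).sum()),
        d=int(((frame["a"] == "fail") & (frame["b"] == "fail")).sum()),
    )


def _paired_categoricals(scored_a: pd.DataFrame, scored_b: pd.DataFrame, item_code: str):
    a = scored_a[scored_a["item_code"] == item_code].set_index("child_id")["categorical"]
    b = scored_b[scored_b["item_code"] == item_code].set_index("child_id")["categorical"]
    shared = a.index.intersection(b.index)
    return a.loc[shared], b.loc[shared]


def item_kappas(
    scored_a: pd.DataFrame, scored_b: pd.DataFrame, instrument: Instrument,
    min_pairs: int = 1,
) -> tuple[list[KappaResult], list[str]]:
    """Per-item kappa between two scored passes; items without pairs listed."""
    results, omitted = [], []
    for it in instrument.items:
        a, b = _paired_categoricals(scored_a, scored_b, it.item_code)
        table = agreement_table_from_pairs(a, b)
        if table.total < min_pairs:
            omitted.append(it.item_code)
            continue
        results.append(cohen_kappa(table, item_code=it.item_code))
    return results, omitted


def band_frequency(results: list[KappaResult]) -> dict[str, int]:
    bands = [b for _, b in LANDIS_KOCH_BANDS] + ["undefined"]
    freq = {b: 0 for b in bands}
    for r in results:
        freq[r.band] += 1
    return freq


def _ratio_matrix(scores_a: pd.DataFrame, scores_b: pd.DataFrame, domain: str) -> np.ndarray:
    a = scores_a[(scores_a["domain"] == domain) & scores_a["ratio_defined"]]
    b = scores_b[(scores_b["domain"] == domain) & scores_b["ratio_defined"]]
    merged = a.set_index("child_id")["performance_ratio"].to_frame("m1").join(
        b.set_index("child_id")["performance_ratio"].to_frame("m2"), how="inner"
    )
    return merged.to_numpy()


def reliability_report(
    *,
    tester_test_scored: pd.DataFrame,
    tester_test_scores: pd.DataFrame,
    observer_test_scored: pd.DataFrame | None,
    observer_test_scores: pd.DataFrame | None,
    tester_retest_scored: pd.DataFrame | None,
    tester_retest_scores: pd.DataFrame | None,
    instrument: Instrument,
    min_pairs: int = 10,
) -> dict:
    """Item-level kappa band frequencies and domain-level ICCs.

    Inter-rater uses tester vs observer at the first test occasion only;
    test-retest uses the tester's scores at the two occasions. Returns a
    report dict shaped like the study's reliability table: per-condition band
    counts, undefined-kappa items with their percent agreement, and per-domain
    ICC(1,1) (inter-rater) / ICC(2,1) (test-retest) with 95% CIs.
    """
    report: dict = {"items_total": len(instrument)}
    conditions = []
    if observer_test_scored is not None:
        conditions.append((
            "inter_rater", tester_test_scored, observer_test_scored,
            tester_test_scores, observer_test_scores, "oneway_random",
        ))
    if tester_retest_scored is not None:
        conditions.append((
            "test_retest", tester_test_scored, tester_retest_scored,
            tester_test_scores, tester_retest_scores, "twoway_random",
        ))
    if not conditions:
        raise ValidationError("no paired occasions present")

    for name, sa, sb, ra, rb, icc_type in conditions:
        kappas, omitted = item_kappas(sa, sb, instrument, min_pairs=min_pairs)
        section = {
            "band_frequency": band_frequency(kappas),
            "n_items_computed": sum(1 for r in kappas if r.kappa is not None),
            "n_items_undefined": sum(1 for r in kappas if r.kappa is None),
            "items_omitted_no_pairs": omitted,
            "undefined_items": [
                {"item_code": r.item_code, "pct_agreement": r.pct_agreement,
                 "acceptable": r.acceptable_agreement}
                for r in kappas if r.kappa is None
            ],
            "kappa_by_item": {
                r.item_code: (r.kappa if r.kappa is not None else None) for r in kappas
            },
            "median_kappa": float(np.median(
                [r.kappa for r in kappas if r.kappa is not None]
            )) if any(r.kappa is not None for r in kappas) else None,
        }
        icc_by_domain = {}
        for dom in ("PS", "FM", "LA", "GM"):
            mat = _ratio_matrix(ra, rb, dom)
            if mat.shape[0] < 2:
                continue
            res = icc(mat, icc_type, domain=dom)
            icc_by_domain[dom] = {
                "icc": res.icc, "ci95": list(res.ci95),
                "n_subjects": res.n_subjects, "type": icc_type,
                "notes": res.notes,
            }
        section["icc_by_domain"] = icc_by_domain
        report[name] = section
    return report
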