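"""Synthetic norming cohorts with the statistical structure the pipeline assumes.

The generator emulates the study conditions end to end so every stage is
testable without external data:

* quota-sampled ages across the nine design age bins (0-2, 3-8, 9-14, 15-20,
  21-26, 27-32, 33-41, 42-53, 54-65 months), uniform within a bin;
* per-item pass outcomes drawn from plain logistic age curves whose
  parameters are inverted from a truth norms table (25% and 90% milestone
  ages pin slope and intercept; rows at birth become all-pass items);
* a chart-like administration protocol: testing starts at the age line and
  proceeds left until three consecutive passes and right until three
  consecutive fails are recorded, with small refusal / no-opportunity rates,
  so implied-status resolution has realistic work to do;
* anthropometry drawn so that configured fractions of children are
  malnourished (z <= -2 on the same LMS reference the screen uses) or of
  unknown status, with a subset measured by MUAC only;
* an observer score (independent per-item flip noise) for an inter-rater
  subset, and a revisit after ~14 days with outcomes redrawn at the older
  age for a test-retest subset.

Items are independent given age (no child-level latent ability), which is
the simplest structure consistent with the per-item marginal model; ground
truth is returned alongside the data for parameter-recovery tests and is
never consumed by the pipeline.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import fixtures
from .anthro import lms_inverse
from .instrument import (
    DAYS_PER_MONTH,
    DOMAINS,
    ChildRecord,
    Instrument,
    LmsReference,
    NormsTable,
    ValidationError,
)

#: the study's quota-sampling age bins in months (lo, hi inclusive)
STUDY_AGE_BINS = (
    (0, 2), (3, 8), (9, 14), (15, 20), (21, 26), (27, 32), (33, 41), (42, 53), (54, 65),
)

_STUDY_START = dt.date(2011, 1, 11)


@dataclass
class GeneratorConfig:
    """Study-condition knobs for the cohort generator.

    Defaults reproduce the standardization design: 1682 eligible children,
    equal quotas over the nine age bins, 83 malnourished and 2
    unknown-status children (deterministic rounding of the fractions, so the
    exclusion accounting is exact), a 409-child inter-rater subset of which
    147 children are retested after a mean 14-day interval, and a 2%
    per-item rater disagreement rate.
    """

    n_children: int = 1682
    age_bins: tuple[tuple[float, float], ...] = STUDY_AGE_BINS
    bin_weights: tuple[float, ...] | None = None  # None -> equal quotas
    truth_norms: NormsTable | None = None         # None -> packaged norms table
    instrument: Instrument | None = None          # None -> standardization chart
    lms: LmsReference | None = None               # None -> packaged synthetic LMS
    rater_flip_prob: float = 0.02
    retest_interval_days: tuple[float, float] = (14.0, 2.0)  # mean, sd
    malnourished_frac: float = 83 / 1682
    unknown_frac: float = 2 / 1682
    muac_only_frac: float = 0.03
    refusal_prob: float = 0.01
    no_opportunity_prob: float = 0.01
    n_observer: int = 409
    n_retest: int = 147
    administration: str = "chart"  # chart protocol, or "full" (every item tested)
    seed: int = 0

    def __post_init__(self):
        for name in ("rater_flip_prob", "malnourished_frac", "unknown_frac",
                     "muac_only_frac", "refusal_prob", "no_opportunity_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.n_children < 0:
            raise ValidationError("n_children must be nonnegative")
        if self.administration not in ("chart", "full"):
            raise ValidationError("administration must be 'chart' or 'full'")
        if self.bin_weights is not None:
            w = np.asarray(self.bin_weights, dtype=float)
            if len(w) != len(self.age_bins) or w.min() < 0 or not math.isclose(w.sum(), 1.0):
                raise ValidationError("bin_weights must be nonnegative and sum to 1")

    def resolve(self):
        truth = self.truth_norms if self.truth_norms is not None else fixtures.load_jimma_norms()
        inst = self.instrument if self.instrument is not None else fixtures.load_standardization_instrument()
        lms = self.lms if self.lms is not None else fixtures.load_synthetic_lms()
        return truth, inst, lms


def truth_to_logistic(p25_months: float, p90_months: float) -> tuple[float, float]:
    """Invert a (25%, 90%) milestone-age pair to logistic (alpha, beta/day).

    A degenerate birth row (p25 = p90 = 0) returns the all-pass marker
    (alpha = +inf, beta = 0), whose curve is identically 1.
    """
    if p25_months < 0 or p90_months < 0:
        raise ValidationError("milestone ages must be nonnegative")
    if p25_months > p90_months:
        raise ValidationError("p25 must not exceed p90")
    if p90_months <= 0:
        return (math.inf, 0.0)
    if p25_months == p90_months:
        raise ValidationError("p25 and p90 must differ for a non-degenerate item")
    d25 = p25_months * DAYS_PER_MONTH
    d90 = p90_months * DAYS_PER_MONTH
    beta = (logit(0.9) - logit(0.25)) / (d90 - d25)
    alpha = logit(0.25) - beta * d25
    return (float(alpha), float(beta))


def _truth_curves(truth: NormsTable, instrument: Instrument):
    """(alpha, beta, p50_days) arrays per domain, in chart order."""
    curves = {}
    for dom in DOMAINS:
        items = instrument.domain_items(dom)
        alphas, betas, p50s = [], [], []
        for it in items:
            if it.item_code not in truth:
                raise ValidationError(f"truth norms lack item {it.item_code}")
            a, b = truth_to_logistic(
                truth.percentile_months(it.item_code, 25),
                truth.percentile_months(it.item_code, 90),
            )
            alphas.append(a)
            betas.append(b)
            p50s.append(0.0 if not math.isfinite(a) else -a / b)
        curves[dom] = (
            [it.item_code for it in items],
            np.array(alphas), np.array(betas), np.array(p50s),
        )
    return curves


def _pass_probs(alphas: np.ndarray, betas: np.ndarray, age_days: float) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        probs = expit(alphas + betas * age_days)
    probs[~np.isfinite(alphas)] = 1.0
    return probs


def _administer_domain(
    probs: np.ndarray, p50s: np.ndarray, age_days: float, rng,
    refusal_prob: float, no_opportunity_prob: float,
    administration: str = "chart",
) -> dict[int, str]:
    """Chart protocol: test around the age line until basal and ceiling found.

    With ``administration='full'`` every item is tested (no basal/ceiling),
    which keeps the tested set free of the protocol's age-selection effects —
    useful for calibration and recovery studies.
    """
    n = len(probs)
    if n == 0:
        return {}
    start = int(np.searchsorted(p50s, age_days, side="right")) - 1
    start = min(max(start, 0), n - 1)

    def draw(i: int) -> str:
        u = rng.random()
        if u < no_opportunity_prob:
            return "no_opportunity"
        if u < no_opportunity_prob + refusal_prob:
            return "refusal"
        return "tested_pass" if rng.random() < probs[i] else "tested_fail"

    if administration == "full":
        return {i: draw(i) for i in range(n)}

    tested: dict[int, str] = {}
    run = 0
    for i in range(start, -1, -1):  # leftward: find 3 consecutive passes
        res = draw(i)
        tested[i] = res
        if res == "tested_pass":
            run += 1
        elif res != "no_opportunity":
            run = 0
        if run >= 3:
            break
    run = 0
    for i in range(start + 1, n):   # rightward: find 3 consecutive fails
        res = draw(i)
        tested[i] = res
        if res in ("tested_fail", "refusal"):
            run += 1
        elif res != "no_opportunity":
            run = 0
        if run >= 3:
            break
    return tested


def _draw_z(rng, malnourished: bool) -> float:
    if malnourished:
        return float(rng.uniform(-3.2, -2.05))
    return float(np.clip(rng.normal(-0.3, 0.9), -1.85, 3.5))


def generate_cohort(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[list[ChildRecord], pd.DataFrame, dict]:
    """Roster + tester first-occasion responses + ground-truth labels."""
    truth, instrument, lms = config.resolve()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_children
    curves = _truth_curves(truth, instrument)

    # --- ages and identities -------------------------------------------------
    weights = (
        np.asarray(config.bin_weights, dtype=float)
        if config.bin_weights is not None
        else np.full(len(config.age_bins), 1.0 / len(config.age_bins))
    )
    bin_idx = rng.choice(len(config.age_bins), size=n, p=weights)
    ages_days = np.empty(n, dtype=int)
    for i, b in enumerate(bin_idx):
        lo, hi = config.age_bins[b]
        ages_days[i] = max(4, int(round(rng.uniform(lo, hi + 1) * DAYS_PER_MONTH)))
    sexes = np.where(rng.random(n) < 0.5, "male", "female")
    test_offsets = rng.integers(0, 160, size=n)

    # --- nutrition assignment (deterministic counts) -------------------------
    n_mal = int(round(config.malnourished_frac * n))
    n_unk = int(round(config.unknown_frac * n))
    if n_mal + n_unk > n:
        raise ValidationError("malnourished + unknown fractions exceed the cohort")
    order = rng.permutation(n)
    status = np.full(n, "normal", dtype=object)
    status[order[:n_mal]] = "malnourished"
    status[order[n_mal:n_mal + n_unk]] = "unknown"

    # --- rater pairing and reliability subsets -------------------------------
    pair = rng.integers(0, 5, size=n)
    n_obs = min(config.n_observer, n)
    obs_idx = set(rng.choice(n, size=n_obs, replace=False).tolist()) if n_obs else set()
    obs_list = sorted(obs_idx)
    n_retest = min(config.n_retest, len(obs_list))
    retest_idx = (
        set(rng.choice(obs_list, size=n_retest, replace=False).tolist())
        if n_retest else set()
    )

    mean_iv, sd_iv = config.retest_interval_days
    roster: list[ChildRecord] = []
    width = max(4, len(str(max(n, 1))))
    for i in range(n):
        test_date = _STUDY_START + dt.timedelta(days=int(test_offsets[i]))
        birth_date = test_date - dt.timedelta(days=int(ages_days[i]))
        weight = muac = None
        if status[i] != "unknown":
            z_w = _draw_z(rng, status[i] == "malnourished")
            z_m = float(np.clip(z_w + rng.normal(0, 0.3), -3.4, 3.5))
            if status[i] == "malnourished":
                z_m = min(z_m, -2.05)
            else:
                z_m = max(z_m, -1.85)
            muac_only = rng.random() < config.muac_only_frac
            if not muac_only:
                lw = lms.lookup("weight_for_age", str(sexes[i]), int(ages_days[i]))
                if lw is not None:
                    weight = round(lms_inverse(z_w, *lw), 3)
            lm = lms.lookup("muac_for_age", str(sexes[i]), int(ages_days[i]))
            if lm is not None:
                muac = round(lms_inverse(z_m, *lm), 3)
        retest_date = None
        if i in retest_idx:
            interval = max(7, int(round(rng.normal(mean_iv, sd_iv))))
            retest_date = test_date + dt.timedelta(days=interval)
        roster.append(ChildRecord(
            child_id=f"C{i + 1:0{width}d}",
            sex=str(sexes[i]),
            birth_date=birth_date,
            test_date=test_date,
            weight_kg=weight,
            muac_cm=muac,
            tester_id=f"N{2 * pair[i] + 1:02d}",
            observer_id=f"N{2 * pair[i] + 2:02d}" if i in obs_idx else None,
            retest_date=retest_date,
        ))

    # --- tester responses at the first occasion ------------------------------
    rows = []
    for i, child in enumerate(roster):
        age = ages_days[i]
        for dom in DOMAINS:
            codes, alphas, betas, p50s = curves[dom]
            probs = _pass_probs(alphas, betas, age)
            tested = _administer_domain(
                probs, p50s, age, rng, config.refusal_prob, config.no_opportunity_prob,
                administration=config.administration,
            )
            for j, res in sorted(tested.items()):
                rows.append((child.child_id, "test", "tester", codes[j], res))
    responses = pd.DataFrame(
        rows, columns=["child_id", "occasion", "rater_role", "item_code", "raw_result"]
    )

    truth_out = {
        "items": {
            code: {"alpha": a if math.isfinite(a) else None,
                   "beta": b,
                   "all_pass": not math.isfinite(a)}
            for dom in DOMAINS
            for code, a, b in zip(curves[dom][0], curves[dom][1], curves[dom][2])
        },
        "nutrition_status": {roster[i].child_id: str(status[i]) for i in range(n)},
        "seed": config.seed,
    }
    return roster, responses, truth_out


def add_rater_and_retest(
    roster: list[ChildRecord],
    responses: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Add observer copies (flip noise) and redrawn retest-occasion responses."""
    truth, instrument, _ = config.resolve()
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    curves = _truth_curves(truth, instrument)
    by_id = {c.child_id: c for c in roster}
    flip = config.rater_flip_prob

    new_rows = []
    tester_test = responses[
        (responses["occasion"] == "test") & (responses["rater_role"] == "tester")
    ]
    for row in tester_test.itertuples(index=False):
        child = by_id[row.child_id]
        if child.observer_id is None:
            continue
        res = row.raw_result
        if res in ("tested_pass", "tested_fail") and rng.random() < flip:
            res = "tested_fail" if res == "tested_pass" else "tested_pass"
        new_rows.append((row.child_id, "test", "observer", row.item_code, res))

    for child in roster:
        if child.retest_date is None:
            continue
        age = (child.retest_date - child.birth_date).days
        for dom in DOMAINS:
            codes, alphas, betas, p50s = curves[dom]
            probs = _pass_probs(alphas, betas, age)
            tested = _administer_domain(
                probs, p50s, age, rng, config.refusal_prob, config.no_opportunity_prob,
                administration=config.administration,
            )
            for j, res in sorted(tested.items()):
                if res in ("tested_pass", "tested_fail") and rng.random() < flip:
                    res = "tested_fail" if res == "tested_pass" else "tested_pass"
                new_rows.append((child.child_id, "retest", "tester", codes[j], res))

    extra = pd.DataFrame(
        new_rows, columns=["child_id", "occasion", "rater_role", "item_code", "raw_result"]
    )
    return pd.concat([responses, extra], ignore_index=True)


def generate_study(
    config: GeneratorConfig | None = None,
) -> tuple[list[ChildRecord], pd.DataFrame, dict]:
    """Full study emulation: cohort plus observer and retest occasions."""
    config = config if config is not None else GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    roster, responses, truth = generate_cohort(config, rng=rng)
    responses = add_rater_and_retest(roster, responses, config, rng=rng)
    return roster, responses, truth


def standardization_cohort() -> tuple[list[ChildRecord], pd.DataFrame, dict]:
    """The packaged standardization cohort (n = 1682, fixed seed).

    Generated programmatically rather than shipped as CSV; the exclusion
    accounting (83 malnourished, 2 unknown, 1597 retained) is exact by the
    generator's deterministic status counts.
    """
    return generate_study(GeneratorConfig(seed=20110111))
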