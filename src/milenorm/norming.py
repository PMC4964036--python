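"""Per-item age-of-attainment models and milestone-age derivation.

For every chart item a binary logistic regression of the tested pass/fail
outcome on age in days is fitted by maximum likelihood:

    logit P(pass | age) = alpha + beta * age_days

Calibration is checked with the Hosmer-Lemeshow statistic over deciles of
predicted risk; items whose plain fit is rejected at the 5% level are
refitted as a logistic model on a restricted cubic spline basis of age
(4 knots at the 5/35/65/95 age percentiles of the item's observations,
linear beyond the boundary knots). Milestone ages are the 25/50/75/90%
points of the fitted curve: closed-form inversion for the plain model,
smallest upward crossing found by bracketed root-finding for splines.

Items every tested child passed are reported as attained at birth; items
with too few usable observations, or only one outcome class for other
reasons, are left unfitted. Under complete separation the percentiles
collapse onto the separating age boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import chi2

from .instrument import DAYS_PER_MONTH, Instrument, NormsTable, ValidationError

logger = logging.getLogger(__name__)

#: minimum usable observations (with both outcome classes) to fit an item
MIN_N = 20

#: significance level of the Hosmer-Lemeshow refit gate
HL_ALPHA = 0.05

#: number of Hosmer-Lemeshow risk groups (df = groups - 2)
HL_GROUPS = 10

#: restricted-cubic-spline knot placement (percentiles of observed ages)
RCS_KNOT_QUANTILES = (0.05, 0.35, 0.65, 0.95)

MODEL_FORMS = (
    "plain_logistic", "spline_logistic", "unfitted_all_pass", "unfitted_degenerate",
)


@dataclass
class LogisticItemModel:
    item_code: str
    model_form: str
    alpha: float = float("nan")
    beta: float = float("nan")
    spline_knots: tuple[float, ...] = ()
    spline_coefs: tuple[float, ...] = ()
    n_used: int = 0
    converged: bool = False
    separation: bool = False
    separation_age: float = float("nan")
    age_range: tuple[float, float] = (0.0, 0.0)
    notes: list[str] = field(default_factory=list)

    def predict(self, ages_days) -> np.ndarray:
        """Fitted pass probability at the given ages (days)."""
        a = np.asarray(ages_days, dtype=float)
        if self.model_form == "unfitted_all_pass":
            return np.ones_like(a)
        if self.model_form == "plain_logistic":
            if self.separation:
                return (a >= self.separation_age).astype(float)
            return expit(self.alpha + self.beta * a)
        if self.model_form == "spline_logistic":
            X = rcs_basis(a, np.asarray(self.spline_knots))
            eta = self.alpha + X @ np.asarray(self.spline_coefs)
            return expit(eta)
        raise ValidationError(f"model for {self.item_code} is unfitted")


@dataclass
class FitDiagnostics:
    item_code: str
    hl_statistic: float
    hl_df: int
    hl_p: float
    refit_triggered: bool = False
    model_form: str = "plain_logistic"
    n_used: int = 0
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# plain logistic fit
# ---------------------------------------------------------------------------

def fit_logistic(
    ages_days, outcomes, item_code: str = "", min_n: int = MIN_N
) -> LogisticItemModel:
    """Maximum-likelihood logistic fit of pass/fail on age in days."""
    ages = np.asarray(ages_days, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if ages.shape != y.shape:
        raise ValidationError("ages and outcomes must have equal length")
    n = len(y)
    rng_lo, rng_hi = (float(ages.min()), float(ages.max())) if n else (0.0, 0.0)

    if n and y.min() == y.max():
        form = "unfitted_all_pass" if y[0] == 1 else "unfitted_degenerate"
        note = "all tested children passed" if y[0] == 1 else "all tested children failed"
        return LogisticItemModel(
            item_code=item_code, model_form=form, n_used=n,
            age_range=(rng_lo, rng_hi), notes=[note],
        )
    if n < min_n:
        return LogisticItemModel(
            item_code=item_code, model_form="unfitted_degenerate", n_used=n,
            age_range=(rng_lo, rng_hi), notes=[f"only {n} usable observations (< {min_n})"],
        )

    X = sm.add_constant(ages)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            alpha, beta = float(res.params[0]), float(res.params[1])
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception as exc:  # perfect separation raises in some versions
            logger.debug("logit fit failed for %s: %s", item_code, exc)
            alpha, beta, converged = float("nan"), float("nan"), False

    model = LogisticItemModel(
        item_code=item_code, model_form="plain_logistic", alpha=alpha, beta=beta,
        n_used=n, converged=converged, age_range=(rng_lo, rng_hi),
    )
    if _is_separated(ages, y) or not np.isfinite([alpha, beta]).all():
        model.separation = True
        model.converged = False
        model.separation_age = _separation_boundary(ages, y)
        model.notes.append("complete separation; percentiles at the separating boundary")
        logger.warning("item %s: complete separation on age", item_code or "<anon>")
    elif beta <= 0:
        # a developmental item whose fitted pass probability does not rise
        # with age carries no milestone information
        model.notes.append("non-positive fitted slope; milestone ages unattained")
    return model


def _is_separated(ages: np.ndarray, y: np.ndarray) -> bool:
    """True when a single age threshold splits passes from fails perfectly."""
    return float(np.max(ages[y == 0])) < float(np.min(ages[y == 1]))


def _separation_boundary(ages: np.ndarray, y: np.ndarray) -> float:
    return 0.5 * (float(np.max(ages[y == 0])) + float(np.min(ages[y == 1])))


# ---------------------------------------------------------------------------
# Hosmer-Lemeshow calibration gate
# ---------------------------------------------------------------------------

def hosmer_lemeshow(
    model: LogisticItemModel, ages_days, outcomes, groups: int = HL_GROUPS
) -> FitDiagnostics:
    """Calibration chi-square over `groups` groups of predicted risk.

    Groups are deciles of the fitted probabilities; tied probabilities that
    collapse group boundaries are merged (logged), reducing the degrees of
    freedom accordingly (df = effective groups - 2).
    """
    ages = np.asarray(ages_days, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if len(y) < groups:
        raise ValidationError("need at least `groups` observations for the HL test")
    p = model.predict(ages)

    edges = np.quantile(p, np.linspace(0, 1, groups + 1))
    edges = np.unique(edges)
    if len(edges) - 1 < groups:
        logger.debug("HL: tied risk deciles merged to %d groups", len(edges) - 1)
    # assign by interval; rightmost edge inclusive
    idx = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, len(edges) - 2)

    stat = 0.0
    g_eff = 0
    for g in range(len(edges) - 1):
        mask = idx == g
        n_g = int(mask.sum())
        if n_g == 0:
            continue
        g_eff += 1
        obs = float(y[mask].sum())
        exp = float(p[mask].sum())
        denom = exp * (1.0 - exp / n_g)
        if denom <= 1e-12:
            # group with all-certain predictions contributes 0 unless wrong
            if abs(obs - exp) > 1e-9:
                stat = float("inf")
            continue
        stat += (obs - exp) ** 2 / denom

    df = max(g_eff - 2, 1)
    p_value = float(chi2.sf(stat, df)) if np.isfinite(stat) else 0.0
    return FitDiagnostics(
        item_code=model.item_code, hl_statistic=float(stat), hl_df=df,
        hl_p=p_value, model_form=model.model_form, n_used=len(y),
    )


# ---------------------------------------------------------------------------
# restricted cubic spline refit
# ---------------------------------------------------------------------------

def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline basis (linear tails), Harrell normalization.

    With k knots t_1..t_k the basis has k-1 columns: x itself plus k-2
    truncated-cubic terms scaled by (t_k - t_1)^2.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    k = len(t)
    if k < 3:
        raise ValidationError("restricted cubic spline needs at least 3 knots")
    norm = (t[-1] - t[0]) ** 2
    cols = [x]

    def cube(u):
        return np.maximum(u, 0.0) ** 3

    for j in range(k - 2):
        term = (
            cube(x - t[j])
            - cube(x - t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
            + cube(x - t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2])
        )
        cols.append(term / norm)
    return np.column_stack(cols)


def spline_knots_for(ages: np.ndarray, quantiles=RCS_KNOT_QUANTILES) -> np.ndarray:
    knots = np.quantile(np.asarray(ages, dtype=float), quantiles)
    return np.unique(knots)


def refit_spline(
    ages_days, outcomes, item_code: str = "", knots=None
) -> LogisticItemModel:
    """Logistic fit on a restricted-cubic-spline basis of age."""
    ages = np.asarray(ages_days, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    t = np.asarray(knots, dtype=float) if knots is not None else spline_knots_for(ages)
    if len(t) < 3:
        raise ValidationError(f"item {item_code}: too few distinct knots for a spline")
    basis = rcs_basis(ages, t)
    dim = basis.shape[1] + 1
    if len(y) < dim:
        raise ValidationError(
            f"item {item_code}: {len(y)} observations cannot identify a {dim}-parameter spline"
        )
    X = sm.add_constant(basis)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=300)
            converged = bool(res.mle_retvals.get("converged", True))
            params = np.asarray(res.params, dtype=float)
        except Exception:
            converged, params = False, np.full(dim, np.nan)
    if not np.isfinite(params).all():
        converged = False
    model = LogisticItemModel(
        item_code=item_code, model_form="spline_logistic",
        alpha=float(params[0]) if converged else float("nan"),
        spline_knots=tuple(t),
        spline_coefs=tuple(params[1:]) if converged else (),
        n_used=len(y), converged=converged,
        age_range=(float(ages.min()), float(ages.max())),
    )
    if converged:
        grid = np.linspace(model.age_range[0], model.age_range[1], 200)
        probs = model.predict(grid)
        if np.any(np.diff(probs) < -1e-6):
            model.notes.append("fitted spline curve is non-monotone on the observed range")
    return model


# ---------------------------------------------------------------------------
# milestone-age inversion
# ---------------------------------------------------------------------------

def percentile_age(model: LogisticItemModel, p: float) -> float:
    """Age in days at which the fitted curve reaches pass probability p.

    Plain form: closed-form (logit(p) - alpha)/beta, clipped below at 0
    (birth). Spline form: smallest upward crossing of p on [0, max observed
    age], refined by bracketed root-finding. NaN when the curve never
    reaches p on the supported range (flagged unattained by the caller).
    """
    if not 0.0 < p < 1.0:
        raise ValidationError("percentile probability must lie in (0, 1)")
    if model.model_form == "unfitted_all_pass":
        return 0.0
    if model.model_form == "unfitted_degenerate":
        return float("nan")
    if model.model_form == "plain_logistic":
        if model.separation:
            return max(model.separation_age, 0.0)
        if not np.isfinite(model.beta) or model.beta <= 0:
            return float("nan")
        return max((logit(p) - model.alpha) / model.beta, 0.0)

    # spline: scan a fine grid for the first upward crossing
    hi = model.age_range[1]
    grid = np.linspace(0.0, hi, 2001)
    probs = model.predict(grid) - p
    if probs[0] >= 0:
        return 0.0
    crossing = np.nonzero((probs[:-1] < 0) & (probs[1:] >= 0))[0]
    if len(crossing) == 0:
        return float("nan")
    i = int(crossing[0])
    f = lambda a: float(model.predict(np.array([a]))[0]) - p
    try:
        return float(brentq(f, grid[i], grid[i + 1], xtol=1e-6))
    except ValueError:
        return float(grid[i + 1])


def milestone_months(model: LogisticItemModel) -> dict[str, float]:
    """The four milestone ages in months (NaN where unattained)."""
    out = {}
    for pct, p in ((25, 0.25), (50, 0.50), (75, 0.75), (90, 0.90)):
        days = percentile_age(model, p)
        out[f"p{pct}_months"] = days / DAYS_PER_MONTH if np.isfinite(days) else float("nan")
    return out


# ---------------------------------------------------------------------------
# whole-instrument norming
# ---------------------------------------------------------------------------

def fit_item(
    ages_days, outcomes, item_code: str = "", *,
    min_n: int = MIN_N, hl_alpha: float = HL_ALPHA, hl_groups: int = HL_GROUPS,
) -> tuple[LogisticItemModel, FitDiagnostics | None]:
    """Plain fit, HL gate, and spline refit when the gate rejects.

    When both the plain and the spline fit are available, the model with the
    better calibration diagnostic is kept (and still flagged when neither
    passes the gate).
    """
    model = fit_logistic(ages_days, outcomes, item_code=item_code, min_n=min_n)
    if model.model_form != "plain_logistic" or model.separation:
        return model, None
    diag = hosmer_lemeshow(model, ages_days, outcomes, groups=hl_groups)
    if diag.hl_p >= hl_alpha:
        return model, diag

    diag.refit_triggered = True
    try:
        spline = refit_spline(ages_days, outcomes, item_code=item_code)
    except ValidationError as exc:
        diag.notes.append(f"spline refit impossible: {exc}")
        return model, diag
    if not spline.converged:
        diag.notes.append("spline refit did not converge; plain fit kept")
        return model, diag
    sdiag = hosmer_lemeshow(spline, ages_days, outcomes, groups=hl_groups)
    sdiag.refit_triggered = True
    sdiag.notes = diag.notes + [f"plain-fit HL p = {diag.hl_p:.4g}"]
    if sdiag.hl_p > diag.hl_p:
        if sdiag.hl_p < hl_alpha:
            sdiag.notes.append("poor fit persists after spline refit")
        return spline, sdiag
    diag.notes.append(f"spline HL p = {sdiag.hl_p:.4g} no better; plain fit kept")
    return model, diag


def build_norms(
    instrument: Instrument,
    scored: pd.DataFrame,
    *,
    min_n: int = MIN_N,
    hl_alpha: float = HL_ALPHA,
    hl_groups: int = HL_GROUPS,
) -> tuple[NormsTable, list[FitDiagnostics], dict[str, LogisticItemModel]]:
    """Fit every item from a scored frame and assemble the norms table.

    `scored` is the long output of :func:`milenorm.scoring.score_cohort`
    (columns item_code, categorical, age_days); only tested pass/fail rows
    enter the fits — implied results are missing by construction. Items that
    cannot be fitted (too few observations, one outcome class other than
    all-pass) are excluded from the norms output and reported in the
    diagnostics.
    """
    usable = scored[scored["categorical"].isin(["pass", "fail"])]
    rows = {}
    diagnostics: list[FitDiagnostics] = []
    models: dict[str, LogisticItemModel] = {}
    for it in instrument.items:
        sub = usable[usable["item_code"] == it.item_code]
        ages = sub["age_days"].to_numpy(dtype=float)
        y = (sub["categorical"] == "pass").to_numpy(dtype=float)
        model, diag = fit_item(
            ages, y, item_code=it.item_code,
            min_n=min_n, hl_alpha=hl_alpha, hl_groups=hl_groups,
        )
        models[it.item_code] = model
        if diag is not None:
            diagnostics.append(diag)
        else:
            diagnostics.append(FitDiagnostics(
                item_code=it.item_code, hl_statistic=float("nan"), hl_df=0,
                hl_p=float("nan"), model_form=model.model_form,
                n_used=model.n_used, notes=list(model.notes),
            ))
        if model.model_form == "unfitted_degenerate":
            continue
        ms = milestone_months(model)
        if any(not np.isfinite(v) for v in ms.values()):
            diagnostics[-1].notes.append("percentile unattained on supported range")
            continue
        vals = [ms[c] for c in ("p25_months", "p50_months", "p75_months", "p90_months")]
        if any(b - a < -1e-6 for a, b in zip(vals, vals[1:])):
            diagnostics[-1].notes.append("non-monotone milestone ages; item not normed")
            continue
        ms = dict(zip(ms.keys(), np.maximum.accumulate(vals)))  # absorb float jitter
        rows[it.item_code] = {**ms, "flag": "similar"}
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "item_code"
    if frame.empty:
        frame = pd.DataFrame(
            columns=["p25_months", "p50_months", "p75_months", "p90_months", "flag"]
        )
        frame.index.name = "item_code"
    return NormsTable(frame), diagnostics, models
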