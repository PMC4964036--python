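# Methods

## The norming model

Every chart item is treated as a monotone developmental milestone. The
outcome entering the model is the *categorical* score — pass only for a
tested pass, fail for a tested fail or refusal — so implied results and
"no opportunity" never contribute information they do not carry; they are
missing. The covariate is exact age in days, computed as the calendar-day
difference between birth and test date. Days and months convert at
`DAYS_PER_MONTH = 365.25 / 12 = 30.4375` everywhere; ages are held in days
internally and rendered in months to one decimal only at reporting
boundaries.

The per-item fit is maximum-likelihood binary logistic regression
(statsmodels `Logit`). Special cases:

* every tested child passed → `unfitted_all_pass`; the item is reported as
  attained at birth (all four milestone ages 0);
* fewer than `MIN_N = 20` usable observations, or only the failing class
  present → `unfitted_degenerate`; the item is excluded from the norms
  output and listed in the diagnostics. The floor of 20 with both classes
  present is this package's choice; there is no canonical value;
* complete separation (an age threshold splits passes from fails perfectly)
  → the fit is flagged and all percentiles collapse onto the midpoint
  between the oldest fail and the youngest pass, with a warning;
* a converged fit with non-positive slope carries no milestone information
  (pass probability not rising with age); its percentiles are flagged
  unattained rather than inverted into decreasing "ages".

## Calibration gate and spline refit

Goodness of fit is the Hosmer–Lemeshow statistic over `g = 10` groups of
predicted risk, `df = g − 2`. Groups are decile bins of the fitted
probabilities; tied probabilities that collapse bin edges are merged, with
the degrees of freedom reduced accordingly (never below 1). The statistic
is Σ (O − E)² / (E·(1 − E/n_g)); a group whose predictions are all certain
contributes 0 unless contradicted. Simulation at the study scale puts the
gate's type-I rate slightly under the nominal 5 % (≈ 3.5–4 % at n = 400),
consistent with the test's known mild conservatism.

Items rejected at the 5 % level are refitted as a logistic model on a
restricted cubic spline basis of age: 4 knots at the 5/35/65/95 percentiles
of the item's observed ages (the standard Harrell placement and
normalization, linear beyond the boundary knots). A refit that does not
converge, or that does not improve the calibration p-value, is discarded
and the plain fit kept; when neither model passes the gate the
better-calibrated one is kept and flagged — the fitting report never
silently drops an item for poor calibration alone. Spline milestone ages
are the smallest upward crossing of the target probability on [0, max
observed age], located on a 2001-point grid and refined by Brent's method;
a non-monotone fitted curve is noted, and "earliest attainment" semantics
(first upward crossing) resolve any ambiguity. A curve that never reaches
the target probability on the supported range yields an unattained flag,
not an extrapolated age.

Milestone ages from the plain model satisfy the exact equal-spacing
identity (logit spacings −1.0986, 0, 1.0986, 2.1972 are equidistant);
the test suite uses this identity to distinguish plain from spline rows.
Percentiles are clipped at 0 and rendered "birth"-equivalent (0.0 months)
when the curve is already above the target at age zero.

## Screening, scoring, comparison, reliability

**Screening.** z-scores follow the LMS construction with the L → 0
logarithmic limit; reference parameters are linearly interpolated on the
age grid, and an age outside the grid yields a missing z-score. The
exclusion rule is exactly: malnourished iff WAZ ≤ −2, or MUACZ ≤ −2 *only
when* WAZ is unavailable (a present WAZ always decides); unknown iff
neither z-score is computable. No extreme-value restricted adjustment is
applied to |z| > 3 — the z-scores are plain LMS transforms, a documented
difference from growth-software pipelines that apply one. Prematurity age
correction is not implemented: at-risk children (including the premature)
are excluded by the eligibility screen, never age-adjusted.

**Scoring.** Implied-status resolution operates within a domain on chart
order: items left of the *leftmost* run of three consecutive tested passes
become implied passes, items right of the *rightmost* run of three
consecutive tested fails become implied fails; any qualifying run counts,
not only runs adjacent to the age line (the administration order is
validated but not enforced — data may arrive from any protocol, and a
tested result always beats an implied one). The performance ratio is
actual passes (tested + implied) over expected passes (items whose 75 %
milestone age is at or below the child's age); with nothing yet expected
the ratio is undefined — flagged, not zero — and such rows are excluded
from domain ICCs. Note that the ratio's population mean sits slightly
above 1 by construction: the numerator credits passes of items whose 50 %
age is below the child's age while the denominator counts only items past
their 75 % age. With the packaged norms the ideal-scoring domain means are
≈ 1.10–1.19, and the chart protocol realizes values a few percent below
that; the self-consistency test checks the simulated means against this
analytically computed ideal rather than against 1.

**Comparison.** The relative difference uses the reference age as the
denominator (the reference is the fixed standard); the 10 % threshold is
strict ("more than"), so exactly 10 % is similar, and the rule is
scale-invariant between days and months. A reference age of 0 with a
nonzero local age admits no relative difference and is flagged
incomparable.

**Reliability.** Kappa is the unweighted 2×2 form; a degenerate margin
(chance agreement 1) leaves kappa undefined and the percent agreement is
reported against the 70 % floor instead — mirroring how heavily skewed
items are handled in practice. Landis–Koch cutpoints are implemented as
half-open intervals (≤ 0.20 slight, (0.20, 0.40] fair, (0.40, 0.60]
moderate, (0.60, 0.80] substantial, (0.80, 1.00] excellent), closing the
0.20/0.21-style gaps the verbal convention leaves open. Kappa is known to
be unstable on low-prevalence items: a handful of discordant pairs on a
skewed table can drop an otherwise well-agreeing item several bands.
Domain ICCs are single-measure (one score per child is what downstream
decisions use): ICC(1,1) from one-way random-effects ANOVA for inter-rater
agreement, ICC(2,1) absolute-agreement from two-way random-effects ANOVA
for test–retest, with F-based 95 % CIs (Satterthwaite degrees of freedom
for the two-way form). Inter-rater agreement uses the first test occasion
only. Rows with missing measurements are dropped and counted; zero
between-subject variance reports ICC 0 with a warning note.

## The synthetic cohort generator

The generator emulates the standardization study's design, and its defaults
are those conditions: 1682 eligible children; equal quotas over the nine
design age bins (0–2 … 54–65 months; the real per-bin counts are
unpublished, equal quotas are this package's declared assumption), uniform
ages within a bin with a 4-day floor; 83 malnourished and 2 unknown-status
children assigned by deterministic rounding of the configured fractions, so
the exclusion accounting is exact at the default size; a 409-child
inter-rater subset, 147 of whom are retested after a mean 14 ± 2 day
interval; a 2 % per-item rater disagreement (flip) rate; 1 % refusal and
1 % no-opportunity rates per administered item.

Truth curves are inverted from a norms table using only the 25 % and 90 %
ages (β = 3.2958/Δdays, α anchored at the 25 % point); rows at birth
become all-pass items. Administration follows the chart: testing starts at
the age line (the last item whose truth 50 % age is below the child's age)
and proceeds left until three consecutive passes and right until three
consecutive fails are recorded, so implied-status resolution has realistic
work to do. An alternative `administration="full"` mode tests every item,
which frees calibration and recovery studies from the protocol's
age-selection effects. Anthropometry is drawn by inverting target z-scores
through the same LMS tables the screen uses (malnourished z ∈ [−3.2,
−2.05], normal z truncated above −1.85), with a 3 % MUAC-only subset
exercising the WAZ-missing fallback.

What the generator deliberately does **not** emulate: children have no
latent ability — item outcomes are independent given age, the simplest
structure consistent with the per-item marginal model. Two consequences
follow. Inter-rater statistics behave realistically (the observer sees the
same outcomes through flip noise), but *test–retest* agreement is a lower
bound: retest outcomes are redrawn independently from the (older-age)
truth curve plus flip noise, so items near a child's transition zone
re-randomize and test–retest kappa/ICC sit far below what stable real
children produce. Passing reliability tests therefore demonstrates the
statistics are computed correctly, not that real-world retest reliability
would be high. Likewise domain-score ICCs are driven only by binomial
variation around the age trend, not by true between-child spread.
Ground-truth labels (curve parameters, nutrition status) are emitted
alongside the data for recovery tests and are never read by the pipeline.

## Packaged fixtures

Two instrument editions ship: the 126-item standardization-era chart
(including the later-dropped toilet-going item PS26) and the final 125-item
chart with 36 adapted items (17 PS, 10 FM, 8 LA, 1 GM). The norms fixture
carries all 126 rows with their similar/earlier/later flags at the 90 %
age; summaries over the final instrument give 42 differing items (15
earlier, 27 later) and 83 similar. One row's 50 % age (GM3) was
regularized to 2.0 months to satisfy the percentile-monotonicity invariant
every norms table must obey, and a few cells deliberately retain a decimal
comma to exercise the reader's dialect tolerance. Culture-specific flags
beyond the adapted set are a synthetic assignment padding each domain to
its documented count (20/18/15/2) — the item-level membership is not
published. The LMS tables are synthetic smooth curves (so are the roster
and responses produced by the generator); they exist to make the machinery
testable and are not WHO reference values — real tables plug in through
the same CSV schema.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline at the
study scale (n = 1682 → 1597 after screening, 126 items), the estimator
bias study at 200 replicates of a 10-item subset at n = 1597, and the
calibration study of the refit gate at 500 replicates of n = 400 — sizes
chosen so each check is statistically informative at interactive runtimes.
Stochastic assertions use fixed seeds and binomial (3σ) tolerances.
Recovery of the 90 % age is weakest for items whose milestone ages lie
near birth (tiny denominators make relative error unstable) and beyond the
oldest sampled age (pure extrapolation); both situations are visible in
the diagnostics rather than hidden.
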