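"""Agreement statistics against hand-computed and library oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import milenorm as mn
from milenorm.instrument import ValidationError
from milenorm.reliability import (
    AgreementTable,
    agreement_table_from_pairs,
    band_frequency,
    cohen_kappa,
    icc,
    landis_koch_band,
    percent_agreement,
    reliability_report,
)


class TestPercentAgreement:
    def test_seventy_percent_boundary_acceptable(self):
        k = cohen_kappa(AgreementTable(4, 2, 1, 3))
        assert k.pct_agreement == pytest.approx(70.0)
        assert k.acceptable_agreement

    def test_perfect(self):
        assert percent_agreement(AgreementTable(5, 0, 0, 5)) == 100.0

    def test_hand_value(self):
        assert percent_agreement(AgreementTable(40, 5, 10, 45)) == 85.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            percent_agreement(AgreementTable(0, 0, 0, 0))


class TestCohenKappa:
    def test_hand_arithmetic_oracle(self):
        k = cohen_kappa(AgreementTable(40, 5, 10, 45))
        assert k.po == pytest.approx(0.85)
        assert k.pe == pytest.approx(0.50)
        assert k.kappa == pytest.approx(0.70, abs=1e-12)
        assert k.band == "substantial"

    def test_against_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(4)
        a = rng.integers(0, 2, 200)
        flip = rng.random(200) < 0.2
        b = np.where(flip, 1 - a, a)
        table = AgreementTable(
            int(((a == 1) & (b == 1)).sum()), int(((a == 1) & (b == 0)).sum()),
            int(((a == 0) & (b == 1)).sum()), int(((a == 0) & (b == 0)).sum()),
        )
        assert cohen_kappa(table).kappa == pytest.approx(
            cohen_kappa_score(a, b), abs=1e-12
        )

    def test_perfect_diagonal(self):
        k = cohen_kappa(AgreementTable(30, 0, 0, 20))
        assert k.kappa == 1.0 and k.band == "excellent"

    def test_degenerate_margin_undefined_but_agreement_reported(self):
        k = cohen_kappa(AgreementTable(50, 0, 0, 0))
        assert k.kappa is None and k.band == "undefined"
        assert k.pct_agreement == 100.0 and k.acceptable_agreement

    @settings(max_examples=200, deadline=None)
    @given(st.tuples(*[st.integers(min_value=0, max_value=50)] * 4))
    def test_kappa_never_exceeds_observed_agreement(self, counts):
        a, b, c, d = counts
        if a + b + c + d == 0:
            return
        k = cohen_kappa(AgreementTable(a, b, c, d))
        if k.kappa is not None:
            assert k.kappa <= k.po + 1e-12
            assert (k.kappa == pytest.approx(1.0)) == (b == 0 and c == 0)


class TestLandisKochBands:
    @pytest.mark.parametrize("kappa,band", [
        (0.15, "slight"), (-0.2, "slight"), (0.20, "slight"), (0.21, "fair"),
        (0.40, "fair"), (0.41, "moderate"), (0.60, "moderate"), (0.74, "substantial"),
        (0.80, "substantial"), (0.81, "excellent"), (1.0, "excellent"),
        (None, "undefined"),
    ])
    def test_cutpoints(self, kappa, band):
        assert landis_koch_band(kappa) == band


def anova_oracle(x):
    """Brute-force ANOVA decomposition for ICC cross-checking."""
    n, k = x.shape
    grand = x.mean()
    bms = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    wms = ((x - x.mean(axis=1, keepdims=True)) ** 2).sum() / (n * (k - 1))
    jms = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    ems = (((x - grand) ** 2).sum()
           - (n - 1) * bms - (k - 1) * jms) / ((n - 1) * (k - 1))
    icc1 = (bms - wms) / (bms + (k - 1) * wms)
    icc2 = (bms - ems) / (bms + (k - 1) * ems + k * (jms - ems) / n)
    return icc1, icc2


class TestIcc:
    def test_identical_columns_give_one(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        assert icc(x, "oneway_random").icc == 1.0
        assert icc(x, "twoway_random").icc == 1.0

    def test_constant_column_shift_penalized(self):
        x = np.column_stack([np.arange(10.0), np.arange(10.0) + 2.0])
        one = icc(x, "oneway_random")
        two = icc(x, "twoway_random")
        o1, o2 = anova_oracle(x)
        assert one.icc == pytest.approx(o1, abs=1e-10)
        assert two.icc == pytest.approx(o2, abs=1e-10)
        assert one.icc < 1.0 and two.icc < 1.0

    def test_random_matrix_matches_anova_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(6, 2))
        o1, o2 = anova_oracle(x)
        assert icc(x, "oneway_random").icc == pytest.approx(o1, abs=1e-10)
        assert icc(x, "twoway_random").icc == pytest.approx(o2, abs=1e-10)

    def test_matches_pingouin_estimates_and_cis(self):
        import pingouin as pg

        rng = np.random.default_rng(8)
        x = rng.normal(size=(15, 3)) + rng.normal(size=(15, 1))
        long = pd.DataFrame({
            "s": np.repeat(np.arange(15), 3),
            "r": np.tile(np.arange(3), 15),
            "y": x.ravel(),
        })
        ref = pg.intraclass_corr(long, targets="s", raters="r", ratings="y").set_index("Type")
        for icc_type, name in (("oneway_random", "ICC(1,1)"), ("twoway_random", "ICC(A,1)")):
            got = icc(x, icc_type)
            assert got.icc == pytest.approx(ref.loc[name, "ICC"], abs=1e-10)
            lo, hi = ref.loc[name, "CI95"]
            assert got.ci95[0] == pytest.approx(lo, abs=5e-3)
            assert got.ci95[1] == pytest.approx(hi, abs=5e-3)

    def test_variance_components_recovery(self):
        """One-way ICC estimates sigma_s^2 / (sigma_s^2 + sigma_e^2)."""
        rng = np.random.default_rng(12)
        sigma_s, sigma_e = 2.0, 1.0
        truth = sigma_s**2 / (sigma_s**2 + sigma_e**2)
        x = sigma_s * rng.normal(size=(800, 1)) + sigma_e * rng.normal(size=(800, 2))
        assert icc(x, "oneway_random").icc == pytest.approx(truth, abs=0.05)

    def test_zero_between_subject_variance_reports_zero(self):
        x = np.array([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])
        res = icc(x, "twoway_random")
        assert res.icc == 0.0
        assert any("zero between-subject" in n for n in res.notes)

    def test_rows_with_missing_dropped_and_noted(self):
        x = np.array([[1.0, 1.1], [2.0, np.nan], [3.0, 3.1], [4.0, 3.9]])
        res = icc(x, "oneway_random")
        assert res.n_subjects == 3
        assert any("dropped 1" in n for n in res.notes)


class TestReliabilityReport:
    def test_zero_noise_raters_perfect(self, jimma_norms, std_instrument):
        cfg = mn.GeneratorConfig(
            n_children=200, seed=5, rater_flip_prob=0.0, n_observer=200,
            n_retest=0, malnourished_frac=0, unknown_frac=0,
            refusal_prob=0, no_opportunity_prob=0,
        )
        roster, resp, _ = mn.generate_study(cfg)
        scored, scores = mn.score_cohort(std_instrument, jimma_norms, roster, resp)
        oscored, oscores = mn.score_cohort(
            std_instrument, jimma_norms, roster, resp, rater_role="observer"
        )
        rep = reliability_report(
            tester_test_scored=scored, tester_test_scores=scores,
            observer_test_scored=oscored, observer_test_scores=oscores,
            tester_retest_scored=None, tester_retest_scores=None,
            instrument=std_instrument,
        )
        sec = rep["inter_rater"]
        kappas = [v for v in sec["kappa_by_item"].values() if v is not None]
        assert kappas and all(k == pytest.approx(1.0) for k in kappas)
        for dom_res in sec["icc_by_domain"].values():
            assert dom_res["icc"] == pytest.approx(1.0)

    def test_band_counts_sum_to_items_with_pairs(self, small_cohort, jimma_norms,
                                                 std_instrument):
        _, roster, resp, _ = small_cohort
        scored, scores = mn.score_cohort(std_instrument, jimma_norms, roster, resp)
        oscored, oscores = mn.score_cohort(
            std_instrument, jimma_norms, roster, resp, rater_role="observer"
        )
        rep = reliability_report(
            tester_test_scored=scored, tester_test_scores=scores,
            observer_test_scored=oscored, observer_test_scores=oscores,
            tester_retest_scored=None, tester_retest_scores=None,
            instrument=std_instrument, min_pairs=5,
        )
        sec = rep["inter_rater"]
        assert (
            sum(sec["band_frequency"].values())
            == sec["n_items_computed"] + sec["n_items_undefined"]
        )
        assert sec["n_items_computed"] + sec["n_items_undefined"] + len(
            sec["items_omitted_no_pairs"]
        ) == len(std_instrument)

    def test_no_paired_occasion_rejected(self, std_instrument):
        empty = pd.DataFrame(columns=["child_id", "item_code", "categorical",
                                      "domain", "status", "age_days"])
        with pytest.raises(ValidationError, match="paired"):
            reliability_report(
                tester_test_scored=empty, tester_test_scores=empty,
                observer_test_scored=None, observer_test_scores=None,
                tester_retest_scored=None, tester_retest_scores=None,
                instrument=std_instrument,
            )


class TestAgreementTableFromPairs:
    def test_missing_pairs_dropped(self):
        a = pd.Series(["pass", "fail", "missing", "pass"], index=list("wxyz"))
        b = pd.Series(["pass", "pass", "pass", "fail"], index=list("wxyz"))
        t = agreement_table_from_pairs(a, b)
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 0)

    def test_band_frequency_keys(self):
        assert set(band_frequency([])) == {
            "slight", "fair", "moderate", "substantial", "excellent", "undefined"
        }
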