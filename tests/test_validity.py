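"""Content-validity index and diagnostic-accuracy statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crece import (
    ContingencyTable,
    RiskCategory,
    ValidityError,
    build_contingency,
    chi_square_independence,
    compute_cvi,
    diagnostic_accuracy,
)

LOW, MOD, HIGH = RiskCategory.LOW, RiskCategory.MODERATE, RiskCategory.HIGH


def panel(n_experts, n_good, item_id="Q1"):
    """Long-form ratings: n_good experts rate 3-4, the rest rate 1-2, on
    every dimension."""
    rows = []
    for e in range(n_experts):
        for d in ("relevancy", "clarity", "simplicity"):
            rows.append(
                {
                    "item_id": item_id,
                    "expert_id": f"e{e}",
                    "dimension": d,
                    "rating": 4 if e < n_good else 2,
                }
            )
    return pd.DataFrame(rows)


class TestComputeCVI:
    def test_unanimous_panel_accepts(self, unanimous_panel):
        rep = compute_cvi(unanimous_panel)
        assert rep.loc[0, "combined_cvi"] == 1.0
        assert rep.loc[0, "decision"] == "accept"

    def test_three_quarters_revises(self):
        rep = compute_cvi(panel(8, 6))
        assert rep.loc[0, "combined_cvi"] == pytest.approx(0.75)
        assert rep.loc[0, "decision"] == "revise"

    def test_four_of_seven_eliminates(self):
        rep = compute_cvi(panel(7, 4))
        assert rep.loc[0, "combined_cvi"] == pytest.approx(4 / 7)
        assert rep.loc[0, "decision"] == "eliminate"

    def test_per_dimension_values_reported(self):
        tab = panel(5, 5)
        # degrade clarity only: 2 of 5 experts rate clarity low
        mask = (tab["dimension"] == "clarity") & tab["expert_id"].isin(["e0", "e1"])
        tab.loc[mask, "rating"] = 1
        rep = compute_cvi(tab)
        assert rep.loc[0, "cvi_relevancy"] == 1.0
        assert rep.loc[0, "cvi_clarity"] == pytest.approx(0.6)
        assert rep.loc[0, "combined_cvi"] == pytest.approx((1 + 0.6 + 1) / 3)

    def test_single_expert_rejected(self):
        with pytest.raises(ValidityError, match="2 experts"):
            compute_cvi(panel(1, 1))

    def test_out_of_scale_rating_rejected(self):
        tab = panel(3, 3)
        tab.loc[0, "rating"] = 5
        with pytest.raises(ValidityError):
            compute_cvi(tab)


class TestBuildContingency:
    def test_published_pairs_collapse_to_printed_cells(self, published_table):
        t = published_table
        assert (t.tn, t.fn, t.fp, t.tp) == (22, 1, 5, 11)
        assert t.n == 39

    def test_perfect_agreement_all_low(self):
        t = build_contingency([(LOW, LOW)] * 7)
        assert (t.tn, t.fn, t.fp, t.tp) == (7, 0, 0, 0)

    def test_high_maps_positive_on_both_axes(self):
        t = build_contingency([(HIGH, HIGH)])
        assert t.tp == 1 and t.n == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValidityError):
            build_contingency([])

    def test_collapse_commutes_with_counting(self):
        """Collapsing categories before counting equals counting 3x3 then
        collapsing."""
        rng = np.random.default_rng(42)
        cats = [LOW, MOD, HIGH]
        pairs = [
            (cats[i], cats[j])
            for i, j in zip(rng.integers(0, 3, 200), rng.integers(0, 3, 200))
        ]
        t = build_contingency(pairs)
        sign = lambda c: "negative" if c is LOW else "positive"
        direct = {
            (s, r): sum(1 for a, b in pairs if sign(a) == s and sign(b) == r)
            for s in ("negative", "positive")
            for r in ("negative", "positive")
        }
        assert direct[("positive", "positive")] == t.tp
        assert direct[("positive", "negative")] == t.fp
        assert direct[("negative", "positive")] == t.fn
        assert direct[("negative", "negative")] == t.tn


class TestDiagnosticAccuracy:
    def test_published_table_metrics(self, published_table):
        rep = diagnostic_accuracy(published_table)
        assert rep.sensitivity.value == pytest.approx(91.67, abs=0.005)
        assert rep.specificity.value == pytest.approx(81.48, abs=0.005)
        assert rep.ppv.value == pytest.approx(68.75, abs=1e-9)
        assert rep.ppv.rounded == 69
        assert rep.npv.value == pytest.approx(95.65, abs=0.005)
        assert rep.npv.rounded == 96

    def test_published_table_wald_ses(self, published_table):
        rep = diagnostic_accuracy(published_table)
        # computed Wald SEs, in percentage points
        assert rep.sensitivity.se == pytest.approx(7.98, abs=0.005)
        assert rep.specificity.se == pytest.approx(7.48, abs=0.005)

    def test_perfect_screen_scores_100_everywhere(self):
        rep = diagnostic_accuracy(ContingencyTable.from_cells(tp=9, fp=0, fn=0, tn=13))
        assert [m.value for m in rep.metrics] == [100.0] * 4

    def test_zero_denominator_reported_undefined_not_zero(self):
        rep = diagnostic_accuracy(ContingencyTable.from_cells(tp=0, fp=0, fn=0, tn=12))
        assert not rep.sensitivity.defined
        assert math.isnan(rep.sensitivity.value)
        assert rep.specificity.value == 100.0

    def test_random_tables_match_independent_arithmetic(self):
        """1000 random tables agree with naive quotient arithmetic to
        1e-12 on the proportion scale."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            tp, fp, fn, tn = (int(v) for v in rng.integers(1, 60, 4))
            rep = diagnostic_accuracy(ContingencyTable.from_cells(tp=tp, fp=fp, fn=fn, tn=tn))
            oracle = {
                "sensitivity": tp / (tp + fn),
                "specificity": tn / (tn + fp),
                "ppv": tp / (tp + fp),
                "npv": tn / (tn + fn),
            }
            for m in rep.metrics:
                assert abs(m.value / 100.0 - oracle[m.name]) < 1e-12

    def test_monotone_in_correct_cells(self):
        base = dict(tp=8, fp=4, fn=3, tn=10)
        rep0 = diagnostic_accuracy(ContingencyTable.from_cells(**base))
        rep_tp = diagnostic_accuracy(ContingencyTable.from_cells(**{**base, "tp": 12}))
        rep_tn = diagnostic_accuracy(ContingencyTable.from_cells(**{**base, "tn": 15}))
        assert rep_tp.sensitivity.value >= rep0.sensitivity.value
        assert rep_tp.npv.value >= rep0.npv.value  # fixed fn, more tp -> same; >= holds
        assert rep_tn.specificity.value >= rep0.specificity.value
        assert rep_tn.ppv.value >= rep0.ppv.value

    def test_clopper_pearson_interval_contains_wald_point(self, published_table):
        rep = diagnostic_accuracy(published_table)
        lo, hi = rep.sensitivity.interval("clopper-pearson")
        assert lo < rep.sensitivity.value < hi


def closed_form_chi2(tp, fp, fn, tn, yates=False):
    """Independent closed-form 2x2 chi-square."""
    n = tp + fp + fn + tn
    det = abs(tp * tn - fp * fn)
    if yates:
        det = max(0.0, det - n / 2)
    denom = (tp + fp) * (fn + tn) * (tp + fn) * (fp + tn)
    return n * det**2 / denom


class TestChiSquare:
    def test_published_table_uncorrected(self, published_table):
        with pytest.warns(UserWarning, match="expected cell"):
            stat, p = chi_square_independence(published_table)
        assert stat == pytest.approx(closed_form_chi2(11, 5, 1, 22), abs=1e-9)
        assert stat == pytest.approx(18.37, abs=0.005)
        assert p < 0.0001

    def test_published_table_yates_smaller_but_still_significant(self, published_table):
        with pytest.warns(UserWarning):
            stat_u, _ = chi_square_independence(published_table, "none")
            stat_y, p_y = chi_square_independence(published_table, "yates")
        assert stat_y == pytest.approx(closed_form_chi2(11, 5, 1, 22, yates=True), abs=1e-9)
        assert stat_y < stat_u
        assert p_y < 0.0001

    def test_exact_independence_gives_zero(self):
        stat, p = chi_square_independence(ContingencyTable.from_cells(tp=8, fp=8, fn=8, tn=8))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_observed_minus_expected_form(self):
        """The product formula agrees with sum over cells of (O-E)^2/E."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            tp, fp, fn, tn = (int(v) for v in rng.integers(1, 40, 4))
            obs = np.array([[tp, fp], [fn, tn]], dtype=float)
            expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
            oe_form = ((obs - expected) ** 2 / expected).sum()
            assert closed_form_chi2(tp, fp, fn, tn) == pytest.approx(oe_form, abs=1e-9)
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                stat, _ = chi_square_independence(
                    ContingencyTable.from_cells(tp=tp, fp=fp, fn=fn, tn=tn)
                )
            assert stat == pytest.approx(oe_form, abs=1e-9)

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValidityError, match="margin"):
            chi_square_independence(ContingencyTable.from_cells(tp=0, fp=0, fn=3, tn=9))

    def test_p_value_is_chi2_survival_at_1_df(self, published_table):
        with pytest.warns(UserWarning):
            stat, p = chi_square_independence(published_table)
        assert p == pytest.approx(stats.chi2.sf(stat, df=1), rel=1e-12)
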