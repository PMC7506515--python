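"""Validation statistics: review-count arithmetic, exact CIs, bands, AUC, kappa."""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ciedwatch.emr import ReviewLabel
from ciedwatch.evaluation import (
    band_table,
    cohen_kappa,
    confusion_metrics,
    infection_summary,
    mann_whitney_auc,
    metrics_from_counts,
    pct,
    roc_auc,
)


def brute_force_auc(scores, labels):
    """All-pairs enumeration: concordant pairs + half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p, n in product(pos, neg):
        total += 1.0 if p > n else 0.5 if p == n else 0.0
    return total / (len(pos) * len(neg))


class TestConfusionMetrics:
    @pytest.mark.parametrize("tp,fp,fn,tn,ppv,sens,spec", [
        # development-style review counts
        (41, 58, 6, 276, 41.4, 87.2, 82.6),
        # validation-style review counts
        (101, 131, 6, 125, 43.5, 94.4, 48.8),
    ])
    def test_partial_verification_arithmetic(self, tp, fp, fn, tn,
                                             ppv, sens, spec):
        m = metrics_from_counts(tp, fp, fn, tn)
        assert pct(m.ppv.value) == ppv
        assert pct(m.sensitivity.value) == sens
        assert pct(m.specificity.value) == spec
        assert m.reviewed == tp + fp + fn + tn

    def test_perfect_classifier(self):
        m = metrics_from_counts(tp=10, fp=0, fn=0, tn=20)
        assert (m.ppv.value, m.sensitivity.value, m.specificity.value) \
            == (1.0, 1.0, 1.0)

    def test_zero_denominator_reported_as_undefined(self):
        m = metrics_from_counts(tp=0, fp=0, fn=0, tn=5)
        assert not m.ppv.defined and not m.sensitivity.defined
        assert m.specificity.value == 1.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(k=st.integers(0, 50), n=st.integers(1, 50))
    def test_clopper_pearson_interval_contains_point_estimate(self, k, n):
        from ciedwatch.evaluation import Proportion
        p = Proportion(min(k, n), n)
        assert p.ci_low - 1e-12 <= p.value <= p.ci_high + 1e-12

    def test_only_reviewed_cases_enter_the_table(self):
        labels = [ReviewLabel(procedure_id=f"p{i}", reviewed=True,
                              infection=(i == 0),
                              infection_type="pocket" if i == 0 else "none",
                              onset_day=10 if i == 0 else None)
                  for i in range(4)]
        frame = pd.DataFrame({
            "procedure_id": [f"p{i}" for i in range(4)],
            "probability": [0.9, 0.9, 0.01, 0.01],
            "above_threshold": [True, True, False, False],
            "selected_for_review": [True, True, True, False],
        })
        m = confusion_metrics(labels, frame)
        assert (m.tp, m.fp, m.fn, m.tn) == (1, 1, 0, 1)


class TestBandTable:
    def band_fixture(self):
        # 39 reviewed / 28 infections planted in the top band
        probs = [0.995] * 100 + [0.2] * 150 + [0.001] * 750
        reviewed = [True] * 39 + [False] * 61 + [True] * 60 + [False] * 90 \
            + [True] * 100 + [False] * 650
        infected = [True] * 28 + [False] * (100 - 28) + [True] * 13 \
            + [False] * 137 + [True] * 1 + [False] * 749
        return probs, reviewed, infected

    def test_top_band_ppv(self):
        probs, reviewed, infected = self.band_fixture()
        table = band_table(probs, reviewed, infected)
        top = table.iloc[-1]
        assert top["band"] == "50%-100%"
        assert top["reviewed_n"] == 39
        assert top["infections_n"] == 28
        assert top["ppv_pct"] == 71.8

    def test_conservation(self):
        probs, reviewed, infected = self.band_fixture()
        table = band_table(probs, reviewed, infected)
        assert table["cohort_n"].sum() == len(probs)
        assert table["reviewed_n"].sum() == sum(reviewed)
        assert table["infections_n"].sum() == sum(
            r and i for r, i in zip(reviewed, infected))

    def test_all_zero_probabilities_fall_in_lowest_band(self):
        table = band_table([0.0] * 10, [False] * 10, [False] * 10)
        assert table.iloc[0]["cohort_n"] == 10
        assert table["cohort_n"].iloc[1:].sum() == 0

    def test_probability_one_lands_in_top_closed_band(self):
        table = band_table([1.0], [False], [False])
        assert table.iloc[-1]["cohort_n"] == 1

    def test_unsorted_edges_rejected(self):
        with pytest.raises(ValueError):
            band_table([0.5], [False], [False], band_edges=[0, 0.5, 0.5, 1])


class TestAuc:
    def test_perfect_separation_gives_one(self):
        _, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError):
            mann_whitney_auc([0.1, 0.9], [1, 1])

    def test_uninformative_scores_near_half(self):
        rng = np.random.default_rng(6)
        scores = rng.random(2000)
        labels = rng.integers(0, 2, 2000)
        auc = mann_whitney_auc(scores, labels)
        n1, n0 = labels.sum(), (1 - labels).sum()
        se = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
        assert abs(auc - 0.5) < 3 * se

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_equals_all_pairs_enumeration(self, data):
        n = data.draw(st.integers(2, 50))
        labels = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
        if not (any(labels) and not all(labels)):
            labels[0], labels[1] = True, False
        scores = data.draw(st.lists(
            st.floats(0, 1, allow_nan=False).map(lambda x: round(x, 2)),
            min_size=n, max_size=n))
        assert mann_whitney_auc(scores, labels) \
            == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_roc_curve_spans_unit_square(self):
        rng = np.random.default_rng(3)
        scores = rng.random(200)
        labels = (rng.random(200) < scores).astype(int)
        curve, auc = roc_auc(scores, labels)
        assert curve["fpr"].iloc[-1] == 1.0 and curve["tpr"].iloc[-1] == 1.0
        assert 0.5 < auc <= 1.0


class TestKappa:
    def test_identical_nonconstant_vectors(self):
        assert cohen_kappa([0, 1, 0, 1], [0, 1, 0, 1]) == 1.0

    def test_hand_computed_two_by_two(self):
        # agreement table a=40, b=5, c=5, d=50:
        # po = 0.90, pe = 0.505, kappa = 0.395/0.495
        a = [1] * 45 + [0] * 55
        b = [1] * 40 + [0] * 5 + [1] * 5 + [0] * 50
        assert cohen_kappa(a, b) == pytest.approx(0.395 / 0.495, abs=1e-12)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(12)
        a = rng.integers(0, 2, 5000)
        b = rng.integers(0, 2, 5000)
        assert abs(cohen_kappa(a, b)) < 3 / np.sqrt(5000)

    def test_identical_constant_raters_convention(self):
        assert cohen_kappa([1, 1, 1], [1, 1, 1]) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cohen_kappa([1, 0], [1])


class TestInfectionSummary:
    def label(self, i, itype, onset=None):
        return ReviewLabel(procedure_id=f"p{i}", reviewed=True,
                           infection=itype != "none", infection_type=itype,
                           onset_day=onset)

    def test_type_shares(self):
        labels = ([self.label(i, "pocket", 30) for i in range(128)]
                  + [self.label(200 + i, "endocarditis_or_lead", 40)
                     for i in range(23)]
                  + [self.label(300 + i, "cellulitis_only", 33)
                     for i in range(3)])
        table = infection_summary(labels).set_index("infection_type")
        assert table.loc["pocket", "percent"] == 83.1
        assert table.loc["endocarditis_or_lead", "percent"] == 14.9
        assert table["count"].sum() == 154

    def test_single_infection_sd_undefined(self):
        table = infection_summary([self.label(0, "pocket", 12)])
        row = table.set_index("infection_type").loc["pocket"]
        assert row["count"] == 1 and np.isnan(row["onset_sd_d"])

    def test_empty_label_set(self):
        table = infection_summary([])
        assert table["count"].sum() == 0
        assert np.isnan(table["percent"]).all()


def test_half_up_rounding_of_percentages():
    assert pct(0.41414) == 41.4
    assert pct(0.1235) == 12.4  # ties round away from zero, not to even
    assert pct(0.5) == 50.0
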