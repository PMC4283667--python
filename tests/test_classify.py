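"""Count-score classifier: scoring, aggregation, ROC/AUC, metrics, search."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afipanel import (
    MARKERS,
    PanelDefinition,
    aggregate_cohort,
    aggregate_patient,
    choose_cutoff,
    diagnostic_metrics,
    exhaustive_panel_search,
    generate_cohort,
    panel_score,
    panel_scores,
    roc_auc,
)
from afipanel.classify import enumerate_panels

from conftest import make_biopsy_row, planted_params

PANEL3 = PanelDefinition(members=("p53_IHC", "cyclinA_IHC", "aneuploidy"), cutoff=2)


class TestPanelScore:
    def test_two_of_three_is_high_risk_at_cutoff_two(self):
        markers = {"p53_IHC": "positive", "cyclinA_IHC": "positive", "aneuploidy": "negative"}
        score = panel_score(markers, PANEL3)
        assert score == 2 and score >= PANEL3.cutoff

    def test_all_negative_scores_zero(self):
        assert panel_score({m: 0.0 for m in PANEL3.members}, PANEL3) == 0

    def test_missing_member_is_undetermined_by_default(self):
        markers = {"p53_IHC": 1.0, "cyclinA_IHC": np.nan, "aneuploidy": 1.0}
        assert panel_score(markers, PANEL3) is None
        assert panel_score(markers, PANEL3, missing_policy="count-observed") == 2

    def test_vectorised_scores_match_scalar(self):
        df = pd.DataFrame(
            {"p53_IHC": [1, 0, 1], "cyclinA_IHC": [1, np.nan, 0], "aneuploidy": [0, 1, 1]}
        )
        v = panel_scores(df, PANEL3)
        assert v[0] == 2 and np.isnan(v[1]) and v[2] == 2


class TestAggregatePatient:
    def test_any_positive_rule_over_afi_pos_biopsies(self):
        rows = [
            make_biopsy_row("p1", "a1", "AFI+", "HGD", aneuploidy=0.0),
            make_biopsy_row("p1", "a2", "AFI+", "NDBO", aneuploidy=1.0),
        ]
        calls = aggregate_patient(pd.DataFrame(rows))
        assert calls["aneuploidy"] == 1.0

    def test_fallback_to_afi_negative_biopsies(self):
        rows = [make_biopsy_row("p1", "a1", "AFI-", "NDBO", p53_IHC=1.0)]
        df = pd.DataFrame(rows)
        assert aggregate_patient(df, fallback=True)["p53_IHC"] == 1.0
        assert np.isnan(aggregate_patient(df, fallback=False)["p53_IHC"])

    def test_fallback_changes_only_patients_without_afi_pos(self):
        cohort = generate_cohort(planted_params(n_patients=120, seed=23))
        with_fb = aggregate_cohort(cohort, fallback=True)
        without_fb = aggregate_cohort(cohort, fallback=False)
        has_pos = cohort.biopsies.groupby("patient_id")["afi_status"].apply(
            lambda s: (s == "AFI+").any()
        )
        for pid in with_fb.index:
            a = with_fb.loc[pid, list(MARKERS)].astype(float)
            b = without_fb.loc[pid, list(MARKERS)].astype(float)
            if has_pos[pid]:
                pd.testing.assert_series_equal(a, b, check_names=False)
            else:
                assert b.isna().all()

    def test_marker_missing_only_if_unobserved_everywhere(self):
        rows = [
            make_biopsy_row("p1", "a1", "AFI+", "NDBO", **{"LOH9p": np.nan}),
            make_biopsy_row("p1", "a2", "AFI+", "NDBO", **{"LOH9p": np.nan}),
        ]
        calls = aggregate_patient(pd.DataFrame(rows))
        assert np.isnan(calls["LOH9p"])
        assert calls["p53_IHC"] == 0.0  # observed negative in both


class TestRocAuc:
    def test_perfect_separation_gives_one(self):
        res = roc_auc([0, 0, 1, 3, 3], [0, 0, 0, 1, 1], n_boot=50, seed=1)
        assert res.auc == 1.0

    def test_constant_scores_give_half(self):
        res = roc_auc([2, 2, 2, 2], [0, 1, 0, 1], n_boot=50, seed=1)
        assert res.auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1], n_boot=10, seed=0)

    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(2)
        scores = rng.integers(0, 4, 150)
        labels = rng.random(150) < 0.3
        res = roc_auc(scores, labels, n_boot=300, seed=3)
        assert res.ci[0] <= res.auc <= res.ci[1]

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 2**20))
    def test_equals_pair_counting_oracle(self, seed):
        """AUC equals the Mann-Whitney pair count: ties count one half."""
        rng = np.random.default_rng(seed)
        n = 40
        scores = rng.integers(0, 5, n).astype(float)
        labels = rng.random(n) < 0.4
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        res = roc_auc(scores, labels, n_boot=0)
        pos, neg = scores[labels], scores[~labels]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert res.auc == pytest.approx(wins / (len(pos) * len(neg)), rel=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 2**20))
    def test_invariant_to_monotone_rescoring(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 4, 60).astype(float)
        labels = rng.random(60) < 0.5
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        a = roc_auc(scores, labels, n_boot=0).auc
        b = roc_auc(np.exp(2 * scores) - 3, labels, n_boot=0).auc
        assert a == pytest.approx(b, rel=1e-12)


class TestChooseCutoff:
    def test_argmax_by_construction(self):
        # cutoff 1: acc .5; cutoff 2: acc .9; cutoff 3: acc .7
        scores = np.array([3] * 9 + [2] * 0 + [1] * 1 + [1] * 4 + [2] * 1 + [0] * 5)
        labels = np.array([1] * 9 + [1] * 1 + [0] * 10)
        acc = {c: ((scores >= c) == labels).mean() for c in (1, 2, 3)}
        best = max(acc, key=lambda c: (acc[c], c))
        assert choose_cutoff(scores, labels, max_cutoff=3) == best

    def test_ties_break_toward_higher_cutoff(self):
        scores = np.array([2, 2, 0, 0])
        labels = np.array([1, 1, 0, 0])
        # cutoffs 1 and 2 both give perfect accuracy -> pick 2
        assert choose_cutoff(scores, labels, max_cutoff=2) == 2

    def test_single_class_labels_error(self):
        with pytest.raises(ValueError):
            choose_cutoff([1, 2], [0, 0])


class TestDiagnosticMetrics:
    def test_published_training_operating_point(self):
        res = diagnostic_metrics(tp=23, fp=10, fn=1, tn=78)
        assert res.display()["sensitivity"] == "95.8%"
        assert res.display()["specificity"] == "88.6%"

    def test_half_sensitivity_when_tp_equals_fn(self):
        res = diagnostic_metrics(tp=7, fp=3, fn=7, tn=5)
        assert res.sensitivity == pytest.approx(0.5)

    @settings(max_examples=50, deadline=None)
    @given(
        tp=st.integers(0, 80), fp=st.integers(0, 80),
        fn=st.integers(0, 80), tn=st.integers(0, 80),
    )
    def test_matches_confusion_arithmetic_oracle(self, tp, fp, fn, tn):
        if tp + fn == 0 or tn + fp == 0:
            with pytest.raises(ValueError):
                diagnostic_metrics(tp, fp, fn, tn)
            return
        res = diagnostic_metrics(tp, fp, fn, tn)
        assert res.sensitivity == pytest.approx(tp / (tp + fn))
        assert res.specificity == pytest.approx(tn / (tn + fp))
        assert res.accuracy == pytest.approx((tp + tn) / (tp + fp + fn + tn))
        assert res.sens_ci[0] <= res.sensitivity <= res.sens_ci[1]

    def test_clopper_pearson_against_beta_quantiles(self):
        from scipy.stats import beta

        res = diagnostic_metrics(tp=23, fp=10, fn=1, tn=78)
        lo = beta.ppf(0.025, 23, 2)
        hi = beta.ppf(0.975, 24, 1)
        assert res.sens_ci == pytest.approx((lo, hi), rel=1e-9)


class TestExhaustiveSearch:
    def test_enumeration_counts(self):
        assert len(enumerate_panels((2, 3))) == 120
        assert len(enumerate_panels((2,))) == 36
        assert len(enumerate_panels((3,))) == 84

    def test_fixed_resample_reduces_to_plain_accuracy(self):
        cohort = generate_cohort(planted_params(n_patients=100, seed=31))
        table = aggregate_cohort(cohort)
        idx = np.arange((~table[list(PANEL3.members)].isna().any(axis=1)).sum())
        # a fixed identity resample on a complete-data cohort: mean accuracy is
        # exactly the best plain accuracy of each panel
        complete = generate_cohort(
            planted_params(n_patients=100, seed=31, missing_probs={m: 0.0 for m in MARKERS})
        )
        t = aggregate_cohort(complete)
        n = len(t)
        df = exhaustive_panel_search(t, sizes=(2,), fixed_resample=np.arange(n))
        row = df.iloc[0]
        sub = t[row["panel"].split("+")].to_numpy(dtype=float)
        s = sub.sum(axis=1)
        y = t["label"].to_numpy(dtype=bool)
        best_acc = max(((s >= c) == y).mean() for c in (1, 2))
        assert row["mean_accuracy"] == pytest.approx(best_acc)

    def test_recovers_planted_panel_single_seed(self):
        cohort = generate_cohort(planted_params(n_patients=157, seed=37))
        df = exhaustive_panel_search(cohort, n_boot=200, seed=5)
        assert df.iloc[0]["panel"] == "p53_IHC+cyclinA_IHC+aneuploidy"
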