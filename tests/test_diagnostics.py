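import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from trfdr.core import CLASSES
from trfdr.diagnostics import (ConfusionMatrix3, TransitionTable,
                               bowker_test, confusion_matrix,
                               mcnemar_binary_cc, net_gain, percent_round,
                               roc_auc, sensitivity, specificity,
                               transition_table)
from trfdr.tables import (REPORTED_METRICS_PCT, reference_confusion,
                          reference_transitions)


def _preds(true_labels, pred_labels, scores=None, patients=None):
    n = len(true_labels)
    df = pd.DataFrame({
        "patient_id": patients if patients is not None
        else [f"P{i}" for i in range(n)],
        "true_label": true_labels,
        "pred_label": pred_labels,
    })
    if scores is not None:
        for i, cls in enumerate(CLASSES):
            df[f"score_{cls}"] = scores[:, i]
    return df


class TestConfusionMatrix:
    def test_all_correct_is_diagonal(self):
        labels = ["adipose"] * 5 + ["fibroglandular"] * 3 + ["tumor"] * 4
        cm = confusion_matrix(_preds(labels, labels))
        np.testing.assert_array_equal(cm.counts, np.diag([5, 3, 4]))
        assert cm.total == 12

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(0)
        true = [CLASSES[i] for i in rng.integers(0, 3, 200)]
        pred = [CLASSES[i] for i in rng.integers(0, 3, 200)]
        cm = confusion_matrix(_preds(true, pred))
        for i, a in enumerate(CLASSES):
            for j, p in enumerate(CLASSES):
                expected = sum(1 for t, q in zip(true, pred)
                               if t == a and q == p)
                assert cm.counts[i, j] == expected
        assert cm.total == 200

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="necrotic"):
            confusion_matrix(_preds(["adipose"], ["necrotic"]))


class TestSensitivitySpecificity:
    def test_reference_matrices_reproduce_reported_metrics(self):
        """Every printed sensitivity/specificity cell follows from the
        corresponding printed confusion matrix at one-decimal precision."""
        for model, per_class in REPORTED_METRICS_PCT.items():
            cm = reference_confusion(model)
            for cls, want in per_class.items():
                assert percent_round(sensitivity(cm, cls)) == \
                    want["sensitivity"], (model, cls, "sensitivity")
                assert percent_round(specificity(cm, cls)) == \
                    want["specificity"], (model, cls, "specificity")

    def test_reference_row_sums_match_cohort_counts(self):
        for model in ("trf", "dr", "combined"):
            cm = reference_confusion(model)
            assert [cm.row_total(c) for c in CLASSES] == [761, 77, 347]

    def test_perfect_diagonal_gives_unity(self):
        cm = ConfusionMatrix3(counts=np.diag([10, 5, 7]))
        for cls in CLASSES:
            assert sensitivity(cm, cls) == 1.0
            assert specificity(cm, cls) == 1.0

    def test_bounds_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            cm = ConfusionMatrix3(
                counts=rng.integers(1, 50, (3, 3)))
            for cls in CLASSES:
                assert 0.0 <= sensitivity(cm, cls) <= 1.0
                assert 0.0 <= specificity(cm, cls) <= 1.0

    def test_empty_row_flagged(self):
        cm = ConfusionMatrix3(counts=np.array([[5, 0, 0], [0, 0, 0],
                                               [0, 0, 5]]))
        with pytest.raises(ValueError, match="undefined"):
            sensitivity(cm, "fibroglandular")


def pair_counting_auc(scores_pos, scores_neg):
    """AUC oracle: P(pos > neg) + 0.5 P(pos == neg) by explicit loops."""
    wins = ties = 0
    for sp in scores_pos:
        for sn in scores_neg:
            if sp > sn:
                wins += 1
            elif sp == sn:
                ties += 1
    return (wins + 0.5 * ties) / (len(scores_pos) * len(scores_neg))


class TestROC:
    def test_perfect_ranking_gives_auc_one(self):
        true = ["tumor"] * 5 + ["adipose"] * 5
        scores = np.zeros((10, 3))
        scores[:, 2] = [0.9] * 5 + [0.1] * 5
        scores[:, 0] = 1.0 - scores[:, 2]
        _, _, auc = roc_auc(_preds(true, true, scores), "tumor")
        assert auc == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(2)
        n = 4000
        true = ["tumor" if v else "adipose" for v in rng.random(n) < 0.4]
        scores = np.zeros((n, 3))
        scores[:, 2] = rng.random(n)
        _, _, auc = roc_auc(_preds(true, true, scores), "tumor")
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_matches_pair_counting_oracle_with_ties(self):
        rng = np.random.default_rng(3)
        for trial in range(10):
            n = 30
            true = ["tumor" if v else "adipose" for v in rng.random(n) < 0.5]
            if len(set(true)) < 2:
                continue
            scores = np.zeros((n, 3))
            scores[:, 2] = rng.integers(0, 5, n) / 4.0   # heavy ties
            preds = _preds(true, true, scores)
            _, _, auc = roc_auc(preds, "tumor")
            s = scores[:, 2]
            pos = [s[i] for i in range(n) if true[i] == "tumor"]
            neg = [s[i] for i in range(n) if true[i] != "tumor"]
            assert auc == pytest.approx(pair_counting_auc(pos, neg))

    def test_constant_scores_warn_and_return_half(self):
        true = ["tumor", "adipose", "tumor"]
        scores = np.full((3, 3), 1 / 3)
        with pytest.warns(UserWarning, match="constant"):
            _, _, auc = roc_auc(_preds(true, true, scores), "tumor")
        assert auc == 0.5


class TestTransitionTable:
    def test_identical_models_give_diagonal(self):
        rng = np.random.default_rng(4)
        true = ["tumor"] * 40 + ["adipose"] * 10
        pred = [CLASSES[i] for i in rng.integers(0, 3, 50)]
        a = _preds(true, pred)
        tt = transition_table(a, a)
        assert np.all(tt.counts == np.diag(np.diag(tt.counts)))
        assert tt.total == 40

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(5)
        true = [CLASSES[i] for i in rng.integers(0, 3, 120)]
        pa = [CLASSES[i] for i in rng.integers(0, 3, 120)]
        pb = [CLASSES[i] for i in rng.integers(0, 3, 120)]
        tt = transition_table(_preds(true, pa), _preds(true, pb))
        for i, ca in enumerate(CLASSES):
            for j, cb in enumerate(CLASSES):
                expected = sum(1 for t, x, y in zip(true, pa, pb)
                               if t == "tumor" and x == ca and y == cb)
                assert tt.counts[i, j] == expected

    def test_reference_tables_total_347(self):
        for comp in ("trf_vs_combined", "dr_vs_combined"):
            assert reference_transitions(comp).total == 347

    def test_record_mismatch_rejected(self):
        a = _preds(["tumor"] * 3, ["tumor"] * 3)
        b = _preds(["tumor", "adipose", "tumor"], ["tumor"] * 3)
        with pytest.raises(ValueError, match="different records"):
            transition_table(a, b)


class TestNetGain:
    def test_reference_trf_vs_combined(self):
        gain = net_gain(reference_transitions("trf_vs_combined"))
        assert gain == {"gained": 73, "lost": 27, "net": 46, "pct": 13.3}

    def test_reference_dr_vs_combined(self):
        gain = net_gain(reference_transitions("dr_vs_combined"))
        assert gain["gained"] == 35 and gain["lost"] == 17
        assert gain["net"] == 18
        assert gain["pct"] == pytest.approx(5.2)

    def test_identical_models_zero_net(self):
        tt = TransitionTable(counts=np.diag([5, 3, 40]))
        assert net_gain(tt)["net"] == 0


class TestSymmetryTests:
    def test_symmetric_table_gives_zero_statistic(self):
        tt = TransitionTable(counts=np.array([[10, 4, 6], [4, 8, 2],
                                              [6, 2, 30]]))
        res = bowker_test(tt)
        assert res.statistic == 0.0 and res.p_value == 1.0
        assert res.df == 3

    def test_reference_table_significant(self):
        res = bowker_test(reference_transitions("trf_vs_combined"))
        assert res.p_value < 0.01
        # the (adipose, fibroglandular) pair is 0/0 and drops from the df
        assert res.df == 2

    def test_matches_term_by_term_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            c = rng.integers(0, 20, (3, 3))
            tt = TransitionTable(counts=c)
            expected = 0.0
            dof = 0
            for i in range(3):
                for j in range(3):
                    if i < j and c[i, j] + c[j, i] > 0:
                        expected += (c[i, j] - c[j, i]) ** 2 \
                            / (c[i, j] + c[j, i])
                        dof += 1
            res = bowker_test(tt)
            if dof == 0:
                assert not res.defined
            else:
                assert res.statistic == pytest.approx(expected)
                assert res.df == dof

    def test_agrees_with_statsmodels_on_full_tables(self):
        from statsmodels.stats.contingency_tables import SquareTable
        rng = np.random.default_rng(7)
        for _ in range(5):
            c = rng.integers(1, 30, (3, 3))
            res = bowker_test(TransitionTable(counts=c))
            sm = SquareTable(c).symmetry(method="bowker")
            assert res.statistic == pytest.approx(float(sm.statistic))
            assert res.p_value == pytest.approx(float(sm.pvalue))

    def test_reduces_to_classic_mcnemar_on_collapsed_table(self):
        # only the (adipose, tumor) pair populated: Bowker == (b-c)^2/(b+c)
        c = np.zeros((3, 3), dtype=int)
        c[0, 2], c[2, 0] = 21, 9
        res = bowker_test(TransitionTable(counts=c))
        assert res.statistic == pytest.approx((21 - 9) ** 2 / 30)
        assert res.df == 1

    def test_mcnemar_cc_closed_form(self):
        # b=35, c=17 -> chi2 = (18-1)^2/52, df=1
        c = np.zeros((3, 3), dtype=int)
        c[0, 2], c[1, 2] = 20, 15      # b = 35 gained
        c[2, 0], c[2, 1] = 10, 7       # c = 17 lost
        res = mcnemar_binary_cc(TransitionTable(counts=c))
        assert res.statistic == pytest.approx(289 / 52)
        assert res.p_value == pytest.approx(float(chi2.sf(289 / 52, 1)))
        assert 0.01 < res.p_value < 0.05

    def test_reference_tables_under_both_variants(self):
        t9 = reference_transitions("trf_vs_combined")
        assert mcnemar_binary_cc(t9).p_value < 0.01
        t10 = reference_transitions("dr_vs_combined")
        assert mcnemar_binary_cc(t10).p_value == pytest.approx(0.018, abs=5e-3)
        # the symmetric 3x3 variant on the same table is not significant
        assert bowker_test(t10).p_value > 0.05

    def test_all_zero_discordance_flagged(self):
        tt = TransitionTable(counts=np.diag([5, 5, 5]))
        assert not bowker_test(tt).defined
        assert not mcnemar_binary_cc(tt).defined


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 25), min_size=9, max_size=9))
def test_bowker_statistic_property(flat):
    """On any 3x3 table the Bowker statistic equals the explicit pair sum,
    is non-negative, and is zero iff the table is symmetric."""
    c = np.array(flat, dtype=int).reshape(3, 3)
    res = bowker_test(TransitionTable(counts=c))
    pairs = [(i, j) for i in range(3) for j in range(i + 1, 3)
             if c[i, j] + c[j, i] > 0]
    if not pairs:
        assert not res.defined
        return
    expected = sum((c[i, j] - c[j, i]) ** 2 / (c[i, j] + c[j, i])
                   for i, j in pairs)
    assert res.statistic == pytest.approx(expected)
    assert res.statistic >= 0.0
    assert res.df == len(pairs)
    if np.array_equal(c, c.T):
        assert res.statistic == 0.0 and res.p_value == 1.0


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.booleans(), st.integers(0, 4)),
                min_size=6, max_size=25))
def test_auc_equals_pair_probability_property(items):
    """Pooled one-vs-rest AUC equals P(s+ > s-) + 0.5 P(tie) on every
    small instance with ties."""
    labels = [t for t, _ in items]
    if len(set(labels)) < 2:
        return
    true = ["tumor" if t else "adipose" for t in labels]
    scores = np.zeros((len(items), 3))
    scores[:, 2] = [s / 4.0 for _, s in items]
    if np.all(scores[:, 2] == scores[0, 2]):
        return
    _, _, auc = roc_auc(_preds(true, true, scores), "tumor")
    pos = [scores[i, 2] for i in range(len(items)) if labels[i]]
    neg = [scores[i, 2] for i in range(len(items)) if not labels[i]]
    assert auc == pytest.approx(pair_counting_auc(pos, neg))
    assert 0.0 <= auc <= 1.0


class TestPercentRound:
    @pytest.mark.parametrize("frac,expected", [
        (251 / 347, 72.3), (11 / 77, 14.3), (0.125, 12.5), (297 / 347, 85.6)])
    def test_half_up(self, frac, expected):
        assert percent_round(frac) == expected
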