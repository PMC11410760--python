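import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score, matthews_corrcoef

from pretextnet.clf_metrics import (
    ConfusionCounts,
    UndefinedMetricError,
    balanced_accuracy,
    compute_metrics,
    confusion,
    round_half_away,
    youden_index,
)

# printed per-class recalls of the six models (sensitivity, specificity,
# printed balanced accuracy, printed Youden)
PRINTED_ROWS = {
    "baseline": (0.1983, 0.9344, 0.5654, 0.1327),
    "den_p": (0.3130, 0.8765, 0.5948, 0.1895),
    "deb_p": (0.3391, 0.8484, 0.5938, 0.1875),
    "sa": (0.2643, 0.9140, 0.5892, 0.1783),
    "slsqp_wa": (0.3739, 0.8424, 0.6082, 0.2163),
    "af": (0.4991, 0.7760, 0.6376, 0.2751),
}


class TestConfusion:
    def test_perfect_probabilities(self):
        c = confusion(np.array([0.9, 0.1, 0.8, 0.2]), np.array([1, 0, 1, 0]))
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 0, 2, 0)

    def test_ties_predicted_positive(self):
        c = confusion(np.full(4, 0.5), np.array([1, 1, 0, 0]))
        assert c.tp == 2 and c.fp == 2 and c.tn == 0 and c.fn == 0

    def test_enumeration_oracle(self):
        probs = np.array([0.9, 0.4, 0.6, 0.2, 0.5, 0.1])
        labels = np.array([1, 1, 0, 0, 1, 0])
        c = confusion(probs, labels)
        tp = fp = tn = fn = 0
        for p, y in zip(probs, labels):
            pred = p >= 0.5
            if pred and y:
                tp += 1
            elif pred and not y:
                fp += 1
            elif not pred and not y:
                tn += 1
            else:
                fn += 1
        assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)

    def test_probability_rows_accepted(self):
        rows = np.array([[0.2, 0.8], [0.7, 0.3]])
        c = confusion(rows, np.array([1, 0]))
        assert c.tp == 1 and c.tn == 1

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            confusion(np.array([0.5]), np.array([0, 1]))
        with pytest.raises(ValueError):
            confusion(np.array([1.5]), np.array([1]))
        with pytest.raises(ValueError):
            confusion(np.array([0.5]), np.array([2]))


class TestComputeMetrics:
    def test_den_p_row_identities(self):
        sens, spec = 0.3130, 0.8765
        assert round_half_away(balanced_accuracy(sens, spec)) == 0.5948
        assert round_half_away(youden_index(sens, spec)) == 0.1895

    def test_all_metrics_at_maximum(self):
        rep = compute_metrics(ConfusionCounts(tp=1, fp=0, tn=1, fn=0))
        assert rep.balanced_accuracy == 1.0
        assert rep.mcc == 1.0
        assert rep.kappa == 1.0
        assert rep.youden == 1.0
        assert rep.f_score == 1.0

    def test_chance_level_counts(self):
        rep = compute_metrics(ConfusionCounts(tp=1, fp=1, tn=1, fn=1))
        assert rep.sensitivity == 0.5
        assert rep.specificity == 0.5
        assert rep.mcc == 0.0
        assert rep.kappa == 0.0
        assert rep.youden == 0.0

    def test_empty_class_raises_named_error(self):
        with pytest.raises(UndefinedMetricError, match="sensitivity"):
            compute_metrics(ConfusionCounts(tp=0, fp=1, tn=1, fn=0))
        with pytest.raises(UndefinedMetricError, match="specificity"):
            compute_metrics(ConfusionCounts(tp=1, fp=0, tn=0, fn=1))

    def test_mcc_kappa_match_sklearn(self, rng):
        for _ in range(10):
            y_true = rng.integers(0, 2, 60)
            y_pred = rng.integers(0, 2, 60)
            if len(np.unique(y_true)) < 2 or len(np.unique(y_pred)) < 2:
                continue
            c = confusion(y_pred.astype(float), y_true)
            rep = compute_metrics(c)
            assert rep.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-12)
            assert rep.kappa == pytest.approx(
                cohen_kappa_score(y_true, y_pred), abs=1e-12
            )

    def test_youden_is_two_balanced_accuracy_minus_one(self, rng):
        for _ in range(20):
            tp, fp, tn, fn = rng.integers(1, 50, 4)
            rep = compute_metrics(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            assert rep.youden == pytest.approx(2 * rep.balanced_accuracy - 1, abs=1e-12)

    def test_label_swap_symmetry(self, rng):
        for _ in range(10):
            tp, fp, tn, fn = (int(v) for v in rng.integers(1, 50, 4))
            a = compute_metrics(ConfusionCounts(tp, fp, tn, fn))
            b = compute_metrics(ConfusionCounts(tn, fn, tp, fp))  # classes swapped
            assert a.sensitivity == pytest.approx(b.specificity)
            assert a.specificity == pytest.approx(b.sensitivity)
            assert abs(a.mcc) == pytest.approx(abs(b.mcc), abs=1e-12)


class TestPrintedTableIdentities:
    @pytest.mark.parametrize("model", list(PRINTED_ROWS))
    def test_youden_matches_printed(self, model):
        sens, spec, _, printed_youden = PRINTED_ROWS[model]
        assert round_half_away(youden_index(sens, spec)) == printed_youden

    @pytest.mark.parametrize(
        "model", [m for m in PRINTED_ROWS if m != "baseline"]
    )
    def test_balanced_accuracy_matches_printed(self, model):
        sens, spec, printed_bal, _ = PRINTED_ROWS[model]
        assert round_half_away(balanced_accuracy(sens, spec)) == printed_bal

    def test_baseline_printed_cell_is_inconsistent(self):
        # documented discrepancy: the printed baseline balanced accuracy
        # (0.5654) differs from the mean of its printed recalls (0.5664)
        sens, spec, printed_bal, _ = PRINTED_ROWS["baseline"]
        assert round_half_away(balanced_accuracy(sens, spec)) == 0.5664
        assert printed_bal == 0.5654


class TestPropertyInvariants:
    @settings(max_examples=200, deadline=None)
    @given(st.tuples(*[st.integers(1, 500)] * 4))
    def test_metric_ranges_and_identities(self, counts):
        tp, fp, tn, fn = counts
        rep = compute_metrics(ConfusionCounts(tp, fp, tn, fn))
        assert 0.0 <= rep.balanced_accuracy <= 1.0
        assert -1.0 <= rep.mcc <= 1.0
        assert -1.0 <= rep.kappa <= 1.0
        assert rep.youden == pytest.approx(2 * rep.balanced_accuracy - 1, abs=1e-12)
        assert rep.balanced_accuracy == pytest.approx(
            (rep.sensitivity + rep.specificity) / 2, abs=1e-12
        )

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_rate_helpers_consistent(self, sens, spec):
        assert youden_index(sens, spec) == pytest.approx(
            2 * balanced_accuracy(sens, spec) - 1, abs=1e-12
        )


class TestRounding:
    def test_half_away_from_zero(self):
        assert round_half_away(0.59475) == 0.5948
        assert round_half_away(0.59375) == 0.5938
        assert round_half_away(-0.00005) == -0.0001

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)
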