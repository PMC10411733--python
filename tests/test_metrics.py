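import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neobench.metrics import (
    ConfusionCounts,
    dop,
    false_positive_rate_on_negatives,
    filter_negative_binders,
    metric_panel,
    rank_sum_test,
    roc_auc,
)
from neobench.models import Direction, MethodSpec


def pairwise_auc_oracle(scores, labels):
    """Independent AUC oracle: average over all positive/negative pairs,
    ties counted half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestMetricPanel:
    def test_validation_set_rates(self):
        # 7 positives / 113 negatives: 2 missed positives and 27 false
        # positives give the published 28.57% FNR and 23.89% FPR.
        panel = metric_panel(ConfusionCounts(tp=5, fn=2, fp=27, tn=86))
        assert panel.fnr == pytest.approx(28.57, abs=0.005)
        assert panel.fpr == pytest.approx(23.89, abs=0.005)

    def test_perfect_classifier(self):
        panel = metric_panel(ConfusionCounts(tp=10, fn=0, fp=0, tn=10))
        assert (panel.se, panel.sp, panel.ppv, panel.npv, panel.f1) == (1, 1, 1, 1, 1)
        assert panel.fpr == panel.fnr == 0
        assert panel.dop == 0

    def test_degenerate_all_negative_calls(self):
        panel = metric_panel(ConfusionCounts(tp=0, fn=5, fp=0, tn=5))
        assert panel.se == 0
        assert panel.ppv == 0  # zero-denominator convention
        assert panel.f1 == 0

    def test_fpr_complements_specificity_exactly(self):
        panel = metric_panel(ConfusionCounts(tp=3, fn=4, fp=11, tn=29))
        assert panel.fpr + 100 * panel.sp == pytest.approx(100, abs=1e-12)
        assert panel.fnr + 100 * panel.se == pytest.approx(100, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, tn=1, fn=0)


class TestDop:
    def test_optimal_point(self):
        assert dop(1, 1, 1, 1) == 0

    def test_worst_point(self):
        assert dop(0, 0, 0, 0) == 2.0

    def test_direct_arithmetic(self):
        assert dop(0.8, 0.5, 0.6, 0.7) == pytest.approx(
            math.sqrt(0.04 + 0.25 + 0.16 + 0.09), abs=1e-12
        )
        assert dop(0.8, 0.5, 0.6, 0.7) == pytest.approx(0.7348, abs=5e-5)

    def test_domain_error(self):
        with pytest.raises(ValueError, match="outside"):
            dop(1.1, 0.5, 0.5, 0.5)

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=4, max_size=4),
        st.integers(min_value=0, max_value=3),
        st.floats(min_value=0, max_value=1),
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotone_nonincreasing_in_each_argument(self, args, i, bump):
        improved = list(args)
        improved[i] = min(1.0, improved[i] + bump)
        assert dop(*improved) <= dop(*args) + 1e-12


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([3, 4, 1, 2], [1, 1, 0, 0])
        assert auc == 1.0

    def test_derived_pairwise_example(self):
        # positives {3, 1}, negatives {2, 0}: 3 of 4 pairs concordant
        _, auc = roc_auc([3, 1, 2, 0], [1, 1, 0, 0])
        assert auc == 0.75

    def test_rank_invariance_under_monotone_transform(self):
        scores = [0.1, 0.7, 0.3, 0.9, 0.4]
        labels = [0, 1, 0, 1, 1]
        _, a1 = roc_auc(scores, labels)
        _, a2 = roc_auc([math.exp(5 * s) for s in scores], labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_lower_is_positive_orientation(self):
        # affinity-like scores: positives bind at lower nM
        _, auc = roc_auc([50, 80, 400, 900], [1, 1, 0, 0],
                         Direction.LOWER_IS_POSITIVE)
        assert auc == 1.0

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="AUC undefined"):
            roc_auc([1, 2], [1, 1])

    def test_roc_points_bracket_unit_square(self):
        roc, _ = roc_auc([0.2, 0.8, 0.5, 0.5], [0, 1, 1, 0])
        assert (roc.iloc[0].fpr, roc.iloc[0].tpr) == (0, 0)
        assert (roc.iloc[-1].fpr, roc.iloc[-1].tpr) == (1, 1)

    @given(
        st.lists(
            st.tuples(st.integers(min_value=-5, max_value=5),
                      st.integers(min_value=0, max_value=1)),
            min_size=4,
            max_size=50,
        ).filter(
            lambda rows: 0 < sum(y for _, y in rows) < len(rows)
            and len({s for s, _ in rows}) > 1
        )
    )
    @settings(max_examples=300, derandomize=True)
    def test_matches_pairwise_oracle(self, rows):
        scores = [s for s, _ in rows]
        labels = [y for _, y in rows]
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(pairwise_auc_oracle(scores, labels), abs=1e-12)

    @given(
        st.lists(
            st.tuples(st.floats(min_value=-3, max_value=3),
                      st.integers(min_value=0, max_value=1)),
            min_size=4,
            max_size=30,
        ).filter(
            lambda rows: 0 < sum(y for _, y in rows) < len(rows)
            and len({s for s, _ in rows}) > 1
        )
    )
    @settings(max_examples=200, derandomize=True)
    def test_label_flip_complement(self, rows):
        scores = [s for s, _ in rows]
        labels = [y for _, y in rows]
        flipped = [1 - y for y in labels]
        _, a = roc_auc(scores, labels)
        _, a_flip = roc_auc(scores, flipped)
        assert a + a_flip == pytest.approx(1.0, abs=1e-12)


class TestRankSum:
    def test_exact_enumeration_example(self):
        # all 3-subsets of {1..6}: the observed split is the most extreme of
        # 20, so two-sided p = 2/20
        assert rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1, abs=1e-12)

    def test_identical_large_groups_not_significant(self):
        a = list(range(30))
        assert rank_sum_test(a, list(a)) >= 0.99

    def test_constant_data_returns_one(self):
        assert rank_sum_test([2, 2, 2], [2, 2]) == 1.0

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            rank_sum_test([], [1.0])

    def test_one_sided_alternatives(self):
        p_greater = rank_sum_test([4, 5, 6], [1, 2, 3], "a_greater")
        p_less = rank_sum_test([4, 5, 6], [1, 2, 3], "a_less")
        assert p_greater == pytest.approx(0.05, abs=1e-12)
        assert p_less > 0.9

    def test_exact_close_to_normal_approximation(self, rng):
        # untied 6 vs 6: the two branches agree within 0.02
        from scipy import stats

        for _ in range(25):
            a = rng.normal(size=6)
            b = rng.normal(size=6)
            p_exact = rank_sum_test(a, b)
            p_approx = float(
                stats.mannwhitneyu(a, b, alternative="two-sided",
                                   method="asymptotic").pvalue
            )
            assert abs(p_exact - p_approx) < 0.02


class TestFalsePositiveOnNegatives:
    def _slice(self, values):
        return pd.DataFrame({"value": values, "label": ["non_immunogenic"] * len(values)})

    def test_published_negative_set_rate(self, rng):
        # 297 negatives of which 90 called positive -> 30.3%
        spec = MethodSpec("MixMHCpred", "S")
        values = np.concatenate([rng.uniform(0.6, 1.0, 90), rng.uniform(0.0, 0.4, 207)])
        count, rate = false_positive_rate_on_negatives(self._slice(values), spec, 0.5)
        assert count == 90
        assert round(rate, 1) == 30.3
        assert round(rate) == 30

    def test_threshold_above_everything(self):
        spec = MethodSpec("DeepHLApan", "I")
        count, rate = false_positive_rate_on_negatives(self._slice([0.1, 0.2]), spec, 0.9)
        assert (count, rate) == (0, 0.0)

    def test_all_positive(self):
        spec = MethodSpec("DeepHLApan", "I")
        count, rate = false_positive_rate_on_negatives(
            self._slice([0.9] * 10), spec, 0.5
        )
        assert (count, rate) == (10, 100.0)

    def test_immunogenic_rows_rejected(self):
        spec = MethodSpec("DeepHLApan", "I")
        df = pd.DataFrame({"value": [0.1], "label": ["immunogenic"]})
        with pytest.raises(ValueError, match="immunogenic"):
            false_positive_rate_on_negatives(df, spec, 0.5)

    def test_empty_slice_errors(self):
        spec = MethodSpec("DeepHLApan", "I")
        with pytest.raises(ValueError, match="empty"):
            false_positive_rate_on_negatives(self._slice([]), spec, 0.5)


class TestFilterNegativeBinders:
    def _rows(self):
        return pd.DataFrame(
            {
                "label": ["non_immunogenic"] * 4 + ["immunogenic"],
                "length": [9, 9, 11, 9, 9],
                "ba": [120.0, 600.0, 120.0, None, 120.0],
            }
        )

    def test_filter_rules(self):
        with pytest.warns(UserWarning, match="dropped"):
            kept = filter_negative_binders(self._rows())
        assert len(kept) == 1
        assert kept.iloc[0].ba == 120.0 and kept.iloc[0].length == 9

    def test_boundary_500_excluded(self):
        rows = pd.DataFrame(
            {"label": ["non_immunogenic"], "length": [9], "ba": [500.0]}
        )
        assert len(filter_negative_binders(rows)) == 0

    def test_missing_columns_error(self):
        with pytest.raises(ValueError, match="missing columns"):
            filter_negative_binders(pd.DataFrame({"ba": [1.0]}))
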