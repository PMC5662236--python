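"""Metric correctness against independent oracles: MCC, AUROC, Wilcoxon,
calibration curves and the group summary tables."""

import itertools
import math

import numpy as np
import pytest

from funcfly.errors import ParameterError, ValidationError
from funcfly.evaluation import (
    ConfusionCounts,
    auroc,
    confusion_at_threshold,
    mcc,
    precision_confidence_correlation,
    summarize_groups,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------------------
# MCC
# ---------------------------------------------------------------------------

def _binary_vectors(c):
    y_true = [1] * c.TP + [0] * c.FP + [0] * c.TN + [1] * c.FN
    y_pred = [1] * c.TP + [1] * c.FP + [0] * c.TN + [0] * c.FN
    return np.array(y_true), np.array(y_pred)


class TestMcc:
    def test_perfect_prediction_is_one(self):
        assert mcc(ConfusionCounts(TP=5, FP=0, TN=5, FN=0)) == pytest.approx(1.0)

    def test_inverted_prediction_is_minus_one(self):
        assert mcc(ConfusionCounts(TP=0, FP=5, TN=0, FN=5)) == pytest.approx(-1.0)

    def test_worked_value_10_over_sqrt_600(self):
        c = ConfusionCounts(TP=3, FP=1, TN=4, FN=2)
        assert mcc(c) == pytest.approx(10 / math.sqrt(600))
        assert mcc(c) == pytest.approx(0.4082, abs=5e-5)

    def test_matches_formula_and_pearson_on_all_small_tables(self):
        """Direct formula evaluation and Pearson-correlation equivalence
        over every 2x2 table with cells <= 6."""
        for tp, fp, tn, fn in itertools.product(range(7), repeat=4):
            if tp + fp + tn + fn == 0:
                continue
            c = ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)
            denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            got = mcc(c)
            if denom == 0:
                assert got == 0.0
                continue
            assert got == pytest.approx((tp * tn - fp * fn) / math.sqrt(denom))
            y_true, y_pred = _binary_vectors(c)
            assert got == pytest.approx(np.corrcoef(y_true, y_pred)[0, 1], abs=1e-12)

    def test_empty_table_rejected(self):
        with pytest.raises(ParameterError):
            mcc(ConfusionCounts(TP=0, FP=0, TN=0, FN=0))

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            ConfusionCounts(TP=-1, FP=0, TN=0, FN=0)


# ---------------------------------------------------------------------------
# AUROC
# ---------------------------------------------------------------------------

def _pair_count_auroc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation_is_one(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_constant_scores_are_chance(self):
        assert auroc([0.5] * 10, [1] * 5 + [0] * 5) == pytest.approx(0.5)

    def test_matches_pair_counting_on_random_fixtures(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            labels = rng.integers(0, 2, size=20)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.uniform(size=20), 1)  # induce ties
            assert auroc(scores, labels) == pytest.approx(
                _pair_count_auroc(scores, labels), abs=1e-12
            )

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, size=50)
        labels[0], labels[1] = 0, 1
        scores = rng.uniform(size=50)
        base = auroc(scores, labels)
        assert auroc(np.exp(3 * scores), labels) == pytest.approx(base)
        assert auroc(np.log(scores + 1e-9), labels) == pytest.approx(base)

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            auroc([0.1, 0.2], [1, 1])


# ---------------------------------------------------------------------------
# thresholded confusion
# ---------------------------------------------------------------------------

class TestConfusionAtThreshold:
    def test_threshold_one_yields_no_positives(self):
        c = confusion_at_threshold([0.2, 0.9, 1.0], [0, 1, 1], threshold=1.0)
        assert c.TP == 0 and c.FP == 0 and c.total == 3

    def test_zero_threshold_with_positive_scores_flags_all(self):
        c = confusion_at_threshold([0.2, 0.9], [0, 1], threshold=0.0)
        assert c.TP + c.FP == 2

    def test_counts_conserve_sample_size(self):
        rng = np.random.default_rng(2)
        scores = rng.uniform(size=37)
        labels = rng.integers(0, 2, size=37)
        assert confusion_at_threshold(scores, labels).total == 37


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def _enumerate_wilcoxon(d):
    """Exact two-sided p by enumerating all 2^n sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = float(ranks[d > 0].sum())
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(float(sum(r for s, r in zip(signs, ranks) if s)))
    ws = np.array(ws)
    p = 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean())
    return min(1.0, p)


class TestWilcoxon:
    def test_identical_samples_give_p_one(self):
        x = np.arange(8.0)
        assert wilcoxon_signed_rank(x, x) == 1.0

    def test_eight_positive_differences_exact_p(self):
        x = np.arange(1.0, 9.0)
        assert wilcoxon_signed_rank(x, np.zeros(8)) == pytest.approx(
            2 * (1 / 2**8)
        )

    def test_matches_exhaustive_enumeration_for_small_n(self):
        rng = np.random.default_rng(3)
        for n in range(5, 11):
            for _ in range(5):
                d = rng.normal(size=n)
                while np.unique(np.abs(d)).size < n or (d == 0).any():
                    d = rng.normal(size=n)
                x = np.zeros(n)
                assert wilcoxon_signed_rank(d, x) == pytest.approx(
                    _enumerate_wilcoxon(d), abs=1e-12
                )

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ParameterError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0])


# ---------------------------------------------------------------------------
# precision-confidence calibration
# ---------------------------------------------------------------------------

class TestPrecisionConfidence:
    def test_scores_equal_to_labels_are_degenerate(self):
        labels = np.array([0, 1] * 10)
        curve = precision_confidence_correlation(labels.astype(float), labels)
        assert curve.degenerate
        assert (curve.precisions == 1.0).all()

    def test_calibrated_scores_correlate_strongly(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=5000)
        labels = (rng.uniform(size=5000) < p).astype(int)
        curve = precision_confidence_correlation(p, labels)
        assert curve.r > 0.9

    def test_precisions_lie_in_unit_interval(self):
        rng = np.random.default_rng(5)
        scores = rng.uniform(size=200)
        labels = rng.integers(0, 2, size=200)
        curve = precision_confidence_correlation(scores, labels)
        assert ((0.0 <= curve.precisions) & (curve.precisions <= 1.0)).all()


# ---------------------------------------------------------------------------
# group comparison tables
# ---------------------------------------------------------------------------

def _results(terms, groups, algs, values):
    out = {}
    k = 0
    for t in terms:
        out[t] = {}
        for g in groups:
            out[t][g] = {}
            for a in algs:
                out[t][g][a] = (values[k % len(values)], values[(k + 1) % len(values)])
                k += 1
    return out


class TestSummarizeGroups:
    ALGS = ["RF", "AdaBoost", "KNN", "LDA"]

    def test_single_term_table_equals_its_scores(self):
        results = {"GO:1": {"Seq": {a: (0.3, 0.7) for a in self.ALGS}}}
        table = summarize_groups(results, {"GO:1": "BP"}, metric="mcc").table
        assert table.loc["Seq", ("RF", "BP")] == pytest.approx(0.3)
        assert table.loc["Seq", ("Opt", "BP")] == pytest.approx(0.3)

    def test_mean_of_two_terms(self):
        results = {
            "GO:1": {"Seq": {a: (0.2, 0.6) for a in self.ALGS}},
            "GO:2": {"Seq": {a: (0.4, 0.8) for a in self.ALGS}},
        }
        ns = {"GO:1": "BP", "GO:2": "BP"}
        assert summarize_groups(results, ns, "mcc").table.loc[
            "Seq", ("RF", "BP")
        ] == pytest.approx(0.3)

    def test_opt_column_dominates_every_classifier(self):
        rng = np.random.default_rng(6)
        results = _results(
            [f"GO:{i}" for i in range(6)], ["Seq", "Ave"], self.ALGS,
            list(rng.uniform(-0.2, 0.9, size=37)),
        )
        ns = {f"GO:{i}": ["BP", "MF", "CC"][i % 3] for i in range(6)}
        for metric in ("mcc", "auroc"):
            table = summarize_groups(results, ns, metric).table
            for group in ("Seq", "Ave"):
                for alg in self.ALGS:
                    for space in ("BP", "MF", "CC"):
                        assert (
                            table.loc[group, ("Opt", space)]
                            >= table.loc[group, (alg, space)] - 1e-12
                        )

    def test_missing_cell_names_term_and_group(self):
        results = {
            "GO:1": {"Seq": {a: (0.2, 0.6) for a in self.ALGS}},
            "GO:2": {"Seq": {a: (0.2, 0.6) for a in ["RF", "KNN", "LDA"]}},
        }
        with pytest.raises(ValidationError, match="GO:2.*Seq"):
            summarize_groups(results, {"GO:1": "BP", "GO:2": "BP"})
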