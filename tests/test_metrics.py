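"""Diagnostic accuracy metrics and McNemar comparison."""

import math

import numpy as np
import pytest
from scipy.stats import binom

import irregular_af as ia


class TestConfusion:
    def test_perfect_predictions(self):
        preds = ["AF"] * 10 + ["NOT_AF"] * 10
        truth = ["AF"] * 10 + ["NOT_AF"] * 10
        cm = ia.confusion(preds, truth)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (10, 0, 0, 10)

    def test_all_negative_predictions(self):
        cm = ia.confusion(["NOT_AF"] * 6, ["AF"] * 3 + ["NOT_AF"] * 3)
        assert cm.tp == 0 and cm.fp == 0 and cm.fn == 3 and cm.tn == 3

    def test_matches_loop_oracle_on_shuffled_pairs(self, rng):
        preds = rng.random(200) < 0.4
        truth = rng.random(200) < 0.3
        cm = ia.confusion(list(preds), list(truth))
        tp = sum(p and t for p, t in zip(preds, truth))
        fp = sum(p and not t for p, t in zip(preds, truth))
        fn = sum(t and not p for p, t in zip(preds, truth))
        tn = sum(not p and not t for p, t in zip(preds, truth))
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (tp, fp, fn, tn)

    def test_pair_permutation_leaves_metrics_unchanged(self, rng):
        preds = list(rng.random(100) < 0.5)
        truth = list(rng.random(100) < 0.3)
        order = rng.permutation(100)
        m1 = ia.metrics_from_cm(ia.confusion(preds, truth))
        m2 = ia.metrics_from_cm(
            ia.confusion([preds[i] for i in order], [truth[i] for i in order])
        )
        assert m1 == m2

    def test_inconclusive_scored_as_false_result(self):
        cm = ia.confusion(["inconclusive", "inconclusive"], ["AF", "NOT_AF"])
        assert cm.fn == 1 and cm.fp == 1

    def test_length_mismatch(self):
        with pytest.raises(ia.ValidationError):
            ia.confusion(["AF"], ["AF", "NOT_AF"])


class TestMetrics:
    def test_published_validation_percentages(self):
        # test set of 144 strips, 29 with AF; the novel two-step rule
        report = ia.metrics_from_cm(ia.ConfusionMatrix(tp=26, fp=9, fn=3, tn=106))
        pct = report.as_percent()
        assert pct["sensitivity"] == pytest.approx(89.66, abs=0.01)
        assert pct["specificity"] == pytest.approx(92.17, abs=0.01)
        assert pct["ppv"] == pytest.approx(74.29, abs=0.01)
        assert pct["npv"] == pytest.approx(97.25, abs=0.01)
        assert pct["f2"] == pytest.approx(86.09, abs=0.01)
        assert pct["accuracy"] == pytest.approx(91.67, abs=0.01)

    def test_smartwatch_comparison_percentages(self):
        # same test set scored through the watch's native classifier with
        # inconclusive results counted as false
        pct = ia.metrics_from_cm(
            ia.ConfusionMatrix(tp=24, fp=24, fn=5, tn=91)
        ).as_percent()
        assert pct["sensitivity"] == pytest.approx(82.76, abs=0.01)
        assert pct["specificity"] == pytest.approx(79.13, abs=0.01)
        assert pct["ppv"] == pytest.approx(50.00, abs=0.01)
        assert pct["npv"] == pytest.approx(94.79, abs=0.01)
        assert pct["f2"] == pytest.approx(73.17, abs=0.01)
        assert pct["accuracy"] == pytest.approx(79.86, abs=0.01)

    def test_step1_only_percentages(self):
        # irregularity features alone, before the cluster veto
        pct = ia.metrics_from_cm(
            ia.ConfusionMatrix(tp=26, fp=15, fn=3, tn=100)
        ).as_percent()
        assert pct["sensitivity"] == pytest.approx(89.66, abs=0.01)
        assert pct["specificity"] == pytest.approx(86.96, abs=0.01)

    def test_undefined_ratio_is_nan_not_zero(self):
        rep = ia.metrics_from_cm(ia.ConfusionMatrix(tp=0, fp=0, fn=0, tn=5))
        assert rep.specificity == 1.0
        assert math.isnan(rep.sensitivity)
        assert math.isnan(rep.ppv)

    def test_f2_identity(self, rng):
        for _ in range(100):
            tp, fp, fn, tn = rng.integers(1, 60, 4)
            rep = ia.metrics_from_cm(ia.ConfusionMatrix(*map(int, (tp, fp, fn, tn))))
            lhs = rep.f2 * (4 * rep.ppv + rep.sensitivity)
            rhs = 5 * rep.ppv * rep.sensitivity
            assert abs(lhs - rhs) < 1e-12


class TestMcNemar:
    def test_symmetric_discordance(self):
        res = ia.mcnemar(10, 10)
        assert res.chi2 == 0.0
        assert res.p_value == 1.0

    def test_exact_fraction_statistic(self):
        res = ia.mcnemar(25, 8)
        assert res.chi2 == pytest.approx(289 / 33, rel=1e-15)

    def test_continuity_correction_shrinks_statistic(self):
        assert ia.mcnemar(25, 8, continuity=True).chi2 == pytest.approx(256 / 33)

    def test_continuity_correction_raises_p(self):
        for b in range(0, 51, 5):
            for c in range(0, 51, 7):
                if b == c or b + c == 0:
                    continue
                assert (
                    ia.mcnemar(b, c, continuity=True).p_value
                    >= ia.mcnemar(b, c).p_value
                )

    def test_against_exact_binomial_oracle(self):
        # chi-square tail vs. exact two-sided binomial(n, 1/2) tail; the
        # approximation is documented to stay within 0.09 absolute wherever
        # the exact p <= 0.2, and within 0.25 whenever b + c >= 10
        for b in range(31):
            for c in range(31):
                if b + c == 0:
                    continue
                p_chi = ia.mcnemar(b, c).p_value
                n, lo, hi = b + c, min(b, c), max(b, c)
                p_exact = min(binom.cdf(lo, n, 0.5) + binom.sf(hi - 1, n, 0.5), 1.0)
                if p_exact <= 0.2:
                    assert abs(p_chi - p_exact) <= 0.09
                elif n >= 10:
                    assert abs(p_chi - p_exact) <= 0.25

    def test_no_discordant_pairs_rejected(self):
        with pytest.raises(ia.ValidationError, match="discordant"):
            ia.mcnemar(0, 0)


class TestDiscordantCounts:
    def test_counting(self):
        truth = ["AF", "AF", "NOT_AF", "NOT_AF", "AF"]
        a = ["AF", "NOT_AF", "NOT_AF", "AF", "AF"]  # correct on 0,2,4
        b = ["NOT_AF", "AF", "NOT_AF", "NOT_AF", "inconclusive"]  # correct on 1,2,3
        assert ia.discordant_counts(a, b, truth) == (2, 2)
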