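"""Diagnostic-accuracy evaluation and paired classifier comparison.

Reports sensitivity, specificity, PPV, NPV, F2 and accuracy from a 2x2
confusion matrix with AF as the positive class, and compares two paired
classifiers with McNemar's chi-square test on the discordant pairs (1
degree of freedom).  The F2 score weights sensitivity four times as
heavily as PPV: F2 = 5*PPV*Se / (4*PPV + Se) = 5*tp / (5*tp + 4*fn + fp).

Undefined ratios (zero denominator) are reported as NaN, never 0.
External classifiers may emit "inconclusive"; the evaluation convention
scores those as false results (wrong verdicts) via ``confusion``'s
``inconclusive`` policy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy.stats import chi2 as _chi2

from .core import ValidationError

#: sentinel accepted in prediction lists for external classifiers
INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("counts must be nonnegative")
        if self.tp + self.fp + self.fn + self.tn < 1:
            raise ValidationError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    f2: float
    accuracy: float

    def as_percent(self, decimals: int = 2) -> dict[str, float]:
        """Percentages rounded half-up, as printed in clinical reports."""
        out = {}
        for k, v in self.__dict__.items():
            out[k] = (
                float("nan")
                if math.isnan(v)
                else float(
                    math.floor(v * 100 * 10**decimals + 0.5) / 10**decimals
                )
            )
        return out


def _coerce_af(value) -> bool | str:
    if isinstance(value, str):
        low = value.strip().lower()
        if low == INCONCLUSIVE:
            return INCONCLUSIVE
        return low in ("af", "true", "1", "yes")
    return bool(value)


def confusion(
    predictions: Sequence, truth: Sequence, inconclusive: str = "false"
) -> ConfusionMatrix:
    """Tally predictions against gold-standard labels (AF positive).

    Entries may be booleans or strings ("AF"/"NOT_AF"/"inconclusive").
    ``inconclusive="false"`` scores an inconclusive prediction as a wrong
    verdict (the evaluation convention for external classifiers);
    ``inconclusive="error"`` rejects them.
    """
    if len(predictions) != len(truth):
        raise ValidationError("length mismatch between predictions and truth")
    tp = fp = fn = tn = 0
    for p, t in zip(predictions, truth):
        t_val = _coerce_af(t)
        if t_val == INCONCLUSIVE:
            raise ValidationError("truth labels cannot be inconclusive")
        t_af = bool(t_val)
        p_val = _coerce_af(p)
        if p_val == INCONCLUSIVE:
            if inconclusive == "error":
                raise ValidationError("inconclusive prediction not allowed")
            p_af = not t_af  # scored as a false result
        else:
            p_af = bool(p_val)
        if p_af and t_af:
            tp += 1
        elif p_af and not t_af:
            fp += 1
        elif not p_af and t_af:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp, fp, fn, tn)


def _ratio(num: int, den: int) -> float:
    return num / den if den else float("nan")


def metrics_from_cm(cm: ConfusionMatrix) -> MetricsReport:
    """All six accuracy metrics; NaN where a denominator is zero."""
    return MetricsReport(
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        f2=_ratio(5 * cm.tp, 5 * cm.tp + 4 * cm.fn + cm.fp),
        accuracy=_ratio(cm.tp + cm.tn, cm.total),
    )


@dataclass(frozen=True)
class McNemarResult:
    b: int  # test A correct, test B wrong
    c: int  # test A wrong, test B correct
    chi2: float
    p_value: float
    continuity_corrected: bool


def mcnemar(b: int, c: int, continuity: bool = False) -> McNemarResult:
    """McNemar's chi-square on discordant pair counts.

    chi2 = (|b - c| - cc)^2 / (b + c) with cc = 1 under the continuity
    correction, p from the upper tail of chi-square with 1 df.
    """
    if b < 0 or c < 0:
        raise ValidationError("counts must be nonnegative")
    if b + c == 0:
        raise ValidationError("no discordant pairs")
    delta = abs(b - c) - (1 if continuity else 0)
    delta = max(delta, 0)
    stat = delta**2 / (b + c)
    p = float(_chi2.sf(stat, df=1))
    return McNemarResult(b, c, float(stat), p, continuity)


def discordant_counts(
    pred_a: Sequence, pred_b: Sequence, truth: Sequence
) -> tuple[int, int]:
    """(b, c) = (#A correct & B wrong, #A wrong & B correct) for paired
    predictions; inconclusive entries score as wrong."""
    if not (len(pred_a) == len(pred_b) == len(truth)):
        raise ValidationError("length mismatch")
    b = c = 0
    for pa, pb, t in zip(pred_a, pred_b, truth):
        t_val = _coerce_af(t)
        if t_val == INCONCLUSIVE:
            raise ValidationError("truth cannot be inconclusive")
        t_af = bool(t_val)

        def correct(p) -> bool:
            v = _coerce_af(p)
            if v == INCONCLUSIVE:
                return False
            return bool(v) == t_af

        ca, cb = correct(pa), correct(pb)
        if ca and not cb:
            b += 1
        elif cb and not ca:
            c += 1
    return b, c
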