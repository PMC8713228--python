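"""Agreement between discriminant predictions and final pathology.

The headline statistic is the per-class *coincidence rate* — the fraction
of truly positive (resp. negative) patients the discriminant calls
correctly, i.e. per-class recall — and their unweighted mean (macro or
balanced accuracy).  The mean coincidence rate deliberately is NOT overall
accuracy: with unequal class sizes the two differ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .frequency import ClassConditionalFrequencyTable
from .scheme import ClassLabel
from .scoring import round_half_away


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionMatrix:
    """2×2 counts; rows = final diagnosis (+/−), columns = prediction."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise EvaluationError(f"{name} must be non-negative")

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def swapped(self) -> "ConfusionMatrix":
        """The same matrix with the two classes exchanged."""
        return ConfusionMatrix(tp=self.tn, fn=self.fp, fp=self.fn, tn=self.tp)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self.tp, self.fn], [self.fp, self.tn]],
            index=pd.Index(["+", "-"], name="final diagnosis"),
            columns=pd.Index(["+", "-"], name="discriminant result"),
        )


@dataclass(frozen=True)
class CoincidenceReport:
    """Per-class and mean coincidence rates, in percent."""

    rate_positive: float
    rate_negative: float
    rate_mean: float
    overall_accuracy: float
    cohort_size: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "statistic": [
                    "coincidence rate (+)",
                    "coincidence rate (-)",
                    "mean coincidence rate",
                    "overall accuracy",
                ],
                "percent": [
                    round_half_away(self.rate_positive),
                    round_half_away(self.rate_negative),
                    round_half_away(self.rate_mean),
                    round_half_away(self.overall_accuracy),
                ],
            }
        )


def build_confusion(
    truths: Sequence[ClassLabel], predictions: Sequence[ClassLabel]
) -> ConfusionMatrix:
    """Cross-tabulate final diagnoses against discriminant predictions."""
    if len(truths) != len(predictions):
        raise EvaluationError(
            f"length mismatch: {len(truths)} truths vs {len(predictions)} predictions"
        )
    if not truths:
        raise EvaluationError("empty input")
    tp = fn = fp = tn = 0
    for t, p in zip(truths, predictions):
        t, p = ClassLabel.coerce(t), ClassLabel.coerce(p)
        if t is ClassLabel.POSITIVE:
            if p is ClassLabel.POSITIVE:
                tp += 1
            else:
                fn += 1
        else:
            if p is ClassLabel.POSITIVE:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def coincidence_rates(cm: ConfusionMatrix) -> CoincidenceReport:
    """Per-class recall, macro mean, and overall accuracy (percent).

    Requires both classes present; a per-class rate over an empty class
    is undefined.
    """
    if cm.n_positive == 0 or cm.n_negative == 0:
        raise EvaluationError("undefined per-class rate: a class is empty")
    rate_pos = 100.0 * cm.tp / cm.n_positive
    rate_neg = 100.0 * cm.tn / cm.n_negative
    return CoincidenceReport(
        rate_positive=rate_pos,
        rate_negative=rate_neg,
        rate_mean=(rate_pos + rate_neg) / 2.0,
        overall_accuracy=100.0 * (cm.tp + cm.tn) / cm.total,
        cohort_size=cm.total,
    )


def derived_rates(
    table: ClassConditionalFrequencyTable, factor: str
) -> dict[str, float | None]:
    """Per-category metastasis percentages for one factor.

    For category j: 100 × n(+, j) / (n(+, j) + n(−, j)); a category with
    no patients in either class yields ``None``.
    """
    f = table.scheme.factor(factor)
    out: dict[str, float | None] = {}
    for cat in f.categories:
        pos = table.count(factor, cat, ClassLabel.POSITIVE)
        neg = table.count(factor, cat, ClassLabel.NEGATIVE)
        out[cat] = 100.0 * pos / (pos + neg) if pos + neg else None
    return out


def cohort_metastatic_rate(table: ClassConditionalFrequencyTable) -> float:
    """Whole-cohort metastasis percentage, 100 × N_+ / (N_+ + N_−)."""
    return 100.0 * table.prevalence()
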