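"""The log-probability additive score: fitting, scoring, classification.

Each (factor, category, class) cell of a fitted score table is

    s = (log10 P(category | class) + 1) * 10

so P = 1 maps to 10 points, P = 0.1 to 0, and P < 0.1 goes negative.  A
patient's class total S_g is the sum of their six per-category scores; the
predicted class is the one with the larger total.  Because the per-class
sum is an affine transform of the class log-likelihood
(S_g = 10 * (lg P_g + #factors)), the rule is the prior-free
maximum-likelihood decision over classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Mapping

import pandas as pd

from .frequency import ClassConditionalFrequencyTable
from .scheme import CLASS_LABELS, ClassLabel, PatientProfile, RiskFactorScheme

SCORE_SCALE = 10.0
#: Offset added to log10 P before scaling; makes P = 0.1 score zero.
SCORE_OFFSET = 1.0

TiePolicy = Literal["positive", "negative"]
Precision = Literal["display", "full"]


class ScoringError(ValueError):
    """Raised for zero-probability cells, non-finite scores and the like."""


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (the convention of the
    published score table), rather than Python's banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)


def score_from_probability(p: float) -> float:
    """(log10 p + 1) × 10; raises on p <= 0."""
    if p <= 0:
        raise ScoringError("log of zero probability")
    return (math.log10(p) + SCORE_OFFSET) * SCORE_SCALE


@dataclass(frozen=True)
class ScoreTable:
    """Per-category, per-class score points at full precision.

    Display and serialization round to one decimal (half away from zero);
    arithmetic uses the stored values.
    """

    scheme: RiskFactorScheme
    scores: Mapping[tuple[str, str, ClassLabel], float]

    def score(self, factor: str, category: str, g: ClassLabel) -> float:
        key = (factor, category, ClassLabel.coerce(g))
        try:
            return self.scores[key]
        except KeyError:
            raise KeyError(f"no score for ({factor!r}, {category!r}, {key[2].value})") from None

    def rounded(self) -> "ScoreTable":
        """Copy with every cell rounded to 1 decimal (printed-table form)."""
        return ScoreTable(
            scheme=self.scheme,
            scores={k: round_half_away(v) for k, v in self.scores.items()},
        )

    def to_frame(self, decimals: int | None = 1) -> pd.DataFrame:
        rows = []
        for factor in self.scheme.factors:
            for cat in factor.categories:
                sp = self.score(factor.name, cat, ClassLabel.POSITIVE)
                sn = self.score(factor.name, cat, ClassLabel.NEGATIVE)
                if decimals is not None:
                    sp, sn = round_half_away(sp, decimals), round_half_away(sn, decimals)
                rows.append(
                    {
                        "factor": factor.name,
                        "category": cat,
                        "score_positive": sp,
                        "score_negative": sn,
                    }
                )
        return pd.DataFrame(rows)

    def max_abs_difference(self, other: "ScoreTable") -> float:
        """Largest |cell difference| over all shared cells."""
        return max(abs(self.scores[k] - other.scores[k]) for k in self.scores)


def fit_score_table(
    table: ClassConditionalFrequencyTable,
    smoothing: float | None = None,
) -> ScoreTable:
    """Fit the score table from class-conditional frequencies.

    Parameters
    ----------
    table
        Frequency table; every touched cell must have a positive count
        unless ``smoothing`` is given.
    smoothing
        Optional additive (Laplace) constant applied to counts, with each
        class total inflated by ``smoothing ×`` the factor's category
        count.  Needed only when some cell count is zero.

    Raises
    ------
    ScoringError
        On a zero count without smoothing, naming the offending cell.
    """
    source = table.smoothed(smoothing) if smoothing is not None else table
    scores: dict[tuple[str, str, ClassLabel], float] = {}
    for factor in table.scheme.factors:
        for cat in factor.categories:
            for g in CLASS_LABELS:
                p = source.conditional_frequency(factor.name, cat, g)
                if p <= 0:
                    raise ScoringError(
                        f"log of zero probability at ({factor.name!r}, {cat!r}, "
                        f"{g.value}); supply a smoothing constant"
                    )
                scores[(factor.name, cat, g)] = score_from_probability(p)
    return ScoreTable(scheme=table.scheme, scores=scores)


@dataclass(frozen=True)
class DiscriminantResult:
    """Both class totals and the decision for one patient."""

    s_positive: float
    s_negative: float
    predicted: ClassLabel
    tie_broken: bool
    patient_id: str | None = None

    @property
    def margin(self) -> float:
        return self.s_positive - self.s_negative


def classify(
    s_positive: float,
    s_negative: float,
    tie_policy: TiePolicy = "positive",
) -> tuple[ClassLabel, bool]:
    """Larger total wins; exact ties go to ``tie_policy`` and are flagged.

    The positive default is the clinically conservative choice: when the
    evidence is exactly balanced the patient is flagged as metastatic.
    """
    if not (math.isfinite(s_positive) and math.isfinite(s_negative)):
        raise ScoringError(f"non-finite scores: {s_positive!r}, {s_negative!r}")
    if s_positive > s_negative:
        return ClassLabel.POSITIVE, False
    if s_positive < s_negative:
        return ClassLabel.NEGATIVE, False
    return ClassLabel.coerce(tie_policy), True


def score_patient(
    profile: PatientProfile,
    scores: ScoreTable,
    tie_policy: TiePolicy = "positive",
    precision: Precision = "display",
    prior: float | None = None,
) -> DiscriminantResult:
    """Total both class scores for one patient and classify.

    Parameters
    ----------
    precision
        ``"display"`` (default) sums per-category scores rounded to one
        decimal — the arithmetic a clinician does with the printed table,
        and the convention that reproduces the published worked example
        exactly.  ``"full"`` sums the unrounded cells, which keeps the
        decision identical to the class log-likelihood comparison.
    prior
        Optional positive-class prior probability; when given, each class
        total is shifted by ``10 × log10`` of its prior, turning the
        maximum-likelihood rule into a maximum-posterior rule.  Off by
        default, matching the prior-free published rule.
    """
    scores.scheme.validate_assignment(profile.categories)
    totals = {}
    for g in CLASS_LABELS:
        cells = [
            scores.score(f.name, profile.categories[f.name], g)
            for f in scores.scheme.factors
        ]
        if precision == "display":
            cells = [round_half_away(c) for c in cells]
        total = math.fsum(cells)
        if prior is not None:
            if not 0 < prior < 1:
                raise ScoringError(f"prior must be in (0, 1), got {prior}")
            p_g = prior if g is ClassLabel.POSITIVE else 1.0 - prior
            total += SCORE_SCALE * math.log10(p_g)
        totals[g] = total
    predicted, tie = classify(
        totals[ClassLabel.POSITIVE], totals[ClassLabel.NEGATIVE], tie_policy
    )
    return DiscriminantResult(
        s_positive=totals[ClassLabel.POSITIVE],
        s_negative=totals[ClassLabel.NEGATIVE],
        predicted=predicted,
        tie_broken=tie,
        patient_id=profile.patient_id,
    )


def log_joint_probability(
    profile: PatientProfile,
    table: ClassConditionalFrequencyTable,
    g: ClassLabel,
) -> float:
    """lg P_g = Σ_k log10 P(X_k | Y_g), the class log-likelihood.

    Satisfies S_g = (lg P_g + #factors) × 10 when S_g is summed at full
    precision, so classification by either quantity agrees.
    """
    g = ClassLabel.coerce(g)
    table.scheme.validate_assignment(profile.categories)
    total = 0.0
    for f in table.scheme.factors:
        p = table.conditional_frequency(f.name, profile.categories[f.name], g)
        if p <= 0:
            raise ScoringError(
                f"log of zero probability at ({f.name!r}, "
                f"{profile.categories[f.name]!r}, {g.value})"
            )
        total += math.log10(p)
    return total
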