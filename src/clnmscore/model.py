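"""Model/results interface to the CLNM risk discriminant.

`CLNMDiscriminant` wraps a class-conditional frequency table the way a
regression model wraps its design matrix; `fit` estimates the per-category
score table and returns a `CLNMDiscriminantResults` carrying the
estimates, prediction, simulation and summary methods.

Example
-------
>>> from clnmscore import CLNMDiscriminant
>>> model = CLNMDiscriminant.retrospective()
>>> res = model.fit()
>>> pred = res.predict_raw({"sex": "male", "age": 28, "tumor_diameter": 1.6,
...                         "capsular_invasion": "N", "multifocality": "N",
...                         "tumor_location": "lower pole"})
>>> round(pred.s_positive, 1), round(pred.s_negative, 1), pred.predicted.value
(37.0, 30.2, 'positive')
"""

from __future__ import annotations

from typing import Any, Iterable, Mapping, Sequence

import pandas as pd

from .evaluation import (
    CoincidenceReport,
    build_confusion,
    coincidence_rates,
)
from .frequency import ClassConditionalFrequencyTable, tabulate_cohort
from .scheme import ClassLabel, PatientProfile, RiskFactorScheme, bin_patient
from .scoring import (
    DiscriminantResult,
    Precision,
    ScoreTable,
    TiePolicy,
    fit_score_table,
    round_half_away,
    score_patient,
)
from .simulate import (
    GenerativeSpec,
    enumerate_expected_performance,
    generate_cohort,
)


class CLNMDiscriminant:
    """Maximum-likelihood discriminant over categorical risk factors.

    Parameters
    ----------
    table
        Class-conditional frequency table of the risk factors; the
        training data in aggregated form.
    """

    def __init__(self, table: ClassConditionalFrequencyTable):
        self.table = table
        self.scheme: RiskFactorScheme = table.scheme

    @classmethod
    def retrospective(cls) -> "CLNMDiscriminant":
        """Model on the bundled retrospective frequency distribution."""
        from .io import load_retrospective_frequencies

        return cls(load_retrospective_frequencies())

    @classmethod
    def from_cohort(
        cls,
        profiles: Iterable[PatientProfile],
        labels: Iterable[ClassLabel],
        scheme: RiskFactorScheme,
    ) -> "CLNMDiscriminant":
        """Model from patient-level records, tabulated per class."""
        return cls(tabulate_cohort(profiles, labels, scheme))

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, scheme: RiskFactorScheme | None = None
    ) -> "CLNMDiscriminant":
        """Model from a ``factor,category,count_positive,count_negative`` frame."""
        return cls(ClassConditionalFrequencyTable.from_frame(frame, scheme=scheme))

    def fit(self, smoothing: float | None = None) -> "CLNMDiscriminantResults":
        """Estimate the score table; see :func:`clnmscore.fit_score_table`."""
        scores = fit_score_table(self.table, smoothing=smoothing)
        return CLNMDiscriminantResults(self, scores, smoothing=smoothing)


class CLNMDiscriminantResults:
    """Fitted score table plus prediction, evaluation and simulation."""

    def __init__(
        self,
        model: CLNMDiscriminant,
        score_table: ScoreTable,
        smoothing: float | None = None,
    ):
        self.model = model
        self.score_table = score_table
        self.smoothing = smoothing

    @property
    def params(self) -> pd.DataFrame:
        """Score-table cells at full precision, one row per category."""
        return self.score_table.to_frame(decimals=None)

    # -- prediction -------------------------------------------------------

    def predict_one(
        self,
        profile: PatientProfile,
        tie_policy: TiePolicy = "positive",
        precision: Precision = "display",
        prior: float | None = None,
    ) -> DiscriminantResult:
        return score_patient(
            profile, self.score_table, tie_policy=tie_policy,
            precision=precision, prior=prior,
        )

    def predict_raw(
        self, raw_attributes: Mapping[str, Any], **kwargs: Any
    ) -> DiscriminantResult:
        """Bin raw clinical attributes with the scheme, then score."""
        return self.predict_one(bin_patient(raw_attributes, self.model.scheme), **kwargs)

    def predict(
        self,
        profiles: Sequence[PatientProfile],
        tie_policy: TiePolicy = "positive",
        precision: Precision = "display",
        prior: float | None = None,
    ) -> pd.DataFrame:
        """Score a cohort; one row per patient with both class totals."""
        rows = []
        for p in profiles:
            r = self.predict_one(p, tie_policy=tie_policy, precision=precision, prior=prior)
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "s_positive": r.s_positive,
                    "s_negative": r.s_negative,
                    "margin": r.margin,
                    "predicted": r.predicted.value,
                    "tie_broken": r.tie_broken,
                }
            )
        return pd.DataFrame(rows)

    # -- evaluation -------------------------------------------------------

    def evaluate(
        self,
        profiles: Sequence[PatientProfile],
        truths: Sequence[ClassLabel],
        **kwargs: Any,
    ) -> CoincidenceReport:
        """Coincidence rates of the fitted rule on a labelled cohort."""
        preds = [self.predict_one(p, **kwargs).predicted for p in profiles]
        return coincidence_rates(build_confusion(list(truths), preds))

    def expected_performance(
        self,
        prevalence: float | None = None,
        tie_policy: TiePolicy = "positive",
        precision: Precision = "display",
    ):
        """Exact expected coincidence rates under the generative model
        the rule assumes (class-conditionally independent factors)."""
        prev = prevalence if prevalence is not None else self.model.table.prevalence()
        return enumerate_expected_performance(
            self.model.table, prev, self.score_table,
            tie_policy=tie_policy, precision=precision,
        )

    def simulate(
        self, n: int, prevalence: float | None = None, seed: int = 0
    ) -> tuple[list[PatientProfile], list[ClassLabel]]:
        """Draw a synthetic cohort from the fitted frequency table."""
        prev = prevalence if prevalence is not None else self.model.table.prevalence()
        spec = GenerativeSpec(table=self.model.table, prevalence=prev, n=n, seed=seed)
        return generate_cohort(spec)

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        """Plain-text score table in the layout of the published one."""
        lines = [
            "CLNM risk-factor discriminant — score table",
            f"classes: positive (N={self.model.table.class_totals[ClassLabel.POSITIVE]}) / "
            f"negative (N={self.model.table.class_totals[ClassLabel.NEGATIVE]})",
            f"smoothing: {self.smoothing if self.smoothing is not None else 'none'}",
            "",
            f"{'factor':<14}{'category':<12}{'score +':>9}{'score -':>9}",
        ]
        for factor in self.model.scheme.factors:
            for cat in factor.categories:
                sp = round_half_away(self.score_table.score(factor.name, cat, ClassLabel.POSITIVE))
                sn = round_half_away(self.score_table.score(factor.name, cat, ClassLabel.NEGATIVE))
                lines.append(f"{factor.name:<14}{cat:<12}{sp:>9.1f}{sn:>9.1f}")
        return "\n".join(lines)
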