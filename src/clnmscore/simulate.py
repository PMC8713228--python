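"""Synthetic cohorts and exact expected performance of the discriminant.

The generator draws patients from the generative model the scoring rule
itself assumes: a Bernoulli class label at a stated prevalence, then each
factor's category independently from that class's conditional frequencies.
Because no patient-level data accompany the published frequency table,
cohorts drawn this way stand in for the original records; they share the
marginal class-conditional frequencies but, by construction, carry no
between-factor dependence.

`enumerate_expected_performance` computes the classifier's exact expected
per-class coincidence rates under the same generative model by summing
over every category combination — an oracle the sampler can be checked
against without Monte-Carlo error.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .frequency import ClassConditionalFrequencyTable, FrequencyTableError, tabulate_cohort
from .scheme import CLASS_LABELS, ClassLabel, PatientProfile, RiskFactorScheme
from .scoring import Precision, ScoreTable, TiePolicy, score_patient

#: Retrospective positive-class prevalence (197 metastatic of 412).
RETROSPECTIVE_PREVALENCE = 197 / 412
#: Prospective-cohort alternative (41 metastatic of 104).
PROSPECTIVE_PREVALENCE = 41 / 104

DEFAULT_ENUMERATION_CAP = 10**6


@dataclass(frozen=True)
class GenerativeSpec:
    """Parameters of the synthetic-cohort generative model.

    The frequency table supplies the class-conditional category
    probabilities; ``prevalence`` is the marginal probability of the
    positive class; ``n`` the cohort size; ``seed`` makes draws
    reproducible.
    """

    table: ClassConditionalFrequencyTable
    prevalence: float = RETROSPECTIVE_PREVALENCE
    n: int = 412
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError(f"prevalence must be in (0, 1), got {self.prevalence}")
        if self.n < 1:
            raise ValueError(f"cohort size must be >= 1, got {self.n}")


def generate_cohort(spec: GenerativeSpec) -> tuple[list[PatientProfile], list[ClassLabel]]:
    """Draw a synthetic cohort.

    Reproducibility contract: from a fresh ``numpy`` generator seeded with
    ``spec.seed``, one uniform vector decides all class labels, then one
    uniform vector per factor, in scheme order, decides categories via the
    class-specific inverse CDF.  Identical specs give identical cohorts.
    """
    rng = np.random.default_rng(spec.seed)
    scheme = spec.table.scheme
    labels_pos = rng.random(spec.n) < spec.prevalence
    labels = [ClassLabel.POSITIVE if b else ClassLabel.NEGATIVE for b in labels_pos]

    assigned: list[dict[str, str]] = [{} for _ in range(spec.n)]
    for factor in scheme.factors:
        u = rng.random(spec.n)
        for g, mask in (
            (ClassLabel.POSITIVE, labels_pos),
            (ClassLabel.NEGATIVE, ~labels_pos),
        ):
            probs = np.array(
                [spec.table.conditional_frequency(factor.name, c, g) for c in factor.categories]
            )
            cdf = np.cumsum(probs)
            cdf[-1] = 1.0  # guard against round-off excluding the last category
            idx = np.searchsorted(cdf, u[mask], side="right")
            idx = np.minimum(idx, len(factor.categories) - 1)
            for patient_i, cat_i in zip(np.nonzero(mask)[0], idx):
                assigned[patient_i][factor.name] = factor.categories[cat_i]

    profiles = [
        PatientProfile(categories=cats, patient_id=f"synth-{i:06d}")
        for i, cats in enumerate(assigned)
    ]
    return profiles, labels


def recover_frequencies(
    profiles: list[PatientProfile],
    labels: list[ClassLabel],
    scheme: RiskFactorScheme,
) -> ClassConditionalFrequencyTable:
    """Tabulate a cohort back into a class-conditional frequency table.

    Closes the fit → simulate → refit loop: at large n the recovered
    conditional frequencies concentrate on the generating ones.
    """
    return tabulate_cohort(profiles, labels, scheme)


@dataclass(frozen=True)
class ExpectedPerformance:
    """Exact expected confusion-cell proportions and coincidence rates."""

    p_tp: float
    p_fn: float
    p_fp: float
    p_tn: float
    rate_positive: float
    rate_negative: float
    rate_mean: float
    overall_accuracy: float
    tie_probability: float


def enumerate_expected_performance(
    table: ClassConditionalFrequencyTable,
    prevalence: float,
    scores: ScoreTable,
    tie_policy: TiePolicy = "positive",
    precision: Precision = "display",
    max_combinations: int = DEFAULT_ENUMERATION_CAP,
) -> ExpectedPerformance:
    """Exact expected performance by exhaustive enumeration.

    Iterates every complete category combination (320 for the six-factor
    scheme), weights it by its class-conditional probability times the
    class prior, classifies it with the score table, and accumulates the
    expected confusion-cell proportions.  Deterministic — no sampling.

    Raises
    ------
    FrequencyTableError
        If the combinatorial space exceeds ``max_combinations``.
    """
    if not 0 < prevalence < 1:
        raise ValueError(f"prevalence must be in (0, 1), got {prevalence}")
    scheme = table.scheme
    if scheme.n_profiles > max_combinations:
        raise FrequencyTableError(
            f"enumeration over {scheme.n_profiles} combinations exceeds the "
            f"cap of {max_combinations}; raise max_combinations to proceed"
        )
    priors = {
        ClassLabel.POSITIVE: prevalence,
        ClassLabel.NEGATIVE: 1.0 - prevalence,
    }
    cells = {"tp": 0.0, "fn": 0.0, "fp": 0.0, "tn": 0.0}
    tie_mass = 0.0
    for combo in itertools.product(*(f.categories for f in scheme.factors)):
        profile = PatientProfile(categories=dict(zip(scheme.factor_names, combo)))
        result = score_patient(profile, scores, tie_policy=tie_policy, precision=precision)
        for g in CLASS_LABELS:
            p_combo = priors[g]
            for f, cat in zip(scheme.factors, combo):
                p_combo *= table.conditional_frequency(f.name, cat, g)
            if result.tie_broken:
                tie_mass += p_combo
            correct = result.predicted is g
            if g is ClassLabel.POSITIVE:
                cells["tp" if correct else "fn"] += p_combo
            else:
                cells["tn" if correct else "fp"] += p_combo
    p_pos = cells["tp"] + cells["fn"]
    p_neg = cells["fp"] + cells["tn"]
    rate_pos = 100.0 * cells["tp"] / p_pos
    rate_neg = 100.0 * cells["tn"] / p_neg
    return ExpectedPerformance(
        p_tp=cells["tp"],
        p_fn=cells["fn"],
        p_fp=cells["fp"],
        p_tn=cells["tn"],
        rate_positive=rate_pos,
        rate_negative=rate_neg,
        rate_mean=(rate_pos + rate_neg) / 2.0,
        overall_accuracy=100.0 * (cells["tp"] + cells["tn"]),
        tie_probability=tie_mass,
    )
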