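"""Class-conditional frequency tables of categorical risk factors.

The table stores, for every (factor, category, class) cell, the number of
patients of that class falling in that category, together with the class
totals N_g.  Conditional frequencies P(category | class) are the maximum-
likelihood estimates count / N_g.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .scheme import CLASS_LABELS, ClassLabel, RiskFactorScheme, SchemeError

CountKey = tuple[str, str, ClassLabel]


class FrequencyTableError(ValueError):
    """Raised when counts violate the frequency-table invariants."""


@dataclass(frozen=True)
class ClassConditionalFrequencyTable:
    """Counts n(k, j, g) per factor k, category j, class g.

    Invariants enforced at construction: every (factor, class) block sums
    to the same class total N_g, and N_g > 0 for both classes.
    """

    scheme: RiskFactorScheme
    counts: Mapping[CountKey, int]
    class_totals: Mapping[ClassLabel, int]

    def __post_init__(self) -> None:
        for g in CLASS_LABELS:
            if g not in self.class_totals:
                raise FrequencyTableError(f"missing class total for {g.value}")
            if self.class_totals[g] <= 0:
                raise FrequencyTableError(f"class total for {g.value} must be positive")
        for factor in self.scheme.factors:
            for g in CLASS_LABELS:
                block = 0
                for cat in factor.categories:
                    c = self.counts.get((factor.name, cat, g))
                    if c is None:
                        raise FrequencyTableError(
                            f"missing count for ({factor.name}, {cat}, {g.value})"
                        )
                    if c < 0 or c != int(c):
                        raise FrequencyTableError(
                            f"count for ({factor.name}, {cat}, {g.value}) "
                            f"must be a non-negative integer, got {c!r}"
                        )
                    block += c
                if block != self.class_totals[g]:
                    raise FrequencyTableError(
                        f"factor {factor.name!r} {g.value} block sums to {block}, "
                        f"expected class total {self.class_totals[g]}"
                    )

    @classmethod
    def from_counts(
        cls,
        scheme: RiskFactorScheme,
        counts: Mapping[CountKey, int],
    ) -> "ClassConditionalFrequencyTable":
        """Build a table deriving class totals from the first factor block."""
        totals: dict[ClassLabel, int] = {}
        first = scheme.factors[0]
        for g in CLASS_LABELS:
            totals[g] = sum(counts.get((first.name, cat, g), 0) for cat in first.categories)
        return cls(scheme=scheme, counts=dict(counts), class_totals=totals)

    def count(self, factor: str, category: str, g: ClassLabel) -> int:
        key = (factor, category, ClassLabel.coerce(g))
        try:
            return self.counts[key]
        except KeyError:
            raise KeyError(f"no cell ({factor!r}, {category!r}, {key[2].value})") from None

    def conditional_frequency(self, factor: str, category: str, g: ClassLabel) -> float:
        """P(X_kj | Y_g) = n(k, j, g) / N_g."""
        g = ClassLabel.coerce(g)
        return self.count(factor, category, g) / self.class_totals[g]

    def conditional_distribution(self, factor: str, g: ClassLabel) -> dict[str, float]:
        """All category frequencies of one factor under one class."""
        f = self.scheme.factor(factor)
        return {cat: self.conditional_frequency(factor, cat, g) for cat in f.categories}

    def smoothed(self, alpha: float) -> "ClassConditionalFrequencyTable":
        """Additively smoothed conditional frequencies.

        Adds ``alpha`` to every cell count; class totals are kept per-factor
        consistent by scaling each block back to a common pseudo-total
        (the original N_g plus alpha times that factor's category count is
        factor-dependent, so smoothing is applied at the probability level:
        P = (n + alpha) / (N_g + alpha * n_categories_of_factor)).

        Returns a lightweight view exposing :meth:`conditional_frequency`
        with the smoothed estimates; counts stay integral in ``self``.
        """
        if alpha < 0:
            raise FrequencyTableError("smoothing constant must be >= 0")
        return _SmoothedView(self, alpha)  # type: ignore[return-value]

    # -- cohort-level summaries ------------------------------------------

    @property
    def cohort_size(self) -> int:
        return sum(self.class_totals[g] for g in CLASS_LABELS)

    def prevalence(self) -> float:
        """Positive-class fraction N_+ / (N_+ + N_−)."""
        return self.class_totals[ClassLabel.POSITIVE] / self.cohort_size

    # -- dataframe interop ------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for factor in self.scheme.factors:
            for cat in factor.categories:
                rows.append(
                    {
                        "factor": factor.name,
                        "category": cat,
                        "count_positive": self.count(factor.name, cat, ClassLabel.POSITIVE),
                        "count_negative": self.count(factor.name, cat, ClassLabel.NEGATIVE),
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, scheme: RiskFactorScheme | None = None
    ) -> "ClassConditionalFrequencyTable":
        """Build from a dataframe with factor/category/count_± columns.

        If ``scheme`` is omitted, one is inferred from the row order (no
        binning rules attached).
        """
        required = {"factor", "category", "count_positive", "count_negative"}
        missing = required - set(frame.columns)
        if missing:
            raise FrequencyTableError(f"missing columns: {sorted(missing)}")
        if scheme is None:
            from .scheme import Factor

            factors = []
            for name, block in frame.groupby("factor", sort=False):
                factors.append(Factor(str(name), tuple(str(c) for c in block["category"])))
            scheme = RiskFactorScheme(tuple(factors))
        counts: dict[CountKey, int] = {}
        for _, row in frame.iterrows():
            for g, col in (
                (ClassLabel.POSITIVE, "count_positive"),
                (ClassLabel.NEGATIVE, "count_negative"),
            ):
                value = row[col]
                if pd.isna(value) or float(value) != int(value):
                    raise FrequencyTableError(
                        f"non-integer count {value!r} at ({row['factor']}, {row['category']})"
                    )
                counts[(str(row["factor"]), str(row["category"]), g)] = int(value)
        return cls.from_counts(scheme, counts)


class _SmoothedView:
    """Conditional-frequency view with additive (Laplace) smoothing."""

    def __init__(self, base: ClassConditionalFrequencyTable, alpha: float):
        self._base = base
        self.alpha = alpha
        self.scheme = base.scheme
        self.class_totals = base.class_totals

    def conditional_frequency(self, factor: str, category: str, g: ClassLabel) -> float:
        g = ClassLabel.coerce(g)
        n_cat = len(self.scheme.factor(factor).categories)
        n = self._base.count(factor, category, g)
        return (n + self.alpha) / (self._base.class_totals[g] + self.alpha * n_cat)

    def prevalence(self) -> float:
        return self._base.prevalence()


def tabulate_cohort(
    profiles: Iterable,
    labels: Iterable[ClassLabel],
    scheme: RiskFactorScheme,
) -> ClassConditionalFrequencyTable:
    """Tabulate patient-level records into a frequency table.

    Every (factor, category, class) cell is the number of patients of that
    class assigned to that category.  Both classes must be represented.
    """
    profiles = list(profiles)
    labels = [ClassLabel.coerce(g) for g in labels]
    if not profiles:
        raise FrequencyTableError("empty cohort")
    if len(profiles) != len(labels):
        raise FrequencyTableError("profiles and labels differ in length")
    present = set(labels)
    for g in CLASS_LABELS:
        if g not in present:
            raise FrequencyTableError(f"class {g.value!r} absent from cohort labels")
    counts: dict[CountKey, int] = {
        (f.name, cat, g): 0
        for f in scheme.factors
        for cat in f.categories
        for g in CLASS_LABELS
    }
    for profile, g in zip(profiles, labels):
        scheme.validate_assignment(profile.categories)
        for f in scheme.factors:
            counts[(f.name, profile.categories[f.name], g)] += 1
    return ClassConditionalFrequencyTable.from_counts(scheme, counts)
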