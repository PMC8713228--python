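"""Risk-factor schemes, category binning, and patient profiles.

A :class:`RiskFactorScheme` is an ordered collection of categorical risk
factors.  Each factor carries its ordered category labels and, optionally,
a *binning rule* that maps a raw clinical attribute (a number, a flag, or a
controlled-vocabulary string) onto exactly one category label.  The bundled
scheme for papillary thyroid cancer (PTC) central-compartment lymph node
metastasis (CLNM) has six factors — sex, age, tumor diameter, capsular
invasion, multifocality, tumor location — with 17 categories in total.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping


class SchemeError(ValueError):
    """Raised when a scheme, profile, or raw attribute set is invalid."""


class ClassLabel(enum.Enum):
    """Central-compartment lymph node status: metastatic (+) or not (−)."""

    POSITIVE = "positive"
    NEGATIVE = "negative"

    @property
    def symbol(self) -> str:
        return "+" if self is ClassLabel.POSITIVE else "-"

    @property
    def other(self) -> "ClassLabel":
        return ClassLabel.NEGATIVE if self is ClassLabel.POSITIVE else ClassLabel.POSITIVE

    @classmethod
    def coerce(cls, value: Any) -> "ClassLabel":
        if isinstance(value, cls):
            return value
        text = str(value).strip().lower()
        if text in {"positive", "+", "pos", "1", "true", "y"}:
            return cls.POSITIVE
        if text in {"negative", "-", "−", "neg", "0", "false", "n"}:
            return cls.NEGATIVE
        raise SchemeError(f"unrecognized class label: {value!r}")


CLASS_LABELS = (ClassLabel.POSITIVE, ClassLabel.NEGATIVE)


@dataclass(frozen=True)
class Factor:
    """One categorical risk factor.

    Parameters
    ----------
    name
        Factor name, unique within a scheme.
    categories
        Ordered, unique category labels (at least two).
    binner
        Optional total function mapping an admissible raw attribute value
        to one of ``categories``.
    raw_attribute
        Name of the raw attribute the binner consumes (e.g. ``"age"``).
    """

    name: str
    categories: tuple[str, ...]
    binner: Callable[[Any], str] | None = field(default=None, compare=False)
    raw_attribute: str | None = None

    def __post_init__(self) -> None:
        if len(self.categories) < 2:
            raise SchemeError(f"factor {self.name!r} needs >=2 categories")
        if len(set(self.categories)) != len(self.categories):
            raise SchemeError(f"factor {self.name!r} has duplicate category labels")

    def bin(self, raw_value: Any) -> str:
        if self.binner is None:
            raise SchemeError(f"factor {self.name!r} has no binning rule")
        label = self.binner(raw_value)
        if label not in self.categories:
            raise SchemeError(
                f"binning rule for {self.name!r} produced unknown category {label!r}"
            )
        return label


@dataclass(frozen=True)
class RiskFactorScheme:
    """Ordered set of categorical risk factors."""

    factors: tuple[Factor, ...]

    def __post_init__(self) -> None:
        if not self.factors:
            raise SchemeError("a scheme needs at least one factor")
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise SchemeError("factor names must be unique")

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    def factor(self, name: str) -> Factor:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(f"unknown factor {name!r}")

    @property
    def n_categories(self) -> int:
        return sum(len(f.categories) for f in self.factors)

    @property
    def n_profiles(self) -> int:
        """Number of distinct complete category combinations."""
        n = 1
        for f in self.factors:
            n *= len(f.categories)
        return n

    def validate_assignment(self, categories: Mapping[str, str]) -> None:
        for f in self.factors:
            if f.name not in categories:
                raise SchemeError(f"profile missing factor {f.name!r}")
            if categories[f.name] not in f.categories:
                raise SchemeError(
                    f"category {categories[f.name]!r} not valid for factor {f.name!r}"
                )
        extra = set(categories) - set(self.factor_names)
        if extra:
            raise SchemeError(f"profile has unknown factors: {sorted(extra)}")


@dataclass(frozen=True)
class PatientProfile:
    """One category per factor of a scheme, plus optional identifier."""

    categories: Mapping[str, str]
    patient_id: str | None = None

    def category(self, factor_name: str) -> str:
        return self.categories[factor_name]

    def as_tuple(self, scheme: RiskFactorScheme) -> tuple[str, ...]:
        return tuple(self.categories[name] for name in scheme.factor_names)


# ---------------------------------------------------------------------------
# The six-factor PTC/CLNM scheme
# ---------------------------------------------------------------------------

LOCATIONS = ("Upper pole", "Middle pole", "Lower pole", "Isthmus")

#: Raw attribute names consumed by :func:`bin_patient` for the bundled scheme.
RAW_ATTRIBUTES = (
    "sex",
    "age",
    "tumor_diameter",
    "capsular_invasion",
    "multifocality",
    "tumor_location",
)


def _bin_sex(value: Any) -> str:
    text = str(value).strip().lower()
    if text in {"m", "male"}:
        return "Male"
    if text in {"f", "female"}:
        return "Female"
    raise SchemeError(f"sex must be male/female, got {value!r}")


def _bin_age(value: Any) -> str:
    age = float(value)
    if age < 0:
        raise SchemeError(f"age must be >= 0 years, got {age}")
    return "<45 yrs" if age < 45 else "≥45 yrs"


# Tumor-diameter bins are half-open [lo, hi) so every diameter maps uniquely;
# the upper bin is closed below at 2.0 cm and unbounded above.
_DIAMETER_EDGES = (0.7, 1.0, 1.5, 2.0)
_DIAMETER_LABELS = ("<0.7 cm", "0.7-1.0 cm", "1.0-1.5 cm", "1.5-2.0 cm", "≥2.0 cm")


def _bin_diameter(value: Any) -> str:
    d = float(value)
    if d <= 0:
        raise SchemeError(f"tumor_diameter must be > 0 cm, got {d}")
    for edge, label in zip(_DIAMETER_EDGES, _DIAMETER_LABELS):
        if d < edge:
            return label
    return _DIAMETER_LABELS[-1]


def _bin_flag(value: Any) -> str:
    if isinstance(value, bool):
        return "Y" if value else "N"
    text = str(value).strip().lower()
    if text in {"y", "yes", "true", "1"}:
        return "Y"
    if text in {"n", "no", "false", "0"}:
        return "N"
    raise SchemeError(f"flag must be yes/no, got {value!r}")


def _bin_location(value: Any) -> str:
    text = str(value).strip().lower()
    for label in LOCATIONS:
        if text == label.lower() or text == label.split()[0].lower():
            return label
    raise SchemeError(
        f"tumor_location must be one of {LOCATIONS}, got {value!r}"
    )


def ptc_scheme() -> RiskFactorScheme:
    """The six-factor CLNM risk scheme with its clinical binning rules.

    Category labels match the published frequency table exactly, so fitted
    and bundled tables are directly comparable.
    """
    return RiskFactorScheme(
        factors=(
            Factor("Sex", ("Female", "Male"), _bin_sex, "sex"),
            Factor("Age", ("<45 yrs", "≥45 yrs"), _bin_age, "age"),
            Factor("TD", _DIAMETER_LABELS, _bin_diameter, "tumor_diameter"),
            Factor("CI", ("Y", "N"), _bin_flag, "capsular_invasion"),
            Factor("Multifocality", ("Y", "N"), _bin_flag, "multifocality"),
            Factor("TL", LOCATIONS, _bin_location, "tumor_location"),
        )
    )


def bin_patient(
    raw_attributes: Mapping[str, Any],
    scheme: RiskFactorScheme | None = None,
    patient_id: str | None = None,
) -> PatientProfile:
    """Map raw clinical attributes onto one category per factor.

    Parameters
    ----------
    raw_attributes
        Mapping with one entry per factor's declared raw attribute; for
        the bundled scheme: ``sex``, ``age`` (years), ``tumor_diameter``
        (cm), ``capsular_invasion``, ``multifocality``, ``tumor_location``.
    scheme
        Defaults to :func:`ptc_scheme`.

    Raises
    ------
    SchemeError
        If an attribute is missing or outside its admissible domain; the
        message names the offending attribute.
    """
    scheme = scheme or ptc_scheme()
    categories: dict[str, str] = {}
    for factor in scheme.factors:
        attr = factor.raw_attribute or factor.name
        if attr not in raw_attributes or raw_attributes[attr] is None:
            raise SchemeError(f"missing raw attribute {attr!r} for factor {factor.name!r}")
        categories[factor.name] = factor.bin(raw_attributes[attr])
    return PatientProfile(categories=categories, patient_id=patient_id)
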