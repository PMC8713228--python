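"""Delimited-text readers/writers and the bundled reference tables.

All formats are UTF-8 CSV with a mandatory header and "." decimal point.
Category labels in the bundled fixtures match the published tables
character for character (including "≥"), so files are greppable against
the source.

Formats
-------
frequency table : ``factor,category,count_positive,count_negative``
score table     : ``factor,category,score_positive,score_negative`` at one
                  decimal; fitted tables also write a ``*-full.csv``
                  variant at full precision alongside.
cohort          : ``patient_id,<one column per factor>,true_class``
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .frequency import ClassConditionalFrequencyTable, FrequencyTableError
from .scheme import ClassLabel, PatientProfile, RiskFactorScheme, ptc_scheme
from .scoring import ScoreTable

FREQUENCY_HEADER = ["factor", "category", "count_positive", "count_negative"]
SCORE_HEADER = ["factor", "category", "score_positive", "score_negative"]


class ParseError(ValueError):
    pass


def _read_csv(path: str | Path, expected_header: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file") from None
    if list(frame.columns) != expected_header:
        raise ParseError(
            f"{path}:1: header {list(frame.columns)} does not match {expected_header}"
        )
    return frame


def read_frequency_table(
    path: str | Path, scheme: RiskFactorScheme | None = None
) -> ClassConditionalFrequencyTable:
    """Read a class-conditional frequency table, validating invariants.

    Per-factor column sums must agree on a common pair of class totals;
    a violating block is reported with the offending line range.
    """
    path = Path(path)
    frame = _read_csv(path, FREQUENCY_HEADER)
    for col in ("count_positive", "count_negative"):
        try:
            frame[col] = frame[col].astype(int)
        except (TypeError, ValueError) as exc:
            bad = frame[pd.to_numeric(frame[col], errors="coerce").isna()]
            line = int(bad.index[0]) + 2 if len(bad) else "?"
            raise ParseError(f"{path}:{line}: non-integer count in {col}") from exc
    try:
        return ClassConditionalFrequencyTable.from_frame(frame, scheme=scheme)
    except FrequencyTableError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_frequency_table(table: ClassConditionalFrequencyTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False, encoding="utf-8")


def read_score_table(
    path: str | Path, scheme: RiskFactorScheme | None = None
) -> ScoreTable:
    """Read a score table; values are taken at the file's precision."""
    path = Path(path)
    frame = _read_csv(path, SCORE_HEADER)
    if scheme is None:
        from .scheme import Factor

        factors = []
        for name, block in frame.groupby("factor", sort=False):
            factors.append(Factor(str(name), tuple(str(c) for c in block["category"])))
        scheme = RiskFactorScheme(tuple(factors))
    scores: dict[tuple[str, str, ClassLabel], float] = {}
    for i, row in frame.iterrows():
        for g, col in (
            (ClassLabel.POSITIVE, "score_positive"),
            (ClassLabel.NEGATIVE, "score_negative"),
        ):
            try:
                scores[(str(row["factor"]), str(row["category"]), g)] = float(row[col])
            except (TypeError, ValueError):
                raise ParseError(f"{path}:{int(i) + 2}: non-numeric score in {col}") from None
    return ScoreTable(scheme=scheme, scores=scores)


def write_score_table(
    scores: ScoreTable,
    path: str | Path,
    full_precision_path: str | Path | None = None,
) -> None:
    """Write a score table at 1-decimal display precision.

    If ``full_precision_path`` is given (or derivable as ``<stem>-full.csv``
    when ``write_full`` semantics are wanted), a variant with 12
    significant digits is written alongside for loss-free round-trips.
    """
    path = Path(path)
    scores.to_frame(decimals=1).to_csv(
        path, index=False, encoding="utf-8", float_format="%.1f"
    )
    if full_precision_path is not None:
        scores.to_frame(decimals=None).to_csv(
            Path(full_precision_path), index=False, encoding="utf-8", float_format="%.12g"
        )


def read_cohort(
    path: str | Path, scheme: RiskFactorScheme | None = None
) -> tuple[list[PatientProfile], list[ClassLabel]]:
    """Read a patient-level cohort file."""
    path = Path(path)
    scheme = scheme or ptc_scheme()
    expected = ["patient_id", *scheme.factor_names, "true_class"]
    frame = _read_csv(path, expected)
    profiles, labels = [], []
    for _, row in frame.iterrows():
        categories = {name: str(row[name]) for name in scheme.factor_names}
        scheme.validate_assignment(categories)
        profiles.append(PatientProfile(categories=categories, patient_id=str(row["patient_id"])))
        labels.append(ClassLabel.coerce(row["true_class"]))
    return profiles, labels


def write_cohort(
    profiles: list[PatientProfile],
    labels: list[ClassLabel],
    scheme: RiskFactorScheme,
    path: str | Path,
) -> None:
    rows = []
    for i, (p, g) in enumerate(zip(profiles, labels)):
        row = {"patient_id": p.patient_id or f"p{i:06d}"}
        row.update({name: p.categories[name] for name in scheme.factor_names})
        row["true_class"] = ClassLabel.coerce(g).value
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# Bundled reference tables
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("clnmscore.data").joinpath(name)


def load_retrospective_frequencies() -> ClassConditionalFrequencyTable:
    """The published retrospective frequency distribution (412 PTC cases,
    197 metastatic / 215 not), on the six-factor scheme with binning rules."""
    with resources.as_file(_data_path("retrospective_frequencies.csv")) as p:
        return read_frequency_table(p, scheme=ptc_scheme())


def load_published_scores() -> ScoreTable:
    """The published 1-decimal score table, as printed."""
    with resources.as_file(_data_path("published_scores.csv")) as p:
        return read_score_table(p, scheme=ptc_scheme())
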