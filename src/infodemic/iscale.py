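"""Infodemic-scale (I-scale) rubric: validation, scoring, severity classes.

An *infodemic moniker* is a term, query, hashtag, or phrase that generates or
feeds misinformation, misinterpretation, or discrimination online.  The
I-scale summarises how strongly a moniker does so: an analyst assigns 0-2
points in each of five categories —

* **generic** — the term confuses through lack of specificity
  (1 pt: a scientific term prone to misunderstanding, e.g. "COVID" for
  "COVID-19"; 2 pts: a blend of scientific terms confusable with earlier
  ones, e.g. "SARS-CoV" for "SARS-CoV-2");
* **misinformative** — the term is associated with fake news
  (1 pt: points at individuals; 2 pts: spreads claims from unrelated or
  unconfirmed sources);
* **discriminatory** — the term ties the disease to an ethnicity or region
  (1 pt: names a country; 2 pts: targets an ethnicity explicitly);
* **deviant** — the term pushes an opinion rather than identifying the
  phenomenon (1 pt: expresses an opinion; 2 pts: expresses an attitude meant
  to sway the public);
* **other specificities** — reserved for exceptionally serious cases
  (1 pt: real facts but serious health/economic risk; 2 pts: direct health
  risk).

The total score (0-10) maps onto five severity classes::

    0     not infodemic
    1     slightly infodemic
    2-4   moderately infodemic
    5-8   highly infodemic
    9-10  extremely infodemic

Point assignment is a human judgement.  This module validates annotations,
sums points and classifies; it never infers categories from keyword text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError

__all__ = [
    "CATEGORIES",
    "SEVERITIES",
    "SEVERITY_INTERVALS",
    "CategoryPoints",
    "MonikerAnnotation",
    "IScaleResult",
    "validate_annotation",
    "classify_severity",
    "score_moniker",
    "score_table",
    "read_annotations_csv",
    "write_scores_csv",
    "results_to_frame",
]

#: Rubric categories, in canonical order.
CATEGORIES = (
    "generic",
    "misinformative",
    "discriminatory",
    "deviant",
    "other_specificities",
)

#: Severity classes in increasing order of infodemicity.
SEVERITIES = ("not_infodemic", "slightly", "moderately", "highly", "extremely")

#: Closed score intervals per class; together they partition {0, ..., 10}.
SEVERITY_INTERVALS = {
    "not_infodemic": (0, 0),
    "slightly": (1, 1),
    "moderately": (2, 4),
    "highly": (5, 8),
    "extremely": (9, 10),
}

MAX_SCORE = 10


@dataclass(frozen=True)
class CategoryPoints:
    """Points (0-2 each) assigned in the five rubric categories."""

    generic: int = 0
    misinformative: int = 0
    discriminatory: int = 0
    deviant: int = 0
    other_specificities: int = 0

    def total(self) -> int:
        return sum(getattr(self, c) for c in CATEGORIES)

    def as_dict(self) -> dict[str, int]:
        return {c: getattr(self, c) for c in CATEGORIES}


@dataclass(frozen=True)
class MonikerAnnotation:
    """A moniker plus its analyst-assigned rubric points."""

    moniker: str
    points: CategoryPoints
    rationale: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class IScaleResult:
    """Scored moniker: total I-scale score and severity class."""

    moniker: str
    score: int
    severity: str


def validate_annotation(annotation: MonikerAnnotation) -> MonikerAnnotation:
    """Return ``annotation`` unchanged if it satisfies the rubric contract.

    Raises
    ------
    ValidationError
        If the moniker is empty after trimming, or any category point is
        not an integer in {0, 1, 2} (the offending category is named).
    """
    if not annotation.moniker or not annotation.moniker.strip():
        raise ValidationError("empty moniker")
    for cat in CATEGORIES:
        v = getattr(annotation.points, cat)
        if not isinstance(v, int) or isinstance(v, bool) or v not in (0, 1, 2):
            raise ValidationError(f"{cat} out of range: {v!r} (must be 0, 1 or 2)")
    return annotation


def classify_severity(score: int) -> str:
    """Map an integer I-scale score in [0, 10] to its severity class."""
    if not isinstance(score, int) or isinstance(score, bool):
        raise ValidationError(f"score must be an integer, got {score!r}")
    if not 0 <= score <= MAX_SCORE:
        raise ValidationError(f"score {score} outside [0, {MAX_SCORE}]")
    for severity, (lo, hi) in SEVERITY_INTERVALS.items():
        if lo <= score <= hi:
            return severity
    raise AssertionError("severity intervals must cover 0..10")  # pragma: no cover


def score_moniker(annotation: MonikerAnnotation) -> IScaleResult:
    """Validate, sum category points and classify a single moniker."""
    validate_annotation(annotation)
    score = annotation.points.total()
    return IScaleResult(annotation.moniker, score, classify_severity(score))


def _key(moniker: str) -> str:
    return moniker.strip().casefold()


def score_table(annotations: Sequence[MonikerAnnotation]) -> list[IScaleResult]:
    """Score a list of annotations, preserving input order.

    Monikers must be unique case-insensitively after whitespace trimming
    ("corona" and "Corona" denote the same search query).
    """
    seen: dict[str, str] = {}
    dups: list[str] = []
    for a in annotations:
        k = _key(a.moniker)
        if k in seen:
            dups.append(f"{seen[k]!r}/{a.moniker!r}")
        else:
            seen[k] = a.moniker
    if dups:
        raise ValidationError("duplicate monikers: " + ", ".join(dups))
    return [score_moniker(a) for a in annotations]


# ---------------------------------------------------------------------------
# CSV interface: header moniker,generic,misinformative,discriminatory,deviant,other

_CSV_COLS = ["moniker", "generic", "misinformative", "discriminatory", "deviant", "other"]


def read_annotations_csv(path: str | Path) -> list[MonikerAnnotation]:
    """Read annotations from a UTF-8 CSV with the documented header."""
    df = pd.read_csv(path, dtype={"moniker": str}, comment="#")
    missing = [c for c in _CSV_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"annotations CSV missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        pts = CategoryPoints(
            generic=int(row.generic),
            misinformative=int(row.misinformative),
            discriminatory=int(row.discriminatory),
            deviant=int(row.deviant),
            other_specificities=int(row.other),
        )
        out.append(MonikerAnnotation(str(row.moniker), pts))
    return out


def results_to_frame(results: Iterable[IScaleResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.moniker, r.score, r.severity) for r in results],
        columns=["moniker", "score", "severity"],
    )


def write_scores_csv(results: Iterable[IScaleResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, index=False)
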