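"""BILAG 2004 domain grades: eligibility, numerical score, response rule.

The BILAG 2004 index grades disease activity A (severe) through E (never
active) in nine organ domains.  This module implements the pieces of the
instrument the registry analysis uses:

* eligibility for B cell depletion — at least 1 grade A and/or 2 grade B
  manifestations at baseline;
* the numerical BILAG score — the standard coding A=12, B=8, C=1, D=0, E=0
  summed over domains;
* the first-cycle response rule at month 6 — improvement of all baseline A
  grades, no more than 1 persisting grade B, and no new A/B flares.

Grades are plain letters; an assessment is a mapping from all nine domains to
a grade.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping

import pandas as pd

__all__ = [
    "DOMAINS",
    "GRADES",
    "NUMERIC_CODING",
    "DomainAssessment",
    "ResponseLabel",
    "check_eligibility",
    "numeric_bilag",
    "classify_response",
    "assessments_from_row",
]

#: The nine BILAG 2004 organ domains.
DOMAINS: tuple[str, ...] = (
    "constitutional",
    "mucocutaneous",
    "neuropsychiatric",
    "musculoskeletal",
    "cardiorespiratory",
    "gastroenterology",
    "ophthalmic",
    "renal",
    "hematology",
)

GRADES: tuple[str, ...] = ("A", "B", "C", "D", "E")

#: Standard BILAG 2004 numerical coding.
NUMERIC_CODING: Mapping[str, int] = {"A": 12, "B": 8, "C": 1, "D": 0, "E": 0}


class ResponseLabel(str, Enum):
    RESPONDER = "responder"
    NONRESPONDER = "nonresponder"
    UNDETERMINED = "undetermined"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class DomainAssessment:
    """One BILAG 2004 assessment: a grade for each of the nine domains."""

    grades: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = [d for d in DOMAINS if d not in self.grades]
        if missing:
            raise ValueError(f"missing domains: {missing}")
        extra = [d for d in self.grades if d not in DOMAINS]
        if extra:
            raise ValueError(f"unknown domains: {extra}")
        bad = {d: g for d, g in self.grades.items() if g not in GRADES}
        if bad:
            raise ValueError(f"invalid grades: {bad}")
        object.__setattr__(self, "grades", dict(self.grades))

    def __getitem__(self, domain: str) -> str:
        return self.grades[domain]

    def count(self, grade: str) -> int:
        return sum(1 for g in self.grades.values() if g == grade)

    @classmethod
    def uniform(cls, grade: str = "D") -> "DomainAssessment":
        return cls({d: grade for d in DOMAINS})

    @classmethod
    def with_grades(cls, default: str = "D", **overrides: str) -> "DomainAssessment":
        grades = {d: default for d in DOMAINS}
        grades.update(overrides)
        return cls(grades)


def check_eligibility(baseline: DomainAssessment) -> bool:
    """True iff the baseline has ≥1 grade A or ≥2 grade B manifestations."""
    return baseline.count("A") >= 1 or baseline.count("B") >= 2


def numeric_bilag(assessment: DomainAssessment) -> int:
    """Numerical BILAG score: sum of A=12, B=8, C=1, D=0, E=0 over domains."""
    return sum(NUMERIC_CODING[g] for g in assessment.grades.values())


def classify_response(
    baseline: DomainAssessment,
    month6: DomainAssessment | None,
    persisting_b_rule: str = "total",
) -> ResponseLabel:
    """Classify first-cycle response from baseline and month-6 BILAG grades.

    A patient is a responder iff all of:

    i.   every domain graded A at baseline is graded B or lower at month 6;
    ii.  no more than 1 persisting grade B at month 6;
    iii. no new flare — no domain is graded A at month 6 unless it was A at
         baseline (worsening to A from any lower grade is a new severe
         flare), and no domain graded C/D/E at baseline is B at month 6.

    ``persisting_b_rule`` selects the reading of clause (ii): ``"total"``
    (default) counts every month-6 B, including baseline A grades that
    improved only to B; ``"from_b"`` counts only baseline-B domains still B.
    A missing month-6 assessment yields ``undetermined``.  Patients whose
    baseline fails the eligibility rule have no defined response.
    """
    if persisting_b_rule not in ("total", "from_b"):
        raise ValueError(f"unknown persisting_b_rule {persisting_b_rule!r}")
    if not check_eligibility(baseline):
        raise ValueError("response undefined: baseline fails the eligibility rule")
    if month6 is None:
        return ResponseLabel.UNDETERMINED

    improved_all_a = all(
        month6[d] != "A" for d in DOMAINS if baseline[d] == "A"
    )
    if persisting_b_rule == "total":
        b_count = sum(1 for d in DOMAINS if month6[d] == "B")
    else:
        b_count = sum(
            1 for d in DOMAINS if baseline[d] == "B" and month6[d] == "B"
        )
    no_new_flare = all(
        not (month6[d] == "A" and baseline[d] != "A")
        and not (month6[d] == "B" and baseline[d] in ("C", "D", "E"))
        for d in DOMAINS
    )
    ok = improved_all_a and b_count <= 1 and no_new_flare
    return ResponseLabel.RESPONDER if ok else ResponseLabel.NONRESPONDER


def assessments_from_row(
    row: Mapping[str, object],
    baseline_suffix: str = "_baseline",
    month6_suffix: str = "_m6",
) -> tuple[DomainAssessment, DomainAssessment | None]:
    """Build (baseline, month6) assessments from one clinical-table row.

    Month-6 is ``None`` (→ undetermined) when any month-6 cell is missing.
    """
    baseline = DomainAssessment(
        {d: str(row[f"{d}{baseline_suffix}"]).strip().upper() for d in DOMAINS}
    )
    m6_cells = {d: row.get(f"{d}{month6_suffix}") for d in DOMAINS}
    if any(c is None or (isinstance(c, float) and pd.isna(c)) or str(c).strip() == ""
           for c in m6_cells.values()):
        return baseline, None
    month6 = DomainAssessment(
        {d: str(c).strip().upper() for d, c in m6_cells.items()}
    )
    return baseline, month6
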