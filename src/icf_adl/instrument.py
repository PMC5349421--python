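"""Item catalogs and response model for the ICF-based ADL interview.

The instrument evaluates everyday functioning on the six basic activities
of daily living (b-ADL, the Katz Index items) and nine instrumental
activities (i-ADL, the Lawton Scale items).  Each item is linked to one or
more activity codes of the WHO International Classification of Functioning,
Disability and Health (ICF) and is rated on the ICF performance qualifiers,
a five-point ordinal scale from 0 (no difficulty) to 4 (the activity is no
longer carried out / has been taken over).  For every limitation (score >= 1)
the interviewer records one or more underlying causes: cognitive, physical,
intrapersonal, social or environmental.

Relevance is part of the model: instrumental activities a person never
performed (e.g. gender-dependent tasks) are marked not relevant and excluded
from scoring.  All six basic activities are always relevant — they are
necessary for survival — so ``relevant=False`` on a b-ADL item is a
validation error.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from types import MappingProxyType
from typing import Iterable, Mapping, Optional


class Domain(str, Enum):
    """Activity domain: basic (self-care) or instrumental ADL."""

    BASIC = "basic"
    INSTRUMENTAL = "instrumental"


class Cause(str, Enum):
    """Closed enumeration of the five recognised causes of limitation."""

    COGNITIVE = "cognitive"
    PHYSICAL = "physical"
    INTRAPERSONAL = "intrapersonal"
    SOCIAL = "social"
    ENVIRONMENTAL = "environmental"


#: Stable iteration order for the cause enumeration.
CAUSES: tuple[Cause, ...] = tuple(Cause)

MIN_SCORE, MAX_SCORE = 0, 4

_ICF_CODE_RE = re.compile(r"^d\d{3,4}$")


class ReportMode(str, Enum):
    """Who answered the interview: the person (self) or an informant (proxy)."""

    SELF = "self"
    PROXY = "proxy"


class InstrumentError(ValueError):
    """Base class for instrument-level errors."""


class UnknownDomainError(InstrumentError):
    pass


class InvalidAssessmentError(InstrumentError):
    """Raised when an assessment fails validation and a valid one is required."""

    def __init__(self, violations: list["Violation"]):
        self.violations = violations
        msgs = "; ".join(v.message for v in violations)
        super().__init__(f"invalid assessment: {msgs}")


@dataclass(frozen=True)
class ActivityDefinition:
    """One scoreable instrument item and its ICF linkage.

    ``icf_codes`` are stored exactly as printed in the source tables; where a
    printed code is a known typo the corrected code is carried alongside in
    ``code_corrections`` (printed -> corrected) rather than silently rewritten.
    """

    item_id: str
    domain: Domain
    source_label: str
    icf_codes: tuple[str, ...]
    icf_definitions: tuple[str, ...]
    code_corrections: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for code in self.icf_codes:
            if not _ICF_CODE_RE.match(code):
                raise InstrumentError(f"malformed ICF code {code!r} on {self.item_id}")
        object.__setattr__(self, "code_corrections",
                           MappingProxyType(dict(self.code_corrections)))


def _defs(domain: Domain, rows: Iterable[tuple]) -> tuple[ActivityDefinition, ...]:
    out = []
    for row in rows:
        item_id, label, codes, acts = row[:4]
        corrections = row[4] if len(row) > 4 else {}
        out.append(ActivityDefinition(item_id, domain, label,
                                      tuple(codes), tuple(acts), corrections))
    return tuple(out)


# Katz Index items linked to ICF activity codes.  "Continence" carries the
# code d3501 as printed at source for "Regulating defecation"; the ICF code
# for that activity is d5301, recorded as a correction, not a rewrite.
_BASIC_CATALOG = _defs(Domain.BASIC, [
    ("bathing", "Bathing", ["d510"], ["Washing oneself"]),
    ("dressing", "Dressing", ["d540"], ["Dressing"]),
    ("transferring", "Transferring", ["d410", "d420", "d450"],
     ["Indoor mobility and changing basic body position",
      "Transferring oneself", "Walking"]),
    ("continence", "Continence", ["d5300", "d3501"],
     ["Regulating urination", "Regulating defecation"],
     {"d3501": "d5301"}),
    ("toileting", "Toileting", ["d530"], ["Toileting"]),
    ("feeding", "Feeding", ["d550", "d560"], ["Eating", "Drinking"]),
])

# Lawton Scale items linked to ICF activity codes.
_INSTRUMENTAL_CATALOG = _defs(Domain.INSTRUMENTAL, [
    ("telephone", "Telephone use", ["d360"],
     ["Using communication devices and techniques"]),
    ("transportation", "Using transportation", ["d470"], ["Using transportation"]),
    ("shopping", "Shopping", ["d6200"], ["Shopping"]),
    ("meal_preparation", "Preparing food", ["d630"], ["Preparing meals"]),
    ("housekeeping", "Housekeeping", ["d640"], ["Doing housework"]),
    ("laundry", "Doing laundry", ["d6400"], ["Washing and drying clothes"]),
    ("handyman", "Doing handyman work", ["d650"], ["Caring for household objects"]),
    ("medication", "Responsibility for own medications", ["d5702"],
     ["Maintaining one's health"]),
    ("finances", "Handling finance", ["d860"], ["Basic economic transactions"]),
])


def load_catalog(domain: Domain | str) -> tuple[ActivityDefinition, ...]:
    """Return the fixed, order-stable item catalog for a domain.

    The basic catalog has exactly 6 items (Bathing, Dressing, Transferring,
    Continence, Toileting, Feeding); the instrumental catalog exactly 9.
    The returned tuple of frozen dataclasses is immutable.
    """
    try:
        domain = Domain(domain)
    except ValueError:
        raise UnknownDomainError(f"unknown domain {domain!r}") from None
    return _BASIC_CATALOG if domain is Domain.BASIC else _INSTRUMENTAL_CATALOG


def catalog_item_ids(domain: Domain | str) -> tuple[str, ...]:
    return tuple(d.item_id for d in load_catalog(domain))


@dataclass(frozen=True)
class ItemResponse:
    """Interview response for one item.

    A score is present if and only if the item is relevant; causes are
    recorded only for limitations (score >= 1).  ``causes`` is a set —
    order never matters and duplicates collapse.
    """

    item_id: str
    relevant: bool
    score: Optional[int] = None
    causes: frozenset[Cause] = frozenset()
    note: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "causes", frozenset(Cause(c) for c in self.causes))

    @property
    def limited(self) -> bool:
        return self.score is not None and self.score >= 1


@dataclass(frozen=True)
class Assessment:
    """One participant's full interview record for one domain."""

    participant_id: str
    domain: Domain
    responses: tuple[ItemResponse, ...]
    report_mode: ReportMode = ReportMode.SELF

    def __post_init__(self) -> None:
        object.__setattr__(self, "domain", Domain(self.domain))
        object.__setattr__(self, "report_mode", ReportMode(self.report_mode))
        object.__setattr__(self, "responses", tuple(self.responses))

    def response(self, item_id: str) -> ItemResponse:
        for r in self.responses:
            if r.item_id == item_id:
                return r
        raise KeyError(item_id)


@dataclass(frozen=True)
class Violation:
    """One validation finding, naming the offending item where applicable."""

    rule: str
    message: str
    item_id: Optional[str] = None


@dataclass
class ValidationReport:
    violations: list[Violation]
    warnings: list[Violation]

    @property
    def ok(self) -> bool:
        return not self.violations

    @property
    def cause_data_complete(self) -> bool:
        """False when any limitation lacks a recorded cause (lenient mode)."""
        return not any(v.rule == "missing-cause" for v in self.warnings)


def validate_assessment(a: Assessment, strict: bool = True) -> ValidationReport:
    """Check an assessment against the interview rules.

    Hard violations (any mode): unknown/duplicate/missing items, scores
    outside 0-4, a score on a not-relevant item, a relevant item without a
    score, causes attached to a score of 0, a basic-domain item marked not
    relevant.  A limitation (score >= 1, including 4 "no longer carried
    out") with no recorded cause is a violation under ``strict`` and a
    warning otherwise; in lenient mode indices remain computable but the
    cause-specific indices are flagged incomplete.
    """
    violations: list[Violation] = []
    warnings: list[Violation] = []
    catalog_ids = catalog_item_ids(a.domain)

    seen: set[str] = set()
    for r in a.responses:
        if r.item_id in seen:
            violations.append(Violation("duplicate-item",
                                        f"duplicate item {r.item_id!r}", r.item_id))
        seen.add(r.item_id)
        if r.item_id not in catalog_ids:
            violations.append(Violation(
                "unknown-item",
                f"item {r.item_id!r} not in the {a.domain.value} catalog", r.item_id))
            continue
        if a.domain is Domain.BASIC and not r.relevant:
            violations.append(Violation(
                "basic-not-relevant",
                f"basic item {r.item_id!r} marked not relevant; "
                "all basic activities are relevant for every individual", r.item_id))
        if r.relevant and r.score is None:
            violations.append(Violation("unscored-relevant",
                                        f"relevant item {r.item_id!r} has no score",
                                        r.item_id))
        if not r.relevant and r.score is not None:
            violations.append(Violation("scored-irrelevant",
                                        f"not-relevant item {r.item_id!r} has a score",
                                        r.item_id))
        if r.score is not None and not (MIN_SCORE <= r.score <= MAX_SCORE):
            violations.append(Violation(
                "score-range",
                f"item {r.item_id!r} score {r.score} outside {MIN_SCORE}-{MAX_SCORE}",
                r.item_id))
        if r.score == 0 and r.causes:
            violations.append(Violation("cause-on-zero",
                                        f"item {r.item_id!r} scored 0 but has causes",
                                        r.item_id))
        if r.limited and not r.causes:
            v = Violation("missing-cause",
                          f"limited item {r.item_id!r} has no recorded cause",
                          r.item_id)
            (violations if strict else warnings).append(v)

    for item_id in catalog_ids:
        if item_id not in seen:
            violations.append(Violation("missing-item",
                                        f"catalog item {item_id!r} missing", item_id))

    if not any(r.relevant for r in a.responses):
        violations.append(Violation("no-relevant-activities",
                                    "no relevant activities (TNA = 0); "
                                    "indices cannot be computed"))
    return ValidationReport(violations, warnings)


def require_valid(a: Assessment, strict: bool = True) -> Assessment:
    """Return ``a`` unchanged or raise :class:`InvalidAssessmentError`."""
    report = validate_assessment(a, strict=strict)
    if not report.ok:
        raise InvalidAssessmentError(report.violations)
    return a
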