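"""Disability indices: TNA, LimAct, DI and the per-cause indices (CDI, PDI).

The global disability index expresses observed disability as a percentage of
the maximal possible disability over the activities relevant to the person:

    DI = 100 * absolute_disability / maximal_disability
       = 100 * sum(score_i over limited activities) / (4 * TNA)

where TNA is the Total Number of relevant Activities and a limited activity
is one scored >= 1.  A cause-specific index restricts the numerator to
limitations carrying that cause; an activity limited for several reasons
contributes its full score to each matching cause index, so cause indices
may sum to more than the DI.  Each index lies in [0, 100], higher meaning
more disability, and every cause index is bounded above by the DI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .instrument import (
    CAUSES,
    Assessment,
    Cause,
    Domain,
    InstrumentError,
    MAX_SCORE,
)


class NoRelevantActivitiesError(InstrumentError):
    """TNA = 0: no relevant activities, indices are undefined."""


class UnscoredItemError(InstrumentError):
    """A relevant item has no score; indices cannot be computed."""


def display(value: float, ndigits: int = 1) -> float:
    """Presentation rounding (half-to-even); indices are stored full-precision."""
    return round(value, ndigits)


@dataclass(frozen=True)
class CauseBreakdown:
    """Per-cause components: LimActC-style count, score sum and index."""

    lim_act: int
    score_sum: int
    index: float


@dataclass(frozen=True)
class IndexResult:
    """All indices for one participant x domain.

    Invariants: ``maximal_disability == 4 * tna``; ``di == 0`` iff
    ``lim_act == 0``; ``0 <= per_cause[c].index <= di <= 100`` for every
    cause ``c``.
    """

    participant_id: str
    domain: Domain
    tna: int
    lim_act: int
    absolute_disability: int
    maximal_disability: int
    di: float
    per_cause: Mapping[Cause, CauseBreakdown]
    cause_data_complete: bool = True

    @property
    def cdi(self) -> float:
        return self.per_cause[Cause.COGNITIVE].index

    @property
    def pdi(self) -> float:
        return self.per_cause[Cause.PHYSICAL].index


def _scored_responses(a: Assessment):
    relevant = [r for r in a.responses if r.relevant]
    if not relevant:
        raise NoRelevantActivitiesError(
            f"participant {a.participant_id}: no relevant activities")
    for r in relevant:
        if r.score is None:
            raise UnscoredItemError(
                f"participant {a.participant_id}: relevant item "
                f"{r.item_id!r} has no score")
    return relevant


def compute_tna(a: Assessment) -> int:
    """Total Number of relevant Activities (TNA >= 1 or error)."""
    tna = sum(1 for r in a.responses if r.relevant)
    if tna == 0:
        raise NoRelevantActivitiesError(
            f"participant {a.participant_id}: no relevant activities")
    return tna


def compute_di(a: Assessment) -> IndexResult:
    """Compute the global DI and every cause-specific index for one assessment.

    Values are stored at full precision; use :func:`display` for one-decimal
    presentation.
    """
    relevant = _scored_responses(a)
    tna = len(relevant)
    limited = [r for r in relevant if r.limited]
    absolute = sum(r.score for r in limited)
    maximal = MAX_SCORE * tna
    di = 100.0 * absolute / maximal

    per_cause = {}
    incomplete = any(r.limited and not r.causes for r in relevant)
    for cause in CAUSES:
        with_cause = [r for r in limited if cause in r.causes]
        score_sum = sum(r.score for r in with_cause)
        per_cause[cause] = CauseBreakdown(
            lim_act=len(with_cause),
            score_sum=score_sum,
            index=100.0 * score_sum / maximal,
        )

    return IndexResult(
        participant_id=a.participant_id,
        domain=a.domain,
        tna=tna,
        lim_act=len(limited),
        absolute_disability=absolute,
        maximal_disability=maximal,
        di=di,
        per_cause=per_cause,
        cause_data_complete=not incomplete,
    )


def compute_cause_index(a: Assessment, cause: Cause | str) -> float:
    """Cause-specific disability index (percent), e.g. CDI for ``cognitive``."""
    return compute_di(a).per_cause[Cause(cause)].index


#: Stable column layout consumed by the psychometrics module.
INDEX_COLUMNS = [
    "participant_id", "domain", "tna", "lim_act",
    "absolute_disability", "maximal_disability",
    "di", "cdi", "pdi", "di_intrapersonal", "di_social", "di_environmental",
]

_CAUSE_COLUMN = {
    Cause.COGNITIVE: "cdi",
    Cause.PHYSICAL: "pdi",
    Cause.INTRAPERSONAL: "di_intrapersonal",
    Cause.SOCIAL: "di_social",
    Cause.ENVIRONMENTAL: "di_environmental",
}


def index_table(assessments: Iterable[Assessment]) -> pd.DataFrame:
    """One row per participant x domain with all indices at full precision."""
    rows = []
    for a in assessments:
        res = compute_di(a)
        row = {
            "participant_id": res.participant_id,
            "domain": res.domain.value,
            "tna": res.tna,
            "lim_act": res.lim_act,
            "absolute_disability": res.absolute_disability,
            "maximal_disability": res.maximal_disability,
            "di": res.di,
        }
        for cause, col in _CAUSE_COLUMN.items():
            row[col] = res.per_cause[cause].index
        rows.append(row)
    return pd.DataFrame(rows, columns=INDEX_COLUMNS)


#: Wide-format marker columns produced by :func:`pivot_index_table`.
MARKERS_BASIC = ["b_adl_di", "b_adl_cdi", "b_adl_pdi"]
MARKERS_INSTRUMENTAL = ["i_adl_di", "i_adl_cdi", "i_adl_pdi"]

_DOMAIN_PREFIX = {Domain.BASIC.value: "b_adl", Domain.INSTRUMENTAL.value: "i_adl"}


def pivot_index_table(table: pd.DataFrame,
                      values: Sequence[str] = ("di", "cdi", "pdi"),
                      ) -> pd.DataFrame:
    """Pivot the long index table to one row per participant.

    Columns are prefixed by domain, e.g. ``b_adl_di``, ``i_adl_cdi``.
    """
    wide: Optional[pd.DataFrame] = None
    for domain, prefix in _DOMAIN_PREFIX.items():
        sub = table.loc[table["domain"] == domain, ["participant_id", *values]]
        sub = sub.rename(columns={v: f"{prefix}_{v}" for v in values})
        wide = sub if wide is None else wide.merge(sub, on="participant_id", how="outer")
    return wide if wide is not None else pd.DataFrame(columns=["participant_id"])
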