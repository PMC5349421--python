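"""Delimited-text adapters: assessments, cohort tables, reports, provenance.

The canonical interchange format is UTF-8 comma-separated text with a header
row.  Assessment files are long format, one row per participant x domain x
item with 0/1 cause flag columns.  Output files may carry provenance
comment lines (``# key=value``) before the header; readers skip them.
A thin spreadsheet reader ingests XLSX tables of the same shape with an
optional user-supplied column map.
"""

from __future__ import annotations

import dataclasses
import hashlib
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .instrument import (
    CAUSES,
    Assessment,
    Cause,
    Domain,
    ItemResponse,
    ReportMode,
)
from .psychometrics import Participant

ASSESSMENT_COLUMNS = [
    "participant_id", "domain", "item_id", "relevant", "score",
    *[f"cause_{c.value}" for c in CAUSES], "note", "report_mode",
]

COHORT_COLUMNS = [
    "participant_id", "group", "age", "education", "gender",
    "n_medications", "n_comorbidities", "mmse", "katz_total", "lawton_total",
]


def provenance_lines(seed: Optional[int] = None,
                     config_hash: Optional[str] = None,
                     **extra: object) -> list[str]:
    """Comment lines recording version, seed and config hash for outputs."""
    from . import __version__
    fields = {"icf-adl": __version__, "seed": seed, "config_hash": config_hash,
              **extra}
    return [f"# {k}={v}" for k, v in fields.items() if v is not None]


def config_digest(obj) -> str:
    """Short stable digest of a dataclass/dict configuration."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    return hashlib.sha256(repr(sorted(str(obj))).encode()).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_lines:
            fh.write(line + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    """Read a CSV written by this package, skipping provenance comments."""
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# Assessments
# ---------------------------------------------------------------------------

def assessments_to_frame(assessments: Iterable[Assessment]) -> pd.DataFrame:
    rows = []
    for a in assessments:
        for r in a.responses:
            row = {
                "participant_id": a.participant_id,
                "domain": a.domain.value,
                "item_id": r.item_id,
                "relevant": int(r.relevant),
                "score": "" if r.score is None else r.score,
                "note": "" if r.note is None else r.note,
                "report_mode": a.report_mode.value,
            }
            for c in CAUSES:
                row[f"cause_{c.value}"] = int(c in r.causes)
            rows.append(row)
    return pd.DataFrame(rows, columns=ASSESSMENT_COLUMNS)


def write_assessments(assessments: Iterable[Assessment], path,
                      header_lines: Sequence[str] = ()) -> None:
    _write_csv(assessments_to_frame(assessments), path, header_lines)


def frame_to_assessments(df: pd.DataFrame) -> list[Assessment]:
    required = {"participant_id", "domain", "item_id", "relevant", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"assessment table missing columns: {sorted(missing)}")

    out: list[Assessment] = []
    keys: list[tuple] = []
    grouped: dict[tuple, list[ItemResponse]] = {}
    modes: dict[tuple, str] = {}
    for idx, row in df.iterrows():
        key = (str(row["participant_id"]), str(row["domain"]))
        if key not in grouped:
            grouped[key] = []
            keys.append(key)
            modes[key] = str(row.get("report_mode", "self") or "self")
        score = row["score"]
        score = None if pd.isna(score) or score == "" else int(score)
        causes = frozenset(
            c for c in CAUSES
            if f"cause_{c.value}" in df.columns
            and _truthy(row[f"cause_{c.value}"]))
        note = row.get("note")
        note = None if pd.isna(note) or note == "" else str(note)
        try:
            resp = ItemResponse(str(row["item_id"]), _truthy(row["relevant"]),
                                score, causes, note)
        except ValueError as exc:
            raise ValueError(f"row {idx}: {exc}") from exc
        grouped[key].append(resp)

    for key in keys:
        pid, domain = key
        out.append(Assessment(pid, Domain(domain), tuple(grouped[key]),
                              ReportMode(modes[key])))
    return out


def _truthy(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("1", "true", "yes")
    return bool(int(v)) if not pd.isna(v) else False


def read_assessments(path) -> list[Assessment]:
    df = read_table(path)
    if df.empty:
        raise ValueError(f"no assessment rows in {path}")
    return frame_to_assessments(df)


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

def participants_to_frame(participants: Iterable[Participant]) -> pd.DataFrame:
    rows = [dataclasses.asdict(p) for p in participants]
    if not rows:
        return pd.DataFrame(columns=COHORT_COLUMNS)
    return pd.DataFrame(rows)[COHORT_COLUMNS]


def write_cohort(participants: Iterable[Participant], path,
                 header_lines: Sequence[str] = ()) -> None:
    _write_csv(participants_to_frame(participants), path, header_lines)


def read_cohort(path) -> pd.DataFrame:
    df = read_table(path)
    missing = {"participant_id", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    df["participant_id"] = df["participant_id"].astype(str)
    return df


# ---------------------------------------------------------------------------
# Spreadsheet adapter
# ---------------------------------------------------------------------------

def read_spreadsheet(path, sheet: int | str = 0,
                     column_map: Optional[Mapping[str, str]] = None,
                     ) -> pd.DataFrame:
    """Thin XLSX reader for tables shaped like the canonical CSV formats.

    ``column_map`` renames source columns to canonical names
    (source name -> canonical name), since supplementary spreadsheets may
    use their own headers.
    """
    df = pd.read_excel(path, sheet_name=sheet)
    if column_map:
        df = df.rename(columns=dict(column_map))
    df.columns = [str(c).strip().lower().replace(" ", "_") for c in df.columns]
    return df
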