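"""Data model, readers and preprocessing for longitudinal coded health records.

A patient's record is a set of coded events (ICD-10 diagnoses, procedures,
medications, abnormal labs) with calendar dates.  Preprocessing reduces the
raw event stream to an analysis-ready *timeline*: the first occurrence of
each code per patient (first *abnormal* occurrence for labs), with diagnosis
codes truncated to their 3-character ICD-10 category — except for the
configurable dementia-outcome codes, which keep their full specificity.
Patients with incomplete demographics (sex, race or age) or below the
minimum age are excluded, with per-reason accounting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

DOMAINS = ("diagnosis", "procedure", "medication", "lab")

#: Dementia-related codes allowed as trajectory endpoints.  These keep their
#: full ICD-10 specificity during truncation.  Configurable everywhere; this
#: default covers the common Alzheimer, vascular, Lewy-body, alcohol-related
#: and unspecified dementia categories plus age-related cognitive decline.
DEFAULT_OUTCOME_CODES = frozenset({
    "G30.0", "G30.1", "G30.9", "G31.01", "G31.2", "G31.83",
    "F01.50", "F01.51", "F02.80", "F02.81", "F03.90", "F03.91",
    "F04", "F06.1", "R41.81",
})

DAYS_PER_YEAR = 365.25


class MissingColumnError(ValueError):
    """A mandatory column is absent from an input table."""


@dataclass(frozen=True)
class EventRecord:
    patient_id: str
    code: str
    domain: str
    event_date: pd.Timestamp
    abnormal: Optional[bool] = None


@dataclass(frozen=True)
class Demographics:
    patient_id: str
    birth_date: pd.Timestamp
    sex: str
    race: str
    ethnicity: Optional[str] = None


@dataclass
class LoadReport:
    """Row accounting for ``read_events``."""

    n_rows: int = 0
    n_loaded: int = 0
    n_bad_date: int = 0
    n_empty_code: int = 0
    n_bad_domain: int = 0

    @property
    def n_dropped(self) -> int:
        return self.n_bad_date + self.n_empty_code + self.n_bad_domain

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_loaded": self.n_loaded,
            "n_bad_date": self.n_bad_date,
            "n_empty_code": self.n_empty_code,
            "n_bad_domain": self.n_bad_domain,
        }


@dataclass
class ExclusionReport:
    """Patient accounting for ``build_timelines``.

    Precedence (each patient counted once): incomplete demographics >
    under-age > no events in the study window.
    """

    n_input_patients: int = 0
    n_included: int = 0
    incomplete_demographics: int = 0
    under_age: int = 0
    counts_balance: bool = True

    def to_dict(self) -> dict:
        return {
            "n_input_patients": self.n_input_patients,
            "n_included": self.n_included,
            "incomplete_demographics": self.incomplete_demographics,
            "under_age": self.under_age,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


@dataclass
class CodeVocabulary:
    """Maps each code to its free-text description, domain and outcome flag."""

    entries: dict[str, dict] = field(default_factory=dict)

    @classmethod
    def from_table(cls, df: pd.DataFrame,
                   outcome_codes: Iterable[str] = DEFAULT_OUTCOME_CODES,
                   ) -> "CodeVocabulary":
        outcome = set(outcome_codes)
        entries = {}
        for row in df.itertuples(index=False):
            code = str(row.code)
            entries[code] = {
                "description": str(getattr(row, "description", code) or code),
                "domain": str(getattr(row, "domain", "diagnosis")),
                "is_outcome": code in outcome,
            }
        return cls(entries)

    @classmethod
    def from_codes(cls, codes: Iterable[str],
                   domains: Mapping[str, str] | None = None,
                   outcome_codes: Iterable[str] = DEFAULT_OUTCOME_CODES,
                   ) -> "CodeVocabulary":
        """Fallback vocabulary: each code described by its own token."""
        outcome = set(outcome_codes)
        domains = domains or {}
        return cls({
            c: {"description": c, "domain": domains.get(c, "diagnosis"),
                "is_outcome": c in outcome}
            for c in codes
        })

    def ensure(self, codes: Iterable[str],
               domains: Mapping[str, str] | None = None) -> None:
        domains = domains or {}
        for c in codes:
            self.entries.setdefault(
                c, {"description": c, "domain": domains.get(c, "diagnosis"),
                    "is_outcome": False})

    def description(self, code: str) -> str:
        entry = self.entries.get(code)
        return entry["description"] if entry else code

    def outcome_codes(self) -> frozenset[str]:
        return frozenset(c for c, e in self.entries.items() if e["is_outcome"])

    def __contains__(self, code: str) -> bool:
        return code in self.entries


def read_events(path: str | Path, sep: str | None = None,
                ) -> tuple[pd.DataFrame, LoadReport]:
    """Read a long-format event table (patient_id, code, domain, date[, abnormal]).

    Rows with unparseable dates, empty codes or unknown domains are dropped
    and counted in the returned :class:`LoadReport`.  A missing mandatory
    column or an empty file is a hard error.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[0] == 0:
        raise ValueError(f"event file is empty: {path}")
    for col in ("patient_id", "code", "domain", "date"):
        if col not in df.columns:
            raise MissingColumnError(
                f"event file {path} is missing mandatory column {col!r}")
    report = LoadReport(n_rows=len(df))

    code = df["code"].fillna("").str.strip()
    ok_code = code != ""
    report.n_empty_code = int((~ok_code).sum())

    dates = pd.to_datetime(df["date"], errors="coerce", format="ISO8601")
    ok_date = dates.notna()
    report.n_bad_date = int((ok_code & ~ok_date).sum())

    domain = df["domain"].fillna("").str.strip().str.lower()
    ok_domain = domain.isin(DOMAINS)
    report.n_bad_domain = int((ok_code & ok_date & ~ok_domain).sum())

    keep = ok_code & ok_date & ok_domain
    out = pd.DataFrame({
        "patient_id": df.loc[keep, "patient_id"].astype(str).values,
        "code": code[keep].values,
        "domain": domain[keep].values,
        "date": dates[keep].values,
    })
    if "abnormal" in df.columns:
        ab = df.loc[keep, "abnormal"].str.strip().str.lower()
        out["abnormal"] = ab.isin({"1", "true", "t", "yes", "y"})
    else:
        out["abnormal"] = out["domain"] == "lab"  # absent flag: labs assumed abnormal
    report.n_loaded = len(out)
    return out, report


def read_demographics(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read the demographics table.

    Requires ``patient_id``, ``sex``, ``race`` and either ``birth_date``
    (ISO-8601) or ``age_at_window_start`` (years).  ``ethnicity`` is carried
    through if present but takes no part in matching.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[0] == 0:
        raise ValueError(f"demographics file is empty: {path}")
    for col in ("patient_id", "sex", "race"):
        if col not in df.columns:
            raise MissingColumnError(
                f"demographics file {path} is missing mandatory column {col!r}")
    if "birth_date" not in df.columns and "age_at_window_start" not in df.columns:
        raise MissingColumnError(
            f"demographics file {path} needs 'birth_date' or 'age_at_window_start'")
    out = df.copy()
    out["patient_id"] = out["patient_id"].astype(str)
    if "birth_date" in out.columns:
        out["birth_date"] = pd.to_datetime(out["birth_date"], errors="coerce",
                                           format="ISO8601")
    return out


def truncate_code(code: str, domain: str,
                  outcome_codes: Iterable[str] = DEFAULT_OUTCOME_CODES) -> str:
    """Truncate a diagnosis code to its 3-character ICD-10 category.

    The dot suffix is removed first ("E11.9" -> "E11").  Outcome-set
    diagnosis codes keep their full form, as do all non-diagnosis codes.
    """
    if domain != "diagnosis" or code in outcome_codes:
        return code
    return code.split(".", 1)[0][:3]


def apply_code_mapping(events: pd.DataFrame, mapping: Mapping[str, str],
                       ) -> tuple[pd.DataFrame, int]:
    """Replace medication codes by their mapped therapeutic group.

    Unmapped medication codes pass through unchanged; returns the event
    table and the count of unmapped medication rows.
    """
    if not mapping:
        return events, 0
    out = events.copy()
    med = out["domain"] == "medication"
    mapped = out.loc[med, "code"].map(mapping)
    n_unmapped = int((med.sum()) - mapped.notna().sum())
    out.loc[med, "code"] = mapped.fillna(out.loc[med, "code"])
    return out, n_unmapped


def age_years(birth_date: pd.Timestamp, at: pd.Timestamp) -> float:
    if pd.isna(birth_date) or pd.isna(at):
        raise ValueError("cannot resolve age: missing date")
    return (at - birth_date).days / DAYS_PER_YEAR


def age_decade(birth_date: pd.Timestamp, at: pd.Timestamp) -> int:
    """Decade-of-life index: floor(age/10); age 70.0 falls in decade 7."""
    return int(np.floor(age_years(birth_date, at) / 10.0))


@dataclass
class Cohort:
    """Analysis-ready cohort: per-patient first-occurrence events + demographics.

    ``events`` has one row per (patient, code): columns patient_id, code,
    domain, date.  ``demographics`` is indexed by patient_id with columns
    sex, race, birth_date (and optionally ethnicity).  Patients with
    demographics but no in-window events are retained — they belong to the
    matched-control pool.
    """

    events: pd.DataFrame
    demographics: pd.DataFrame
    window: tuple[pd.Timestamp, pd.Timestamp]
    vocabulary: CodeVocabulary

    @property
    def patient_ids(self) -> np.ndarray:
        return self.demographics.index.to_numpy()

    @property
    def n_patients(self) -> int:
        return len(self.demographics)

    @property
    def codes(self) -> list[str]:
        return sorted(self.events["code"].unique())

    @cached_property
    def date_matrix(self) -> pd.DataFrame:
        """Patients x codes matrix of first-occurrence dates (NaT = absent)."""
        dm = self.events.pivot(index="patient_id", columns="code", values="date")
        return dm.reindex(index=self.demographics.index)

    def dates_of(self, code: str) -> pd.Series:
        if code in self.date_matrix.columns:
            return self.date_matrix[code]
        return pd.Series(pd.NaT, index=self.demographics.index, name=code)

    def timelines(self) -> Iterator[tuple[Demographics, list[EventRecord]]]:
        """Iterate (demographics, ordered events) per patient — convenience view."""
        grouped = dict(list(self.events.sort_values(["patient_id", "date", "code"])
                            .groupby("patient_id")))
        for pid, row in self.demographics.iterrows():
            demo = Demographics(patient_id=str(pid), birth_date=row["birth_date"],
                                sex=row["sex"], race=row["race"],
                                ethnicity=row.get("ethnicity"))
            recs = []
            if pid in grouped:
                for ev in grouped[pid].itertuples(index=False):
                    recs.append(EventRecord(str(ev.patient_id), ev.code, ev.domain,
                                            ev.date))
            yield demo, recs


def build_timelines(events: pd.DataFrame, demographics: pd.DataFrame,
                    study_window: tuple[str | pd.Timestamp, str | pd.Timestamp],
                    min_age: float = 18.0,
                    outcome_codes: Iterable[str] = DEFAULT_OUTCOME_CODES,
                    code_mapping: Mapping[str, str] | None = None,
                    vocabulary: CodeVocabulary | None = None,
                    ) -> tuple[Cohort, ExclusionReport]:
    """Apply the preprocessing rules and assemble the analysis cohort.

    Order of operations: medication mapping -> diagnosis truncation ->
    abnormal-lab restriction -> study-window restriction -> first-occurrence
    reduction -> demographic completeness and minimum-age exclusion
    (age evaluated at the window start).
    """
    w0, w1 = pd.Timestamp(study_window[0]), pd.Timestamp(study_window[1])
    if w1 <= w0:
        raise ValueError("study window end must follow its start")
    outcome_codes = frozenset(outcome_codes)

    ev = events.copy()
    if code_mapping:
        ev, _ = apply_code_mapping(ev, code_mapping)
    is_dx = ev["domain"] == "diagnosis"
    keep_full = ev["code"].isin(outcome_codes) | ~is_dx
    ev["original_code"] = ev["code"]
    ev.loc[~keep_full, "code"] = (
        ev.loc[~keep_full, "code"].str.split(".", n=1).str[0].str[:3])

    # labs: only abnormal results carry signal; normal-only labs are dropped
    if "abnormal" in ev.columns:
        ev = ev[(ev["domain"] != "lab") | ev["abnormal"].fillna(False)]
    ev = ev[(ev["date"] >= w0) & (ev["date"] <= w1)]

    # first occurrence per (patient, post-truncation code); same-day duplicates
    # resolved by the lexicographically smallest original code
    ev = ev.sort_values(["patient_id", "code", "date", "original_code"],
                        kind="mergesort")
    ev = ev.drop_duplicates(subset=["patient_id", "code"], keep="first")

    demo = demographics.copy()
    demo["patient_id"] = demo["patient_id"].astype(str)
    demo = demo.drop_duplicates(subset="patient_id", keep="first")
    if "birth_date" not in demo.columns:
        demo["birth_date"] = pd.NaT
    if "age_at_window_start" in demo.columns:
        age = pd.to_numeric(demo["age_at_window_start"], errors="coerce")
        need = demo["birth_date"].isna() & age.notna()
        demo.loc[need, "birth_date"] = w0 - pd.to_timedelta(
            (age[need] * DAYS_PER_YEAR).round(), unit="D")

    event_pids = set(ev["patient_id"].unique())
    all_pids = set(demo["patient_id"]) | event_pids
    report = ExclusionReport(n_input_patients=len(all_pids))

    demo = demo.set_index("patient_id")
    missing_demo_rows = sorted(event_pids - set(demo.index))
    sex = demo["sex"].fillna("").astype(str).str.strip()
    race = demo["race"].fillna("").astype(str).str.strip()
    complete = (sex != "") & (race != "") & demo["birth_date"].notna()
    report.incomplete_demographics = int((~complete).sum()) + len(missing_demo_rows)

    age_at_start = (w0 - demo["birth_date"]).dt.days / DAYS_PER_YEAR
    of_age = age_at_start >= min_age
    report.under_age = int((complete & ~of_age).sum())

    included = demo[complete & of_age].copy()
    report.n_included = len(included)
    report.counts_balance = (report.n_input_patients ==
                             report.n_included + report.incomplete_demographics
                             + report.under_age)

    ev = ev[ev["patient_id"].isin(included.index)]
    ev = (ev[["patient_id", "code", "domain", "date"]]
          .sort_values(["patient_id", "date", "code"], kind="mergesort")
          .reset_index(drop=True))

    keep_cols = [c for c in ("sex", "race", "ethnicity", "birth_date")
                 if c in included.columns]
    included = included[keep_cols]

    vocab = vocabulary or CodeVocabulary()
    vocab.ensure(ev["code"].unique(),
                 domains=dict(zip(ev["code"], ev["domain"])))
    for c in outcome_codes:
        if c in vocab.entries:
            vocab.entries[c]["is_outcome"] = True

    return Cohort(events=ev, demographics=included, window=(w0, w1),
                  vocabulary=vocab), report
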