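"""The AAA case/control classification cascade.

Every subject in the cohort receives exactly one label:

- **CASE**, with a type in decreasing order of diagnostic certainty —
  Type 1: any AAA-repair procedure code; Type 2: a ruptured-AAA diagnosis
  (441.3) at a specialty clinic; Type 3: AAA diagnoses (441.3/441.4) at
  specialty clinics on at least two distinct calendar dates (single or
  non-specialty encounters are too likely to be working/referral diagnoses);
- **EXCLUDED**, with a reason — a phenocopy diagnosis (syndromic aortic
  disease, thoracic aneurysm, dissection); reference-date age outside
  [40, 89]; first AAA evidence at age ≤ 40 (likely trauma or an
  unrecognized syndrome); a residual ``441.*`` code without case-level
  confirmation; or no encounter within the lookback window;
- **CONTROL** otherwise: recently seen, never carried any ``441.*`` code.

The rules are applied in a fixed order and the cascade stops at the first
match, so exclusion precedes case typing and case typing precedes the
control filters.  Ages are anchored on the age-at-event carried by the
events themselves (the input contract has no birth dates): a subject's age
at the reference date is the age at their most recent event plus the whole
years elapsed since.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import enum
import math
from collections import defaultdict
from typing import Iterable, Sequence

import pandas as pd

from .codesets import CodeSetRegistry, default_registry
from .model import CodingSystem, DiagnosisEvent, ProcedureEvent, events_from_frame

__all__ = [
    "Label",
    "ExclusionReason",
    "EngineConfig",
    "ClassificationResult",
    "CohortSummary",
    "resolve_reference_date",
    "is_type1",
    "is_type2",
    "is_type3",
    "classify_subject",
    "classify_cohort",
    "case_type_distribution",
    "results_to_frame",
]

DAYS_PER_YEAR = 365.25  # leap-year-safe year length for date arithmetic


class Label(str, enum.Enum):
    CASE = "case"
    CONTROL = "control"
    EXCLUDED = "excluded"


class ExclusionReason(str, enum.Enum):
    PHENOCOPY = "phenocopy"
    AGE = "age"
    AAA_ONSET_AT_OR_UNDER_MIN_AGE = "aaa_onset_at_or_under_min_age"
    UNCONFIRMED_AAA_CODE = "unconfirmed_aaa_code"
    NO_RECENT_ENCOUNTER = "no_recent_encounter"


def _fold_clinics(clinics: Iterable[str]) -> frozenset[str]:
    return frozenset(c.strip().casefold() for c in clinics)


@dataclasses.dataclass(frozen=True)
class EngineConfig:
    """Tunable parameters of the cascade.

    Parameters
    ----------
    specialty_clinics
        Clinic names counted as "specialty" for Types 2/3 (exact match after
        trim + case-fold; clinic vocabularies are site-specific).
    min_age, max_age
        Inclusive reference-date age bounds for eligibility (default 40–89).
    onset_age_max
        Subjects whose earliest AAA evidence occurred at or under this age
        are excluded (default 40; early onset suggests trauma or an
        unrecognized syndromic form).
    lookback_years
        Encounter-recency window for controls (default 5 years).
    reference_date
        Explicit anchor date, or ``"auto"`` = the latest event date in the
        cohort.
    min_type3_dates
        Distinct specialty AAA-diagnosis dates required for Type 3
        (default 2).
    type2_requires_specialty
        Whether the ruptured-AAA encounter must be at a specialty clinic
        (default True; set False to accept any clinic).
    """

    registry: CodeSetRegistry = dataclasses.field(default_factory=default_registry)
    specialty_clinics: frozenset[str] = frozenset({"vascular surgery"})
    min_age: int = 40
    max_age: int = 89
    onset_age_max: int = 40
    lookback_years: float = 5.0
    reference_date: dt.date | str = "auto"
    min_type3_dates: int = 2
    type2_requires_specialty: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "specialty_clinics", _fold_clinics(self.specialty_clinics)
        )
        if self.min_age >= self.max_age:
            raise ValueError("min_age must be < max_age")
        if self.lookback_years <= 0:
            raise ValueError("lookback_years must be positive")
        if self.min_type3_dates < 2:
            raise ValueError("min_type3_dates must be >= 2")
        if isinstance(self.reference_date, str) and self.reference_date != "auto":
            object.__setattr__(
                self, "reference_date",
                dt.date.fromisoformat(self.reference_date),
            )

    def is_specialty(self, clinic: str) -> bool:
        return clinic.strip().casefold() in self.specialty_clinics

    def to_dict(self) -> dict[str, object]:
        return {
            "specialty_clinics": sorted(self.specialty_clinics),
            "min_age": self.min_age,
            "max_age": self.max_age,
            "onset_age_max": self.onset_age_max,
            "lookback_years": self.lookback_years,
            "reference_date": (
                "auto" if self.reference_date == "auto"
                else self.reference_date.isoformat()
            ),
            "min_type3_dates": self.min_type3_dates,
            "type2_requires_specialty": self.type2_requires_specialty,
            "code_sets": self.registry.as_dict(),
        }


Event = DiagnosisEvent | ProcedureEvent


@dataclasses.dataclass(frozen=True)
class ClassificationResult:
    """Final label for one subject plus the events that triggered it."""

    subject_id: str
    label: Label
    case_type: int | None = None
    exclusion_reason: ExclusionReason | None = None
    evidence: tuple[Event, ...] = ()

    def __post_init__(self) -> None:
        if (self.case_type is not None) != (self.label is Label.CASE):
            raise ValueError("case_type must be set iff label is CASE")
        if (self.exclusion_reason is not None) != (self.label is Label.EXCLUDED):
            raise ValueError("exclusion_reason must be set iff label is EXCLUDED")


@dataclasses.dataclass(frozen=True)
class CohortSummary:
    """Counts per label / case type / exclusion reason for one run."""

    n_subjects: int
    n_cases: int
    n_controls: int
    n_excluded: int
    by_case_type: dict[int, int]
    by_exclusion_reason: dict[str, int]
    reference_date: dt.date

    def to_dict(self) -> dict[str, object]:
        return {
            "n_subjects": self.n_subjects,
            "labels": {
                "case": self.n_cases,
                "control": self.n_controls,
                "excluded": self.n_excluded,
            },
            "case_types": {str(k): v for k, v in sorted(self.by_case_type.items())},
            "exclusion_reasons": dict(sorted(self.by_exclusion_reason.items())),
            "reference_date": self.reference_date.isoformat(),
        }


def _as_events(obj, system: CodingSystem) -> list:
    if isinstance(obj, pd.DataFrame):
        return events_from_frame(obj, system)
    return list(obj)


def resolve_reference_date(dx_events, px_events, config: EngineConfig) -> dt.date:
    """Resolve the anchor date: explicit config value, or latest event date."""
    if config.reference_date != "auto":
        return config.reference_date
    dx = _as_events(dx_events, CodingSystem.ICD9)
    px = _as_events(px_events, CodingSystem.CPT)
    dates = [e.event_date for e in dx] + [e.event_date for e in px]
    if not dates:
        raise ValueError(
            "reference_date='auto' requires at least one event in the cohort"
        )
    return max(dates)


def is_type1(px_events: Sequence[ProcedureEvent],
             registry: CodeSetRegistry) -> tuple[bool, tuple[ProcedureEvent, ...]]:
    """Type 1: any AAA-repair procedure."""
    ev = tuple(e for e in px_events if registry.aaa_repair_px.matches(e.cpt_code))
    return bool(ev), ev


def is_type2(dx_events: Sequence[DiagnosisEvent], registry: CodeSetRegistry,
             config: EngineConfig) -> tuple[bool, tuple[DiagnosisEvent, ...]]:
    """Type 2: ruptured-AAA diagnosis at a specialty clinic."""
    ev = tuple(
        e for e in dx_events
        if registry.aaa_ruptured_dx.matches(e.icd9_code)
        and (not config.type2_requires_specialty or config.is_specialty(e.clinic))
    )
    return bool(ev), ev


def is_type3(dx_events: Sequence[DiagnosisEvent], registry: CodeSetRegistry,
             config: EngineConfig) -> tuple[bool, tuple[DiagnosisEvent, ...]]:
    """Type 3: AAA diagnoses at specialty clinics on ≥ ``min_type3_dates``
    distinct calendar dates."""
    ev = tuple(
        e for e in dx_events
        if registry.aaa_dx.matches(e.icd9_code) and config.is_specialty(e.clinic)
    )
    distinct = {e.event_date for e in ev}
    return len(distinct) >= config.min_type3_dates, ev


def _age_at_reference(events: Sequence[Event], reference_date: dt.date) -> int:
    latest = max(e.event_date for e in events)
    anchor_age = max(e.age_at_event for e in events if e.event_date == latest)
    elapsed = math.floor((reference_date - latest).days / DAYS_PER_YEAR)
    return anchor_age + elapsed


def classify_subject(
    subject_id: str,
    dx_events: Sequence[DiagnosisEvent],
    px_events: Sequence[ProcedureEvent],
    config: EngineConfig,
    reference_date: dt.date,
) -> ClassificationResult:
    """Run the cascade for one subject (events pre-filtered to the subject).

    Rules fire in fixed order; the first match wins:

    1. phenocopy diagnosis → EXCLUDED/PHENOCOPY
    2. reference-date age outside [min_age, max_age] → EXCLUDED/AGE
    3. earliest AAA evidence at age ≤ onset_age_max → EXCLUDED/AAA_ONSET…
    4.–6. case Types 1, 2, 3
    7. residual ``441.*`` diagnosis → EXCLUDED/UNCONFIRMED_AAA_CODE
    8. no event within lookback_years of the reference date (or no events
       at all) → EXCLUDED/NO_RECENT_ENCOUNTER
    9. otherwise → CONTROL
    """
    reg = config.registry

    pheno = tuple(
        e for e in dx_events if reg.phenocopy_exclusion_dx.matches(e.icd9_code)
    )
    if pheno:
        return ClassificationResult(
            subject_id, Label.EXCLUDED,
            exclusion_reason=ExclusionReason.PHENOCOPY, evidence=pheno,
        )

    events: list[Event] = list(dx_events) + list(px_events)
    if events:
        age_ref = _age_at_reference(events, reference_date)
        if age_ref < config.min_age or age_ref > config.max_age:
            latest = max(e.event_date for e in events)
            anchor = tuple(e for e in events if e.event_date == latest)[:1]
            return ClassificationResult(
                subject_id, Label.EXCLUDED,
                exclusion_reason=ExclusionReason.AGE, evidence=anchor,
            )
        aaa_evidence = [
            e for e in dx_events if reg.aaa_dx.matches(e.icd9_code)
        ] + [e for e in px_events if reg.aaa_repair_px.matches(e.cpt_code)]
        if aaa_evidence:
            first = min(aaa_evidence, key=lambda e: e.event_date)
            if first.age_at_event <= config.onset_age_max:
                return ClassificationResult(
                    subject_id, Label.EXCLUDED,
                    exclusion_reason=ExclusionReason.AAA_ONSET_AT_OR_UNDER_MIN_AGE,
                    evidence=(first,),
                )

    hit, ev = is_type1(px_events, reg)
    if hit:
        return ClassificationResult(subject_id, Label.CASE, case_type=1, evidence=ev)
    hit, ev = is_type2(dx_events, reg, config)
    if hit:
        return ClassificationResult(subject_id, Label.CASE, case_type=2, evidence=ev)
    hit, ev = is_type3(dx_events, reg, config)
    if hit:
        return ClassificationResult(subject_id, Label.CASE, case_type=3, evidence=ev)

    residual = tuple(
        e for e in dx_events if reg.control_exclusion_dx.matches(e.icd9_code)
    )
    if residual:
        return ClassificationResult(
            subject_id, Label.EXCLUDED,
            exclusion_reason=ExclusionReason.UNCONFIRMED_AAA_CODE, evidence=residual,
        )

    if not events:
        return ClassificationResult(
            subject_id, Label.EXCLUDED,
            exclusion_reason=ExclusionReason.NO_RECENT_ENCOUNTER,
        )
    latest = max(e.event_date for e in events)
    if (reference_date - latest).days > config.lookback_years * DAYS_PER_YEAR:
        anchor = tuple(e for e in events if e.event_date == latest)[:1]
        return ClassificationResult(
            subject_id, Label.EXCLUDED,
            exclusion_reason=ExclusionReason.NO_RECENT_ENCOUNTER, evidence=anchor,
        )
    return ClassificationResult(subject_id, Label.CONTROL)


def classify_cohort(
    subjects,
    dx_events,
    px_events,
    config: EngineConfig,
) -> tuple[list[ClassificationResult], CohortSummary]:
    """Classify every subject and summarize the cohort.

    ``subjects`` may be a DataFrame with a ``subject_id`` column or an
    iterable of ids; event arguments may be DataFrames (as loaded by
    :func:`aaapheno.model.load_streams`) or lists of event objects.
    """
    if isinstance(subjects, pd.DataFrame):
        ids = [str(s) for s in subjects["subject_id"]]
    else:
        ids = [str(s) for s in subjects]
    seen = set()
    dupes = {s for s in ids if s in seen or seen.add(s)}
    if dupes:
        raise ValueError(f"duplicate subject ids: {sorted(dupes)[:5]}")

    dx = _as_events(dx_events, CodingSystem.ICD9)
    px = _as_events(px_events, CodingSystem.CPT)
    reference_date = resolve_reference_date(dx, px, config)

    dx_by: dict[str, list[DiagnosisEvent]] = defaultdict(list)
    for e in dx:
        dx_by[e.subject_id].append(e)
    px_by: dict[str, list[ProcedureEvent]] = defaultdict(list)
    for e in px:
        px_by[e.subject_id].append(e)

    results = [
        classify_subject(sid, dx_by.get(sid, ()), px_by.get(sid, ()),
                         config, reference_date)
        for sid in ids
    ]

    by_type: dict[int, int] = {1: 0, 2: 0, 3: 0}
    by_reason: dict[str, int] = {}
    n_cases = n_controls = n_excluded = 0
    for r in results:
        if r.label is Label.CASE:
            n_cases += 1
            by_type[r.case_type] += 1
        elif r.label is Label.CONTROL:
            n_controls += 1
        else:
            n_excluded += 1
            key = r.exclusion_reason.value
            by_reason[key] = by_reason.get(key, 0) + 1
    summary = CohortSummary(
        n_subjects=len(ids), n_cases=n_cases, n_controls=n_controls,
        n_excluded=n_excluded, by_case_type=by_type,
        by_exclusion_reason=by_reason, reference_date=reference_date,
    )
    return results, summary


def results_to_frame(results: Sequence[ClassificationResult]) -> pd.DataFrame:
    """Per-subject output table (one row per subject)."""
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in results],
            "label": [r.label.value for r in results],
            "case_type": [r.case_type if r.case_type is not None else ""
                          for r in results],
            "exclusion_reason": [
                r.exclusion_reason.value if r.exclusion_reason else ""
                for r in results
            ],
            "n_evidence_events": [len(r.evidence) for r in results],
        }
    )


def case_type_distribution(results) -> pd.DataFrame:
    """Case counts and percentages by type (rows 1, 2, 3 and "All").

    ``results`` may be a list of :class:`ClassificationResult`, a results
    frame, or a mapping ``{1: n1, 2: n2, 3: n3}``.  Percentages are
    ``100 * count / total cases`` rounded to 1 decimal; with zero cases no
    division is performed and percentages are 0.
    """
    if isinstance(results, dict):
        counts = {t: int(results.get(t, 0)) for t in (1, 2, 3)}
    elif isinstance(results, pd.DataFrame):
        sub = results[results["label"] == "case"]
        vc = sub["case_type"].astype(int).value_counts()
        counts = {t: int(vc.get(t, 0)) for t in (1, 2, 3)}
    else:
        counts = {t: 0 for t in (1, 2, 3)}
        for r in results:
            if r.label is Label.CASE:
                counts[r.case_type] += 1
    total = sum(counts.values())
    rows = []
    for t in (1, 2, 3):
        pct = round(100.0 * counts[t] / total, 1) if total else 0.0
        rows.append({"case_type": str(t), "count": counts[t], "percent": pct})
    rows.append({"case_type": "All", "count": total,
                 "percent": 100.0 if total else 0.0})
    return pd.DataFrame(rows)
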