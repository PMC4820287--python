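"""Synthetic coded-EHR generator with per-subject ground truth.

Real clinical extracts cannot be redistributed, so the engine and the
validation statistics are exercised on simulated subject/diagnosis/procedure
streams instead.  Each generated subject follows one *archetype* — a recipe
constructed to trigger exactly one rule of the classification cascade under
the default engine configuration — and carries a ground-truth record of the
label the engine is expected to assign.  The ten archetypes cover the three
case types, every exclusion reason reachable from coded data, and two
control flavours (a sparse clean record and a code-heavy noisy one).

A cohort is fully reproducible from its seed.  The generator keeps each
subject's ages arithmetically consistent with one latent birth date, so the
engine's reconstruction of age from age-at-event plus elapsed time is exact.
One benign anchor event is always placed on the last day of the simulation
window so that ``reference_date="auto"`` resolves to the window end, which
is the date the recipes are calibrated against.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import enum
from typing import Mapping

import numpy as np
import pandas as pd

from .codesets import CodeSetRegistry, default_registry
from .engine import ExclusionReason, Label

__all__ = [
    "Archetype",
    "SimConfig",
    "SyntheticCohort",
    "generate_cohort",
    "perturb_to_false_positive",
    "BENIGN_ICD9",
    "BENIGN_CPT",
]

# Benign (non-aortic) filler codes used for noise and control histories.
BENIGN_ICD9 = (
    "401.9",   # essential hypertension
    "250.00",  # type 2 diabetes w/o complication
    "272.4",   # hyperlipidemia
    "530.81",  # esophageal reflux
    "414.01",  # coronary atherosclerosis, native artery
    "715.90",  # osteoarthrosis, unspecified
    "786.50",  # chest pain, unspecified
    "599.0",   # urinary tract infection
    "466.0",   # acute bronchitis
    "311",     # depressive disorder NEC
)
BENIGN_CPT = ("99213", "99214", "93000", "80053", "36415")

# Defaults the recipes are calibrated against (the engine's own defaults).
_MIN_AGE = 40
_MAX_AGE = 89
_ONSET_MAX = 40
_LOOKBACK_YEARS = 5.0
_DAYS_PER_YEAR = 365.25


class Archetype(str, enum.Enum):
    TYPE1_CASE = "type1_case"
    TYPE2_CASE = "type2_case"
    TYPE3_CASE = "type3_case"
    PHENOCOPY = "phenocopy"
    YOUNG_AAA = "young_aaa"
    SINGLE_CODE_AAA = "single_code_aaa"
    NONSPECIALTY_AAA = "nonspecialty_aaa"
    STALE_RECORD = "stale_record"
    CLEAN_CONTROL = "clean_control"
    NOISY_CONTROL = "noisy_control"


#: archetype -> (expected label, case type, exclusion reason, is a true case)
EXPECTED: dict[Archetype, tuple[Label, int | None, ExclusionReason | None, bool]] = {
    Archetype.TYPE1_CASE: (Label.CASE, 1, None, True),
    Archetype.TYPE2_CASE: (Label.CASE, 2, None, True),
    Archetype.TYPE3_CASE: (Label.CASE, 3, None, True),
    Archetype.PHENOCOPY: (Label.EXCLUDED, None, ExclusionReason.PHENOCOPY, False),
    Archetype.YOUNG_AAA: (
        Label.EXCLUDED, None, ExclusionReason.AAA_ONSET_AT_OR_UNDER_MIN_AGE, False,
    ),
    Archetype.SINGLE_CODE_AAA: (
        Label.EXCLUDED, None, ExclusionReason.UNCONFIRMED_AAA_CODE, False,
    ),
    Archetype.NONSPECIALTY_AAA: (
        Label.EXCLUDED, None, ExclusionReason.UNCONFIRMED_AAA_CODE, False,
    ),
    Archetype.STALE_RECORD: (
        Label.EXCLUDED, None, ExclusionReason.NO_RECENT_ENCOUNTER, False,
    ),
    Archetype.CLEAN_CONTROL: (Label.CONTROL, None, None, False),
    Archetype.NOISY_CONTROL: (Label.CONTROL, None, None, False),
}


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Specification of one synthetic cohort.

    ``mixture`` maps archetypes to either exact counts (ints summing to
    ``n_subjects``) or proportions (floats summing to 1).  The default
    10-year window leaves room both for the early-onset archetype (an AAA
    code assigned years before the reference date, at age ≤ 40) and for the
    stale-record archetype (latest encounter more than 5 years old).
    """

    n_subjects: int
    mixture: Mapping[Archetype | str, float]
    seed: int = 0
    date_window: tuple[dt.date, dt.date] = (dt.date(2004, 1, 1),
                                            dt.date(2013, 12, 31))
    specialty_clinics: tuple[str, ...] = ("Vascular Surgery",)
    other_clinics: tuple[str, ...] = (
        "Family Practice", "Internal Medicine", "Cardiology",
        "Emergency Medicine",
    )
    noise_rate: float = 2.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        start, end = self.date_window
        if isinstance(start, str):
            object.__setattr__(self, "date_window",
                               (dt.date.fromisoformat(start),
                                dt.date.fromisoformat(str(end))))
            start, end = self.date_window
        if start >= end:
            raise ValueError("empty date window")
        if self.noise_rate < 0:
            raise ValueError("noise_rate must be >= 0")
        mixture = {Archetype(k): v for k, v in self.mixture.items()}
        object.__setattr__(self, "mixture", mixture)

    def resolve_counts(self) -> dict[Archetype, int]:
        """Exact per-archetype subject counts implied by the mixture."""
        values = list(self.mixture.values())
        if all(float(v).is_integer() for v in values) and sum(values) == self.n_subjects:
            return {a: int(v) for a, v in self.mixture.items()}
        total = sum(values)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                "mixture must be exact counts summing to n_subjects or "
                f"proportions summing to 1 (got sum {total})"
            )
        raw = {a: self.n_subjects * v for a, v in self.mixture.items()}
        counts = {a: int(np.floor(x)) for a, x in raw.items()}
        remainder = self.n_subjects - sum(counts.values())
        order = sorted(raw, key=lambda a: (counts[a] - raw[a], a.value))
        for a in order[:remainder]:
            counts[a] += 1
        return counts

    def to_dict(self) -> dict[str, object]:
        return {
            "n_subjects": self.n_subjects,
            "mixture": {a.value: v for a, v in self.mixture.items()},
            "seed": self.seed,
            "date_window": [d.isoformat() for d in self.date_window],
            "specialty_clinics": list(self.specialty_clinics),
            "other_clinics": list(self.other_clinics),
            "noise_rate": self.noise_rate,
        }


@dataclasses.dataclass
class SyntheticCohort:
    """Generated streams + ground truth (plus latent per-subject birth dates)."""

    subjects: pd.DataFrame
    diagnoses: pd.DataFrame
    procedures: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig
    birth_dates: dict[str, dt.date] = dataclasses.field(default_factory=dict)

    def write(self, out_dir) -> dict[str, str]:
        """Serialize the four tables as CSV under ``out_dir``."""
        import os

        from .model import write_streams

        paths = write_streams(out_dir, self.subjects, self.diagnoses,
                              self.procedures)
        truth_path = os.path.join(out_dir, "truth.csv")
        self.truth.to_csv(truth_path, index=False)
        paths["truth"] = truth_path
        return paths


class _SubjectBuilder:
    """Accumulates one subject's events with a consistent latent birth date."""

    def __init__(self, sid: str, birth: dt.date, rng: np.random.Generator,
                 cfg: SimConfig):
        self.sid = sid
        self.birth = birth
        self.rng = rng
        self.cfg = cfg
        self.dx: list[dict] = []
        self.px: list[dict] = []

    def age_at(self, date: dt.date) -> int:
        return int(np.floor((date - self.birth).days / _DAYS_PER_YEAR))

    def add_dx(self, date: dt.date, code: str, clinic: str) -> None:
        self.dx.append({
            "subject_id": self.sid, "event_date": pd.Timestamp(date),
            "icd9_code": code, "clinic": clinic,
            "age_at_event": self.age_at(date),
        })

    def add_px(self, date: dt.date, code: str, clinic: str) -> None:
        self.px.append({
            "subject_id": self.sid, "event_date": pd.Timestamp(date),
            "cpt_code": code, "clinic": clinic,
            "age_at_event": self.age_at(date),
        })

    def random_date(self, lo: dt.date, hi: dt.date) -> dt.date:
        span = (hi - lo).days
        if span < 0:
            raise ValueError("empty date range in recipe")
        return lo + dt.timedelta(days=int(self.rng.integers(0, span + 1)))

    def pick(self, seq):
        return seq[int(self.rng.integers(0, len(seq)))]


def _birth_for_ref_age(ref_age: int, window_end: dt.date,
                       rng: np.random.Generator) -> dt.date:
    # extra < 1 year keeps floor((end - birth)/365.25) == ref_age
    extra = int(rng.integers(30, 330))
    return window_end - dt.timedelta(days=round(ref_age * _DAYS_PER_YEAR) + extra)


def _literal_codes(code_set) -> tuple[str, ...]:
    codes = tuple(sorted(m.pattern for m in code_set.members if not m.is_wildcard))
    if not codes:
        raise ValueError(
            f"code set {code_set.name!r} has no literal members to sample from"
        )
    return codes


def generate_cohort(sim_config: SimConfig,
                    registry: CodeSetRegistry | None = None) -> SyntheticCohort:
    """Generate the three input streams plus ground-truth labels.

    Exact-count mixtures produce exactly the requested archetype counts;
    identical config + seed produce identical streams.
    """
    registry = registry or default_registry()
    cfg = sim_config
    counts = cfg.resolve_counts()
    if sum(counts.values()) != cfg.n_subjects:
        raise ValueError("mixture counts do not sum to n_subjects")
    non_stale = [a for a, n in counts.items() if n and a is not Archetype.STALE_RECORD]
    if not non_stale:
        raise ValueError(
            "mixture contains only stale-record subjects; the auto reference "
            "date would not resolve to the window end"
        )

    rng = np.random.default_rng(cfg.seed)
    ws, we = cfg.date_window
    lookback = dt.timedelta(days=int(np.ceil(_LOOKBACK_YEARS * _DAYS_PER_YEAR)))
    recent_lo = max(ws, we - dt.timedelta(days=int(2 * _DAYS_PER_YEAR)))

    unruptured = _literal_codes(registry.aaa_unruptured_dx)
    ruptured = _literal_codes(registry.aaa_ruptured_dx)
    repairs = _literal_codes(registry.aaa_repair_px)
    phenocopies = _literal_codes(registry.phenocopy_exclusion_dx)

    order: list[Archetype] = []
    for a in Archetype:
        order.extend([a] * counts.get(a, 0))

    builders: list[tuple[_SubjectBuilder, Archetype]] = []
    truth_rows = []
    births: dict[str, dt.date] = {}
    width = max(4, len(str(cfg.n_subjects)))
    for i, arch in enumerate(order, start=1):
        sid = f"S{i:0{width}d}"
        b, cap = _build_subject(sid, arch, rng, cfg, registry, ws, we,
                                recent_lo, lookback,
                                unruptured, ruptured, repairs, phenocopies)
        _add_noise(b, cap, ws)
        builders.append((b, arch))
        births[sid] = b.birth
        label, ctype, reason, true_case = EXPECTED[arch]
        truth_rows.append({
            "subject_id": sid, "archetype": arch.value,
            "expected_label": label.value,
            "expected_case_type": ctype if ctype is not None else "",
            "expected_exclusion_reason": reason.value if reason else "",
            "true_case": true_case, "perturbed": False,
        })

    # anchor the auto reference date at the window end
    for b, arch in builders:
        if arch is not Archetype.STALE_RECORD:
            b.add_dx(we, b.pick(BENIGN_ICD9), b.pick(cfg.other_clinics))
            break

    dx = pd.DataFrame(
        [e for b, _ in builders for e in b.dx],
        columns=["subject_id", "event_date", "icd9_code", "clinic", "age_at_event"],
    )
    px = pd.DataFrame(
        [e for b, _ in builders for e in b.px],
        columns=["subject_id", "event_date", "cpt_code", "clinic", "age_at_event"],
    )
    subjects = pd.DataFrame({"subject_id": [b.sid for b, _ in builders]})
    truth = pd.DataFrame(truth_rows)
    return SyntheticCohort(subjects=subjects, diagnoses=dx, procedures=px,
                           truth=truth, config=cfg, birth_dates=births)


def _build_subject(sid, arch, rng, cfg, registry, ws, we, recent_lo, lookback,
                   unruptured, ruptured, repairs, phenocopies):
    """Build one subject per its archetype recipe.

    Returns (builder, latest_allowed_event_date) — the cap constrains noise
    so it cannot break the recipe (only the stale record caps it early).
    """
    specialty = cfg.specialty_clinics
    other = cfg.other_clinics

    onset_age = None
    if arch is Archetype.YOUNG_AAA:
        onset_age = 36 + int(rng.integers(0, 4))           # 36–39 (≤ 40)
        ref_age = max(onset_age + 2 + int(rng.integers(0, 4)), _MIN_AGE + 1)
    elif arch is Archetype.STALE_RECORD:
        ref_age = 55 + int(rng.integers(0, 26))            # 55–80
    elif arch in (Archetype.CLEAN_CONTROL, Archetype.NOISY_CONTROL):
        ref_age = 50 + int(rng.integers(0, 36))            # 50–85
    else:
        ref_age = 58 + int(rng.integers(0, 28))            # 58–85

    b = _SubjectBuilder(sid, _birth_for_ref_age(ref_age, we, rng), rng, cfg)
    cap = we
    # earliest date at which any AAA evidence is safely past the onset bound
    adult = max(ws, b.birth + dt.timedelta(days=round(46 * _DAYS_PER_YEAR)))

    if arch is Archetype.TYPE1_CASE:
        b.add_px(b.random_date(adult, we), b.pick(repairs), b.pick(specialty))
        if rng.random() < 0.4:
            b.add_dx(b.random_date(adult, we), b.pick(unruptured),
                     b.pick(specialty))
    elif arch is Archetype.TYPE2_CASE:
        b.add_dx(b.random_date(adult, we), b.pick(ruptured), b.pick(specialty))
        if rng.random() < 0.3:
            b.add_dx(b.random_date(adult, we), b.pick(unruptured),
                     b.pick(specialty))
    elif arch is Archetype.TYPE3_CASE:
        k = 2 + int(rng.integers(0, 3))
        span = (we - adult).days
        offsets = rng.choice(span + 1, size=min(k, span + 1), replace=False)
        for off in offsets:
            b.add_dx(adult + dt.timedelta(days=int(off)), b.pick(unruptured),
                     b.pick(specialty))
    elif arch is Archetype.PHENOCOPY:
        b.add_dx(b.random_date(adult, we), b.pick(phenocopies), b.pick(other))
        if rng.random() < 0.5:
            # would otherwise qualify as Type 3; the phenocopy rule must win
            d1 = b.random_date(adult, we - dt.timedelta(days=40))
            b.add_dx(d1, b.pick(unruptured), b.pick(specialty))
            b.add_dx(d1 + dt.timedelta(days=30), b.pick(unruptured),
                     b.pick(specialty))
    elif arch is Archetype.YOUNG_AAA:
        # onset event at age ≤ 40, then later specialty AAA codes that would
        # qualify as Type 3 were the onset rule absent
        onset_lo = max(ws, b.birth + dt.timedelta(
            days=round(onset_age * _DAYS_PER_YEAR) + 10))
        onset_hi = min(we, b.birth + dt.timedelta(
            days=round((onset_age + 1) * _DAYS_PER_YEAR) - 10))
        onset = b.random_date(onset_lo, onset_hi)
        b.add_dx(onset, b.pick(unruptured), b.pick(specialty))
        later = b.random_date(min(onset + dt.timedelta(days=60), we), we)
        b.add_dx(later, b.pick(unruptured), b.pick(specialty))
        b.add_dx(b.random_date(recent_lo, we), b.pick(BENIGN_ICD9), b.pick(other))
    elif arch is Archetype.SINGLE_CODE_AAA:
        b.add_dx(b.random_date(adult, we), b.pick(unruptured), b.pick(specialty))
        b.add_dx(b.random_date(recent_lo, we), b.pick(BENIGN_ICD9), b.pick(other))
    elif arch is Archetype.NONSPECIALTY_AAA:
        k = 2 + int(rng.integers(0, 2))
        span = (we - adult).days
        offsets = rng.choice(span + 1, size=min(k, span + 1), replace=False)
        for off in offsets:
            b.add_dx(adult + dt.timedelta(days=int(off)), b.pick(unruptured),
                     b.pick(other))
    elif arch is Archetype.STALE_RECORD:
        cap = we - lookback - dt.timedelta(days=1 + int(rng.integers(0, 700)))
        for _ in range(1 + int(rng.integers(0, 4))):
            b.add_dx(b.random_date(ws, cap), b.pick(BENIGN_ICD9), b.pick(other))
    elif arch is Archetype.CLEAN_CONTROL:
        for _ in range(1 + int(rng.integers(0, 3))):
            b.add_dx(b.random_date(ws, we), b.pick(BENIGN_ICD9), b.pick(other))
        b.add_dx(b.random_date(recent_lo, we), b.pick(BENIGN_ICD9), b.pick(other))
        if rng.random() < 0.3:
            b.add_px(b.random_date(ws, we), b.pick(BENIGN_CPT), b.pick(other))
    elif arch is Archetype.NOISY_CONTROL:
        for _ in range(5 + int(rng.integers(0, 7))):
            b.add_dx(b.random_date(ws, we), b.pick(BENIGN_ICD9),
                     b.pick(other + specialty))
        b.add_dx(b.random_date(recent_lo, we), b.pick(BENIGN_ICD9), b.pick(other))
        for _ in range(1 + int(rng.integers(0, 3))):
            b.add_px(b.random_date(ws, we), b.pick(BENIGN_CPT), b.pick(other))
    return b, cap


def _add_noise(b: _SubjectBuilder, cap: dt.date, ws: dt.date) -> None:
    n = int(b.rng.poisson(b.cfg.noise_rate))
    for _ in range(n):
        b.add_dx(b.random_date(ws, cap), b.pick(BENIGN_ICD9),
                 b.pick(b.cfg.other_clinics))


def perturb_to_false_positive(cohort: SyntheticCohort, k: int,
                              seed: int) -> SyntheticCohort:
    """Turn ``k`` clean-control subjects into engine-level Type 3 cases whose
    ground truth stays non-case.

    Models the chart-review false positives seen in practice: subjects with
    repeated specialty AAA codes (e.g. pre-aneurysmal aortic dilatation later
    revised on imaging) whom the code-only algorithm cannot distinguish from
    true cases.  With ``n`` predicted cases after planting, full-review PPV
    is analytically ``100 * (n - k) / n``.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    pool = sorted(
        cohort.truth.loc[
            (cohort.truth["archetype"] == Archetype.CLEAN_CONTROL.value)
            & (~cohort.truth["perturbed"]),
            "subject_id",
        ]
    )
    if k > len(pool):
        raise ValueError(
            f"k={k} exceeds the {len(pool)} clean-control subjects available"
        )
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(pool, size=k, replace=False)) if k else []

    ws, we = cohort.config.date_window
    recent_lo = max(ws, we - dt.timedelta(days=int(2 * _DAYS_PER_YEAR)))
    span = (we - recent_lo).days

    dx_new = []
    truth = cohort.truth.copy()
    registry = default_registry()
    unruptured = _literal_codes(registry.aaa_unruptured_dx)
    for sid in chosen:
        birth = cohort.birth_dates.get(sid)
        if birth is None:
            raise ValueError(
                "cohort carries no latent birth dates (was it re-loaded from "
                "disk?); perturb the in-session cohort instead"
            )
        offsets = rng.choice(span + 1, size=2, replace=False)
        for off in sorted(int(o) for o in offsets):
            date = recent_lo + dt.timedelta(days=off)
            age = int(np.floor((date - birth).days / _DAYS_PER_YEAR))
            dx_new.append({
                "subject_id": sid, "event_date": pd.Timestamp(date),
                "icd9_code": unruptured[int(rng.integers(0, len(unruptured)))],
                "clinic": cohort.config.specialty_clinics[0],
                "age_at_event": age,
            })
        sel = truth["subject_id"] == sid
        truth.loc[sel, "expected_label"] = Label.CASE.value
        truth.loc[sel, "expected_case_type"] = 3
        truth.loc[sel, "expected_exclusion_reason"] = ""
        truth.loc[sel, "perturbed"] = True
        # true_case stays False: these are planted false positives

    diagnoses = pd.concat(
        [cohort.diagnoses, pd.DataFrame(dx_new, columns=cohort.diagnoses.columns)],
        ignore_index=True,
    ) if dx_new else cohort.diagnoses.copy()
    return SyntheticCohort(
        subjects=cohort.subjects.copy(), diagnoses=diagnoses,
        procedures=cohort.procedures.copy(), truth=truth,
        config=cohort.config, birth_dates=dict(cohort.birth_dates),
    )
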