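"""Independent brute-force re-implementation of the classification rules.

Used only as a test oracle: evaluates all nine predicates unordered on raw
event lists (with its own regex-based wildcard matching, no shared rule
code), then applies the documented priority.  Also provides a fuzz
generator of random small cohorts whose events need not follow any
archetype.
"""

from __future__ import annotations

import datetime as dt
import math
import random
import re


def _wildcard_match(pattern: str, code: str) -> bool:
    if pattern.endswith(".*"):
        prefix = re.escape(pattern[:-2])
        return re.fullmatch(prefix + r"(\.\d{1,2})?", code) is not None
    return pattern == code


def _in_set(code_set, code: str) -> bool:
    return any(_wildcard_match(m.pattern, code) for m in code_set.members)


def reference_classify(sid, dx_events, px_events, config, reference_date):
    """Returns (label, case_type, exclusion_reason) as plain strings/ints."""
    reg = config.registry
    spec = {c.strip().casefold() for c in config.specialty_clinics}
    events = list(dx_events) + list(px_events)

    # all predicates, evaluated independently and unordered
    p_phenocopy = any(
        _in_set(reg.phenocopy_exclusion_dx, e.icd9_code) for e in dx_events
    )
    p_age_out = False
    p_onset = False
    if events:
        latest = max(e.event_date for e in events)
        anchor = max(e.age_at_event for e in events if e.event_date == latest)
        ref_age = anchor + math.floor((reference_date - latest).days / 365.25)
        p_age_out = ref_age < config.min_age or ref_age > config.max_age
        aaa = [e for e in dx_events if _in_set(reg.aaa_dx, e.icd9_code)]
        aaa += [e for e in px_events if _in_set(reg.aaa_repair_px, e.cpt_code)]
        if aaa:
            first = min(aaa, key=lambda e: e.event_date)
            p_onset = first.age_at_event <= config.onset_age_max
    p_t1 = any(_in_set(reg.aaa_repair_px, e.cpt_code) for e in px_events)
    p_t2 = any(
        _in_set(reg.aaa_ruptured_dx, e.icd9_code)
        and (not config.type2_requires_specialty
             or e.clinic.strip().casefold() in spec)
        for e in dx_events
    )
    t3_dates = {
        e.event_date for e in dx_events
        if _in_set(reg.aaa_dx, e.icd9_code)
        and e.clinic.strip().casefold() in spec
    }
    p_t3 = len(t3_dates) >= config.min_type3_dates
    p_residual = any(
        _in_set(reg.control_exclusion_dx, e.icd9_code) for e in dx_events
    )
    if events:
        latest = max(e.event_date for e in events)
        p_stale = (reference_date - latest).days > config.lookback_years * 365.25
    else:
        p_stale = True

    # documented priority
    if p_phenocopy:
        return "excluded", None, "phenocopy"
    if p_age_out:
        return "excluded", None, "age"
    if p_onset:
        return "excluded", None, "aaa_onset_at_or_under_min_age"
    if p_t1:
        return "case", 1, None
    if p_t2:
        return "case", 2, None
    if p_t3:
        return "case", 3, None
    if p_residual:
        return "excluded", None, "unconfirmed_aaa_code"
    if p_stale:
        return "excluded", None, "no_recent_encounter"
    return "control", None, None


# ---------------------------------------------------------------------------
# fuzz cohorts
# ---------------------------------------------------------------------------

_DX_POOL = [
    "441.3", "441.4", "441", "441.02", "441.9", "759.82", "756.83", "437.5",
    "401.9", "250.00", "272.4", "786.50", "442.4", "593.9",
]
_PX_POOL = ["34802", "35081", "34830", "99213", "93000", "80053"]
_CLINICS = [
    "Vascular Surgery", "vascular surgery", " Vascular Surgery ",
    "Family Practice", "Cardiology", "Emergency Medicine", "",
]


def random_cohort(seed: int, n_subjects: int = 50):
    """Random valid cohort: (ids, dx_events, px_events), ages consistent
    with one latent birth year per subject."""
    from aaapheno import DiagnosisEvent, ProcedureEvent

    rnd = random.Random(seed)
    ids, dx_events, px_events = [], [], []
    start = dt.date(2004, 1, 1)
    span = (dt.date(2013, 12, 31) - start).days
    for i in range(n_subjects):
        sid = f"F{i:04d}"
        ids.append(sid)
        birth = dt.date(rnd.randint(1920, 1978), rnd.randint(1, 12),
                        rnd.randint(1, 28))
        for _ in range(rnd.randint(0, 6)):
            date = start + dt.timedelta(days=rnd.randint(0, span))
            dx_events.append(DiagnosisEvent(
                subject_id=sid, event_date=date,
                icd9_code=rnd.choice(_DX_POOL), clinic=rnd.choice(_CLINICS),
                age_at_event=max(0, math.floor((date - birth).days / 365.25)),
            ))
        for _ in range(rnd.randint(0, 2)):
            date = start + dt.timedelta(days=rnd.randint(0, span))
            px_events.append(ProcedureEvent(
                subject_id=sid, event_date=date,
                cpt_code=rnd.choice(_PX_POOL), clinic=rnd.choice(_CLINICS),
                age_at_event=max(0, math.floor((date - birth).days / 365.25)),
            ))
    return ids, dx_events, px_events
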