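import datetime as dt

import pytest

from aaapheno import DiagnosisEvent, EngineConfig, ProcedureEvent, default_registry


def dx(sid, date, code, clinic="Vascular Surgery", age=70):
    return DiagnosisEvent(
        subject_id=sid, event_date=dt.date.fromisoformat(date),
        icd9_code=code, clinic=clinic, age_at_event=age,
    )


def px(sid, date, code, clinic="Vascular Surgery", age=70):
    return ProcedureEvent(
        subject_id=sid, event_date=dt.date.fromisoformat(date),
        cpt_code=code, clinic=clinic, age_at_event=age,
    )


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture
def config(registry):
    return EngineConfig(
        registry=registry,
        specialty_clinics=frozenset({"vascular surgery"}),
        reference_date=dt.date(2013, 12, 31),
    )
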