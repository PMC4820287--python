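import datetime as dt

import pytest

from aaapheno import (
    DiagnosisEvent,
    EngineConfig,
    ExclusionReason,
    Label,
    case_type_distribution,
    classify_cohort,
    classify_subject,
    results_to_frame,
)
from aaapheno.engine import is_type1, is_type2, is_type3, resolve_reference_date

from conftest import dx, px
from reference_classifier import random_cohort, reference_classify

REF = dt.date(2013, 12, 31)


class TestResolveReferenceDate:
    def test_explicit(self, registry):
        cfg = EngineConfig(registry=registry, reference_date=dt.date(2013, 1, 1))
        assert resolve_reference_date([], [], cfg) == dt.date(2013, 1, 1)

    def test_auto_is_latest_event(self, registry):
        cfg = EngineConfig(registry=registry)
        events = [dx("A", "2010-05-01", "401.9"), dx("A", "2012-03-02", "401.9")]
        assert resolve_reference_date(events, [], cfg) == dt.date(2012, 3, 2)

    def test_auto_without_events_errors(self, registry):
        with pytest.raises(ValueError, match="auto"):
            resolve_reference_date([], [], EngineConfig(registry=registry))


class TestCasePredicates:
    def test_type1_any_repair_procedure(self, registry):
        hit, ev = is_type1([px("A", "2010-01-01", "34802", age=65)], registry)
        assert hit and len(ev) == 1
        hit, _ = is_type1([px("A", "2010-01-01", "99213")], registry)
        assert not hit
        hit, ev = is_type1(
            [px("A", "2010-01-01", "34802"), px("A", "2011-01-01", "35081")],
            registry,
        )
        assert hit and len(ev) == 2  # all repair events kept as evidence

    def test_type2_needs_ruptured_code_at_specialty(self, registry, config):
        assert is_type2([dx("A", "2010-01-01", "441.3")], registry, config)[0]
        assert not is_type2(
            [dx("A", "2010-01-01", "441.3", clinic="Family Practice")],
            registry, config,
        )[0]
        assert not is_type2([dx("A", "2010-01-01", "441.4")], registry, config)[0]

    def test_type2_specialty_requirement_relaxable(self, registry):
        cfg = EngineConfig(registry=registry, type2_requires_specialty=False,
                           reference_date=REF)
        assert is_type2(
            [dx("A", "2010-01-01", "441.3", clinic="Family Practice")],
            registry, cfg,
        )[0]

    def test_type3_two_distinct_specialty_dates(self, registry, config):
        two_dates = [dx("A", "2010-01-05", "441.4"), dx("A", "2010-06-07", "441.4")]
        assert is_type3(two_dates, registry, config)[0]
        same_day = [dx("A", "2010-01-05", "441.4"), dx("A", "2010-01-05", "441.4")]
        assert not is_type3(same_day, registry, config)[0]
        mixed = [dx("A", "2010-01-05", "441.4"),
                 dx("A", "2010-06-07", "441.4", clinic="Family Practice")]
        assert not is_type3(mixed, registry, config)[0]

    def test_clinic_match_trims_and_casefolds(self, registry, config):
        events = [dx("A", "2010-01-05", "441.4", clinic=" VASCULAR SURGERY "),
                  dx("A", "2010-06-07", "441.4", clinic="vascular surgery")]
        assert is_type3(events, registry, config)[0]


class TestClassifySubject:
    def test_phenocopy_beats_case_typing(self, config):
        events = [
            dx("A", "2010-01-05", "759.82", clinic="Genetics"),
            dx("A", "2010-02-05", "441.4"),
            dx("A", "2010-06-07", "441.4"),
        ]
        r = classify_subject("A", events, [], config, REF)
        assert r.label is Label.EXCLUDED
        assert r.exclusion_reason is ExclusionReason.PHENOCOPY

    def test_type1_beats_type3(self, config):
        events = [dx("A", "2010-01-05", "441.4"), dx("A", "2010-06-07", "441.4"),
                  dx("A", "2011-01-05", "441.4")]
        r = classify_subject("A", events, [px("A", "2011-02-01", "35081")],
                             config, REF)
        assert (r.label, r.case_type) == (Label.CASE, 1)

    def test_type2_beats_type3(self, config):
        events = [dx("A", "2010-01-05", "441.4"), dx("A", "2010-06-07", "441.4"),
                  dx("A", "2011-01-05", "441.3")]
        r = classify_subject("A", events, [], config, REF)
        assert (r.label, r.case_type) == (Label.CASE, 2)

    def test_single_aaa_code_is_unconfirmed(self, config):
        events = [dx("A", "2013-01-05", "441.4"),
                  dx("A", "2013-06-07", "401.9", clinic="Family Practice")]
        r = classify_subject("A", events, [], config, REF)
        assert r.exclusion_reason is ExclusionReason.UNCONFIRMED_AAA_CODE

    def test_bare_441_blocks_control(self, config):
        events = [dx("A", "2013-01-05", "441", clinic="Family Practice"),
                  dx("A", "2013-06-07", "401.9", clinic="Family Practice")]
        r = classify_subject("A", events, [], config, REF)
        assert r.exclusion_reason is ExclusionReason.UNCONFIRMED_AAA_CODE

    @pytest.mark.parametrize(
        "age, expected",
        [(39, ExclusionReason.AGE), (40, None), (89, None),
         (90, ExclusionReason.AGE)],
    )
    def test_reference_age_bounds_inclusive(self, config, age, expected):
        events = [dx("A", "2013-12-31", "401.9", clinic="FP", age=age)]
        r = classify_subject("A", events, [], config, REF)
        if expected:
            assert r.exclusion_reason is expected
        else:
            assert r.label is Label.CONTROL

    def test_age_advances_with_elapsed_years(self, config):
        # 38 at the last event in 2010 -> 41 at the 2013-12-31 reference
        events = [dx("A", "2010-06-01", "401.9", clinic="FP", age=38)]
        r = classify_subject("A", events, [], config, REF)
        assert r.label is Label.CONTROL

    def test_early_onset_aaa_excluded(self, config):
        events = [dx("A", "2006-01-05", "441.4", age=38),
                  dx("A", "2012-01-05", "441.4", age=44),
                  dx("A", "2013-06-01", "401.9", clinic="FP", age=45)]
        r = classify_subject("A", events, [], config, REF)
        assert r.exclusion_reason is ExclusionReason.AAA_ONSET_AT_OR_UNDER_MIN_AGE

    def test_recency_boundary(self, config):
        # exactly 5 * 365.25 days before the reference is still recent
        exactly = REF - dt.timedelta(days=int(5 * 365.25))
        r = classify_subject(
            "A", [dx("A", exactly.isoformat(), "401.9", clinic="FP", age=70)],
            [], config, REF)
        assert r.label is Label.CONTROL
        older = exactly - dt.timedelta(days=2)
        r = classify_subject(
            "A", [dx("A", older.isoformat(), "401.9", clinic="FP", age=70)],
            [], config, REF)
        assert r.exclusion_reason is ExclusionReason.NO_RECENT_ENCOUNTER

    def test_no_events_is_no_recent_encounter(self, config):
        r = classify_subject("A", [], [], config, REF)
        assert r.exclusion_reason is ExclusionReason.NO_RECENT_ENCOUNTER

    def test_type3_evidence_has_min_distinct_dates(self, config):
        events = [dx("A", "2010-01-05", "441.4"), dx("A", "2010-06-07", "441.4")]
        r = classify_subject("A", events, [], config, REF)
        assert (r.label, r.case_type) == (Label.CASE, 3)
        assert len({e.event_date for e in r.evidence}) >= config.min_type3_dates


def _six_subject_cohort():
    """One archetype each: type1, type2, type3, phenocopy, single-code,
    clean control (hand-evaluated against the cascade)."""
    dx_events = [
        dx("T2", "2011-03-01", "441.3", age=75),
        dx("T3", "2010-01-05", "441.4", age=68),
        dx("T3", "2010-06-07", "441.4", age=68),
        dx("PH", "2009-04-01", "759.82", clinic="Genetics", age=50),
        dx("SC", "2013-02-01", "441.4", age=71),
        dx("CC", "2013-05-01", "401.9", clinic="Family Practice", age=60),
    ]
    px_events = [px("T1", "2012-07-15", "34802", age=66)]
    ids = ["T1", "T2", "T3", "PH", "SC", "CC"]
    return ids, dx_events, px_events


class TestClassifyCohort:
    def test_six_archetype_cohort(self, config):
        ids, dxe, pxe = _six_subject_cohort()
        results, summary = classify_cohort(ids, dxe, pxe, config)
        assert (summary.n_cases, summary.n_controls, summary.n_excluded) == (3, 1, 2)
        by_id = {r.subject_id: r for r in results}
        assert by_id["T1"].case_type == 1
        assert by_id["T2"].case_type == 2
        assert by_id["T3"].case_type == 3
        assert by_id["PH"].exclusion_reason is ExclusionReason.PHENOCOPY
        assert by_id["SC"].exclusion_reason is ExclusionReason.UNCONFIRMED_AAA_CODE
        assert by_id["CC"].label is Label.CONTROL

    def test_counts_partition_cohort(self, config):
        ids, dxe, pxe = random_cohort(seed=11, n_subjects=40)
        results, summary = classify_cohort(ids, dxe, pxe, config)
        assert len(results) == 40
        assert summary.n_cases + summary.n_controls + summary.n_excluded == 40
        assert sum(summary.by_case_type.values()) == summary.n_cases
        assert sum(summary.by_exclusion_reason.values()) == summary.n_excluded

    def test_duplicate_ids_rejected(self, config):
        with pytest.raises(ValueError, match="duplicate"):
            classify_cohort(["A", "A"], [dx("A", "2013-01-01", "401.9")], [],
                            config)

    def test_auto_reference_with_no_events_errors(self, registry):
        cfg = EngineConfig(registry=registry)  # reference_date="auto"
        with pytest.raises(ValueError):
            classify_cohort(["A", "B"], [], [], cfg)

    def test_control_purity(self, config):
        """No CONTROL subject carries any diagnosis matched by 441.* —
        asserted over the raw events, independent of the cascade."""
        ids, dxe, pxe = random_cohort(seed=23, n_subjects=60)
        results, _ = classify_cohort(ids, dxe, pxe, config)
        controls = {r.subject_id for r in results if r.label is Label.CONTROL}
        for e in dxe:
            if e.subject_id in controls:
                assert not config.registry.control_exclusion_dx.matches(
                    e.icd9_code)

    def test_determinism_byte_identical(self, config):
        ids, dxe, pxe = random_cohort(seed=7, n_subjects=30)
        a = results_to_frame(classify_cohort(ids, dxe, pxe, config)[0])
        b = results_to_frame(classify_cohort(ids, dxe, pxe, config)[0])
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_monotone_safety_phenocopy_injection(self, config):
        """Adding a phenocopy event can only move a subject to EXCLUDED."""
        ids, dxe, pxe = random_cohort(seed=3, n_subjects=30)
        poison = [dx(s, "2012-01-01", "759.82", clinic="Genetics", age=60)
                  for s in ids]
        results, _ = classify_cohort(ids, dxe + poison, pxe, config)
        assert all(r.label is Label.EXCLUDED for r in results)
        assert all(r.exclusion_reason is ExclusionReason.PHENOCOPY
                   for r in results)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_reference_classifier(self, config, seed):
        ids, dxe, pxe = random_cohort(seed=seed, n_subjects=50)
        results, _ = classify_cohort(ids, dxe, pxe, config)
        dx_by, px_by = {}, {}
        for e in dxe:
            dx_by.setdefault(e.subject_id, []).append(e)
        for e in pxe:
            px_by.setdefault(e.subject_id, []).append(e)
        for r in results:
            expected = reference_classify(
                r.subject_id, dx_by.get(r.subject_id, []),
                px_by.get(r.subject_id, []), config, REF)
            got = (r.label.value, r.case_type,
                   r.exclusion_reason.value if r.exclusion_reason else None)
            assert got == expected, r.subject_id


class TestCaseTypeDistribution:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ({1: 295, 2: 16, 3: 388}, [42.2, 2.3, 55.5]),
            ({1: 0, 2: 7, 3: 249}, [0.0, 2.7, 97.3]),
            # 106/178 rounds to 59.6 at one decimal
            ({1: 72, 2: 0, 3: 106}, [40.4, 0.0, 59.6]),
        ],
    )
    def test_percentages(self, counts, expected):
        table = case_type_distribution(counts)
        assert list(table["percent"][:3]) == expected
        assert table.iloc[3]["count"] == sum(counts.values())
        assert table.iloc[3]["percent"] == 100.0

    def test_zero_cases_no_division(self):
        table = case_type_distribution({})
        assert table.iloc[3]["count"] == 0
        assert all(table["percent"] == 0.0)

    def test_from_results(self, config):
        ids, dxe, pxe = _six_subject_cohort()
        results, _ = classify_cohort(ids, dxe, pxe, config)
        table = case_type_distribution(results)
        assert list(table["count"]) == [1, 1, 1, 3]
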