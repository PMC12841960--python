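import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pfhb import (
    Annotation,
    HILIndices,
    ReportStatus,
    SampleRecord,
    ThresholdConfig,
    decide,
    decide_batch,
)


class TestRecordInvariants:
    def test_dbil_cannot_exceed_tbil(self):
        with pytest.raises(ValueError, match="dbil"):
            SampleRecord("S", HILIndices(0, 0, 0), tbil=10.0, dbil=20.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            SampleRecord("S", HILIndices(0, 0, 0), fhb=-5.0)


class TestWorkedDecisions:
    def test_icteric_restriction_blocks_without_clinician_request(self, cfg):
        rec = SampleRecord("S", HILIndices(0, 5.0, 0), fhb=100.0, tbil=120.0)
        d = decide(rec, cfg)
        assert d.status is ReportStatus.CLINICIAN_REQUEST_ONLY
        assert Annotation.ICTERIC_INTERFERENCE.value in d.annotations

    def test_benign_record_reports_plainly(self, cfg, benign_record):
        d = decide(benign_record(), cfg)
        assert d.status is ReportStatus.REPORT
        assert d.annotations == ()

    def test_unremovable_lipemia_low_fhb_reports_with_annotation(self, cfg, benign_record):
        rec = benign_record(
            fhb=30.0, lipemia_present=True, parenteral_nutrition=True,
            nutrition_discontinuable=False,
        )
        d = decide(rec, cfg)
        assert d.status is ReportStatus.REPORT_WITH_ANNOTATION
        assert d.annotations == (Annotation.LIPEMIC_SAMPLE.value,)

    def test_high_h_index_unverified_venipuncture_blocks(self, cfg, benign_record):
        rec = benign_record(hil=HILIndices(15.0, 0, 0), venipuncture_verified=False)
        assert decide(rec, cfg).status is ReportStatus.VERIFY_PREANALYTICS

    def test_severe_hemolysis_review_annotated(self, cfg, benign_record):
        rec = benign_record(fhb=250.0, tbil=50.0, venipuncture_verified=False)
        d = decide(rec, cfg)
        assert d.status is ReportStatus.VERIFY_PREANALYTICS
        assert Annotation.REVIEW_SAMPLING.value in d.annotations

    def test_icterus_without_tbil_demands_reflex_test(self, cfg, benign_record):
        rec = benign_record(hil=HILIndices(0, 6.0, 0), tbil=None, dbil=None)
        assert decide(rec, cfg).status is ReportStatus.NEEDS_TBIL

    def test_high_fhb_without_tbil_demands_reflex_test(self, cfg, benign_record):
        rec = benign_record(fhb=250.0, tbil=None, dbil=None,
                            venipuncture_verified=False)
        assert decide(rec, cfg).status is ReportStatus.NEEDS_TBIL

    def test_clinician_request_converts_block_to_annotated_report(self, cfg):
        rec = SampleRecord(
            "S", HILIndices(0, 5.0, 0), fhb=100.0, tbil=120.0,
            clinician_requested=True, venipuncture_verified=True,
        )
        d = decide(rec, cfg)
        assert d.status is ReportStatus.REPORT_WITH_ANNOTATION
        assert d.annotations == (Annotation.ICTERIC_INTERFERENCE.value,)

    def test_removable_lipemia_requests_new_sample(self, cfg, benign_record):
        for flags in (
            dict(parenteral_nutrition=True, nutrition_discontinuable=True),
            dict(propofol_sedation=True, sedation_adjustable=True),
        ):
            rec = benign_record(lipemia_present=True, **flags)
            assert decide(rec, cfg).status is ReportStatus.REQUEST_NEW_SAMPLE

    def test_missing_fhb_error_names_the_rule(self, cfg, benign_record):
        rec = benign_record(fhb=None, lipemia_present=True,
                            parenteral_nutrition=True)
        with pytest.raises(ValueError, match="lipemia_report"):
            decide(rec, cfg)


SCAN_CASES = [
    # (description, threshold value, strict_side, record factory taking the scanned value)
    ("icterus_index", 4.0, "above",
     lambda v: dict(hil=HILIndices(0, v, 0), tbil=120.0)),
    ("tbil_restrict", 75.0, "at_or_above",
     lambda v: dict(hil=HILIndices(0, 5.0, 0), tbil=v, dbil=None)),
    ("h_index", 10.0, "above",
     lambda v: dict(hil=HILIndices(v, 0, 0), venipuncture_verified=False)),
    ("fhb_review", 200.0, "above",
     lambda v: dict(fhb=v, tbil=50.0, venipuncture_verified=False)),
]


class TestThresholdScans:
    """Scanning one input with all else benign must switch the status exactly
    once, at the configured threshold, with the documented strictness."""

    @pytest.mark.parametrize("name,thr,side,make", SCAN_CASES,
                             ids=[c[0] for c in SCAN_CASES])
    def test_single_switch_at_threshold(self, cfg, benign_record, name, thr, side, make):
        eps = 1e-9
        grid = [0.0, thr / 2, thr - 0.5, thr - eps, thr, thr + eps,
                thr + 0.5, thr * 2]
        statuses = [decide(benign_record(**make(v)), cfg).status for v in grid]
        switches = sum(1 for a, b in zip(statuses, statuses[1:]) if a != b)
        assert switches == 1
        at_thr = decide(benign_record(**make(thr)), cfg).status
        just_above = decide(benign_record(**make(thr + eps)), cfg).status
        below = decide(benign_record(**make(thr - 0.5)), cfg).status
        if side == "above":  # strict: the threshold itself does not fire
            assert at_thr == below and just_above != below
        else:  # inclusive: the threshold itself fires
            assert at_thr == just_above and at_thr != below

    def test_lipemic_reportability_boundary_strict_below(self, cfg, benign_record):
        def status(fhb):
            rec = benign_record(fhb=fhb, lipemia_present=True,
                                parenteral_nutrition=True)
            return decide(rec, cfg).status

        assert status(49.999) is ReportStatus.REPORT_WITH_ANNOTATION
        assert status(50.0) is ReportStatus.CLINICIAN_REQUEST_ONLY
        assert status(10.0) is ReportStatus.REPORT_WITH_ANNOTATION
        assert status(400.0) is ReportStatus.CLINICIAN_REQUEST_ONLY

    def test_monotone_in_tbil_once_blocked_stays_blocked(self, cfg, benign_record):
        statuses = [
            decide(benign_record(hil=HILIndices(0, 5.0, 0), tbil=t, dbil=None), cfg).status
            for t in [10, 50, 74, 75, 76, 150, 300]
        ]
        blocked = [s is ReportStatus.CLINICIAN_REQUEST_ONLY for s in statuses]
        # once True, never returns to False
        assert blocked == sorted(blocked)


record_strategy = st.builds(
    SampleRecord,
    sample_id=st.just("H"),
    hil=st.builds(
        HILIndices,
        h_index=st.floats(0, 30, allow_nan=False),
        i_index=st.floats(0, 10, allow_nan=False),
        l_index=st.floats(0, 10, allow_nan=False),
    ),
    fhb=st.floats(0, 1000, allow_nan=False),
    tbil=st.one_of(st.none(), st.floats(0, 400, allow_nan=False)),
    lipemia_present=st.booleans(),
    parenteral_nutrition=st.booleans(),
    nutrition_discontinuable=st.booleans(),
    propofol_sedation=st.booleans(),
    sedation_adjustable=st.booleans(),
    venipuncture_verified=st.booleans(),
    clinician_requested=st.booleans(),
)


class TestEngineProperties:
    @given(rec=record_strategy)
    @settings(max_examples=300, deadline=None)
    def test_totality_one_status_per_valid_record(self, rec):
        d = decide(rec, ThresholdConfig())
        assert isinstance(d.status, ReportStatus)

    @given(rec=record_strategy)
    @settings(max_examples=200, deadline=None)
    def test_trace_is_ordered_and_replays_to_same_status(self, rec):
        cfg = ThresholdConfig()
        d1 = decide(rec, cfg)
        d2 = decide(rec, cfg)
        assert d1 == d2
        assert len(d1.rule_trace) >= 1
        # the final trace entry is the rule that decided a blocking status
        if d1.status not in (ReportStatus.REPORT, ReportStatus.REPORT_WITH_ANNOTATION):
            assert d1.rule_trace[-1].fired


class TestBatch:
    def test_empty_batch_rejected(self, cfg):
        with pytest.raises(ValueError, match="empty batch"):
            decide_batch([], cfg)

    def test_batch_equals_elementwise_decide(self, cfg, benign_record):
        records = [
            benign_record(sample_id=f"S{i}", fhb=float(f))
            for i, f in enumerate([10, 250, 40])
        ]
        batch = decide_batch(records, cfg)
        assert batch == [decide(r, cfg) for r in records]
        assert [d.sample_id for d in batch] == ["S0", "S1", "S2"]

    def test_batch_error_carries_sample_id(self, cfg, benign_record):
        records = [benign_record(sample_id="OK"),
                   benign_record(sample_id="BAD", fhb=None)]
        with pytest.raises(ValueError, match="BAD"):
            decide_batch(records, cfg)


class TestThresholdConfig:
    def test_rejects_nonpositive_threshold(self):
        with pytest.raises(ValueError):
            ThresholdConfig(icterus_trigger=0.0)

    def test_rejects_rel_delta_threshold_above_one(self):
        with pytest.raises(ValueError):
            ThresholdConfig(rel_delta_threshold=1.5)

    def test_is_frozen(self, cfg):
        with pytest.raises(dataclasses.FrozenInstanceError):
            cfg.h_trigger = 99.0
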