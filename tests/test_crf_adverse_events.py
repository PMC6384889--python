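"""CRF parsing/validation and the automated adverse-event feed."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trialchain.core_ledger import Chain, append_transaction
from trialchain.crf_adverse_events import (
    CRF,
    CRFValidationError,
    crfs_from_csv,
    extract_adverse_events,
    normalize_event_text,
    parse_crf,
    serialize_crf,
    validate_verification_code,
)
from trialchain.crypto_privacy import encrypt_payload
from trialchain.protocol_roles import VerificationCode
from trialchain.trial_simulator import TRIAL_START

DAY0_73491 = {
    "document_type": "crf",
    "subject_id": "73491",
    "visit_day": 0,
    "arm_code": "ARM_A",
    "labs": {"wbc": 5.9, "eosinophil_pct": 4.6, "platelets": 223},
    "adverse_events": ["muscle strain", "injection site swelling"],
    "verification_code": "AB12CD34",
}


class TestParseCRF:
    def test_day0_worked_example(self):
        crf = parse_crf(json.dumps(DAY0_73491).encode())
        assert crf.subject_id == "73491"
        assert crf.labs.wbc == 5.9
        assert crf.labs.eosinophil_pct == 4.6
        assert crf.labs.platelets == 223
        assert crf.visit_day == 0

    def test_missing_subject_id_names_the_field(self):
        document = {k: v for k, v in DAY0_73491.items() if k != "subject_id"}
        with pytest.raises(CRFValidationError) as excinfo:
            parse_crf(json.dumps(document).encode())
        assert "subject_id" in excinfo.value.fields

    def test_negative_lab_value_rejected(self):
        document = dict(DAY0_73491, labs={"wbc": -1.0})
        with pytest.raises(CRFValidationError) as excinfo:
            parse_crf(json.dumps(document).encode())
        assert any("wbc" in f for f in excinfo.value.fields)

    def test_unknown_fields_preserved_in_extras(self):
        document = dict(DAY0_73491, site_notes="tolerated dose well")
        crf = parse_crf(json.dumps(document).encode())
        assert crf.extras["site_notes"] == "tolerated dose well"
        # and they survive a serialization round trip
        assert parse_crf(serialize_crf(crf)).extras["site_notes"] == "tolerated dose well"

    @given(
        subject_id=st.text(st.characters(min_codepoint=48, max_codepoint=122), min_size=1, max_size=8),
        visit_day=st.integers(min_value=0, max_value=365),
        wbc=st.one_of(st.none(), st.floats(min_value=0, max_value=50, allow_nan=False)),
        events=st.lists(st.text(min_size=1, max_size=20), max_size=4),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_serialize_parse_round_trip(self, subject_id, visit_day, wbc, events):
        crf = CRF(
            subject_id=subject_id, visit_day=visit_day,
            labs={"wbc": wbc}, adverse_events=events,
        )
        assert parse_crf(serialize_crf(crf)) == crf


class TestCSVIngest:
    CSV = (
        "subject_id,visit_day,arm_code,age,gender,wbc,platelets,adverse_events,verification_code\n"
        '73511,0,ARM_B,42,Female,6.1,250,"chest tightness; sinus congestion",ZZ99YY88\n'
    )

    def test_row_maps_to_canonical_crf(self):
        (crf,) = crfs_from_csv(self.CSV)
        assert crf.subject_id == "73511"
        assert crf.labs.wbc == 6.1
        assert crf.demographics.age == 42
        assert crf.adverse_events == ["chest tightness", "sinus congestion"]

    def test_parse_crf_accepts_a_single_csv_row(self):
        crf = parse_crf(self.CSV.encode())
        assert crf.subject_id == "73511"

    def test_header_without_subject_id_rejected(self):
        with pytest.raises(CRFValidationError):
            crfs_from_csv("name,day\nx,0\n")


class TestVerificationCodes:
    ISSUED = [VerificationCode("73491", "AB12CD34"), VerificationCode("73511", "ZZ99YY88")]

    def test_matching_code_is_valid(self):
        crf = parse_crf(json.dumps(DAY0_73491).encode())
        assert validate_verification_code(crf, self.ISSUED).valid

    def test_empty_code_is_missing(self):
        crf = parse_crf(json.dumps(dict(DAY0_73491, verification_code="")).encode())
        check = validate_verification_code(crf, self.ISSUED)
        assert not check.valid and check.reason.startswith("missing")

    def test_another_subjects_code_is_a_mismatch(self):
        crf = parse_crf(json.dumps(dict(DAY0_73491, verification_code="ZZ99YY88")).encode())
        check = validate_verification_code(crf, self.ISSUED)
        assert not check.valid and check.reason.startswith("mismatch")

    def test_unissued_subject_is_flagged(self):
        crf = parse_crf(json.dumps(dict(DAY0_73491, subject_id="99999")).encode())
        check = validate_verification_code(crf, self.ISSUED)
        assert not check.valid and "unknown subject" in check.reason


def _crf_payload(subject_id, events, code="AB12CD34"):
    return serialize_crf(CRF(subject_id=subject_id, visit_day=0,
                             adverse_events=events, verification_code=code))


class TestAdverseEventFeed:
    def test_one_notice_per_event_per_version(self):
        chain = Chain.initialize("T", TRIAL_START)
        append_transaction(chain, "INV", "CRO", "crf_a.json",
                           _crf_payload("73491", ["muscle strain", "nasal congestion"]),
                           False, TRIAL_START)
        append_transaction(chain, "INV", "CRO", "crf_b.json",
                           _crf_payload("73511", ["chest tightness"]),
                           False, TRIAL_START)
        append_transaction(chain, "SPONSOR", "REGULATOR", "crf_a.json",
                           _crf_payload("73491", []), False, TRIAL_START)
        feed = extract_adverse_events(chain)
        # brute-force recount: sum of event-list lengths over all versions
        assert len(feed) == 3
        assert [n.event_text for n in feed] == [
            "muscle strain", "nasal congestion", "chest tightness",
        ]
        assert all(n.crf_version == 1 for n in feed)
        assert sum(1 for n in feed if n.crf_version == 2) == 0

    def test_notices_trace_to_source_blocks(self):
        chain = Chain.initialize("T", TRIAL_START)
        block = append_transaction(chain, "INV", "CRO", "crf.json",
                                   _crf_payload("73491", ["sinus headaches"]),
                                   False, TRIAL_START)
        (notice,) = extract_adverse_events(chain).notices
        assert notice.source_block_index == block.index
        assert notice.timestamp == block.timestamp

    def test_appending_never_rewrites_existing_notices(self):
        chain = Chain.initialize("T", TRIAL_START)
        append_transaction(chain, "INV", "CRO", "crf.json",
                           _crf_payload("73491", ["muscle strain"]), False, TRIAL_START)
        before = extract_adverse_events(chain).notices
        append_transaction(chain, "INV", "CRO", "crf2.json",
                           _crf_payload("73511", ["chest tightness"]), False, TRIAL_START)
        after = extract_adverse_events(chain).notices
        assert after[: len(before)] == before

    def test_non_crf_blocks_are_ignored(self):
        chain = Chain.initialize("T", TRIAL_START)
        append_transaction(chain, "S", "R", "notes.txt", b"just text", False, TRIAL_START)
        feed = extract_adverse_events(chain)
        assert len(feed) == 0 and feed.warnings == ()

    def test_encrypted_block_without_password_is_reported_unreadable(self):
        chain = Chain.initialize("T", TRIAL_START)
        plaintext = _crf_payload("73491", ["muscle strain"])
        blob = encrypt_payload(plaintext, "pw", iterations=10_000)
        append_transaction(chain, "INV", "CRO", "crf.json", blob.to_bytes(),
                           True, TRIAL_START, plaintext=plaintext)
        feed = extract_adverse_events(chain)
        assert len(feed) == 0
        assert len(feed.warnings) == 1 and "no password" in feed.warnings[0].reason
        # with the password supplied, the events surface
        feed = extract_adverse_events(chain, passwords={"crf.json": "pw"})
        assert [n.event_text for n in feed] == ["muscle strain"]

    def test_unparseable_crf_payload_is_a_warning_not_a_crash(self):
        chain = Chain.initialize("T", TRIAL_START)
        broken = json.dumps({"document_type": "crf", "visit_day": -3}).encode()
        append_transaction(chain, "INV", "CRO", "bad.json", broken, False, TRIAL_START)
        append_transaction(chain, "INV", "CRO", "good.json",
                           _crf_payload("73511", ["chest tightness"]), False, TRIAL_START)
        feed = extract_adverse_events(chain)
        assert [n.event_text for n in feed] == ["chest tightness"]
        assert len(feed.warnings) == 1


def test_event_text_normalization_for_dedup():
    assert normalize_event_text("  Muscle   Strain ") == normalize_event_text("muscle strain")
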