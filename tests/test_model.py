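"""Record model: field inventory, validation rules, canonical form."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fhrkit import (
    ChecksumValue,
    FhrRecord,
    ValidationError,
    canonicalize,
    generate_record,
    list_optional_fields,
    list_required_fields,
    load_schema,
    validate_record,
)
from fhrkit.model import OPTIONAL_FIELDS, REQUIRED_FIELDS


class TestFieldInventory:
    def test_required_fields_in_specification_order(self):
        fields = list_required_fields()
        assert fields[0] == "schema"
        assert fields[-1] == "checksum"
        assert len(fields) == 9
        assert len(set(fields)) == 9

    def test_optional_fields(self):
        fields = list_optional_fields()
        assert len(fields) == 11
        assert "voucherSpecimen" in fields

    def test_required_and_optional_disjoint_and_cover_twenty(self):
        req, opt = set(list_required_fields()), set(list_optional_fields())
        assert not req & opt
        assert len(req | opt) == 20

    def test_vendored_schema_mirrors_field_lists(self):
        schema = load_schema()
        assert set(schema["required"]) == set(REQUIRED_FIELDS)
        assert set(schema["properties"]) == set(REQUIRED_FIELDS) | set(OPTIONAL_FIELDS)


class TestValidateRecord:
    def test_worked_example_is_valid(self, worked_example_record):
        report = validate_record(worked_example_record)
        assert report.valid
        assert report.errors == []

    def test_missing_checksum_fails_strict_but_not_pre_injection(self, worked_example_record):
        rec = FhrRecord(worked_example_record)
        del rec["checksum"]
        strict = validate_record(rec, mode="strict")
        assert not strict.valid
        assert [i.path for i in strict.errors] == ["/checksum"]
        assert validate_record(rec, mode="pre_injection").valid

    @pytest.mark.parametrize("field", REQUIRED_FIELDS)
    def test_each_missing_required_field_yields_one_error(self, worked_example_record, field):
        rec = FhrRecord(worked_example_record)
        del rec[field]
        report = validate_record(rec)
        assert not report.valid
        assert len(report.errors) == 1
        assert report.errors[0].path == f"/{field}"
        assert report.errors[0].code == "missing_required"

    def test_taxon_uri_must_be_a_registry_host(self, worked_example_record):
        rec = FhrRecord(worked_example_record)
        rec["taxon"] = dict(rec["taxon"], uri="https://example.com/taxonomy:0000")
        report = validate_record(rec)
        assert not report.valid
        assert report.errors[0].path == "/taxon/uri"
        assert report.errors[0].code == "bad_taxon_host"

    def test_bioregistry_host_accepted(self, worked_example_record):
        rec = FhrRecord(worked_example_record)
        rec["taxon"] = dict(rec["taxon"], uri="https://bioregistry.io/taxonomy:0000")
        assert validate_record(rec).valid

    def test_non_iso_date_rejected(self, worked_example_record):
        rec = FhrRecord(worked_example_record, dateCreated="21-03-2022")
        report = validate_record(rec)
        assert [i.code for i in report.errors] == ["bad_date"]
        assert report.errors[0].path == "/dateCreated"

    def test_impossible_calendar_date_rejected(self, worked_example_record):
        rec = FhrRecord(worked_example_record, dateCreated="2022-02-30")
        assert not validate_record(rec).valid

    def test_en_dash_date_warns_but_validates(self, worked_example_record):
        rec = FhrRecord(worked_example_record, dateCreated="2022–03-21")
        report = validate_record(rec)
        assert report.valid
        assert any(i.code == "nonascii_date_dash" for i in report.warnings)

    def test_unknown_keys_warn_without_failing(self, worked_example_record):
        rec = FhrRecord(worked_example_record, favouriteColour="teal")
        report = validate_record(rec)
        assert report.valid
        warning = [i for i in report.issues if i.path == "/favouriteColour"]
        assert len(warning) == 1 and warning[0].severity == "warning"

    def test_scalar_author_accepted_as_singleton(self, worked_example_record):
        rec = FhrRecord(worked_example_record)
        rec["metadataAuthor"] = {"name": "Solo Author"}
        assert validate_record(rec).valid

    def test_string_schema_version_accepted(self, worked_example_record):
        rec = FhrRecord(worked_example_record, schemaVersion="1")
        assert validate_record(rec).valid
        assert canonicalize(rec)["schemaVersion"] == 1

    @pytest.mark.parametrize(
        "value,code",
        [
            ("md5:zz", "bad_checksum_format"),
            ("md5:abcd", "bad_checksum_format"),  # wrong digest length
            ("crc32:deadbeef", "unsupported_algorithm"),
            ("nodigest", "bad_checksum_format"),
        ],
    )
    def test_malformed_checksums_rejected(self, worked_example_record, value, code):
        rec = FhrRecord(worked_example_record, checksum=value)
        report = validate_record(rec)
        assert not report.valid
        assert report.errors[0].code == code

    def test_bad_curie_identifier_rejected(self, worked_example_record):
        rec = FhrRecord(worked_example_record, identifier=["no curie here"])
        report = validate_record(rec)
        assert report.errors[0].path == "/identifier/0"

    def test_problems_reported_never_raised(self):
        # a thoroughly broken record still produces a report
        report = validate_record(FhrRecord({"taxon": 42, "dateCreated": [1]}))
        assert not report.valid
        assert len(report.errors) >= 2


class TestChecksumValue:
    def test_wire_format_round_trip(self):
        cv = ChecksumValue.parse("MD5:A3D5D9146C3992B7ED6724409BA28AA9")
        assert cv.algorithm == "md5"
        assert str(cv) == "md5:a3d5d9146c3992b7ed6724409ba28aa9"

    def test_rejects_non_hex(self):
        with pytest.raises(ValueError):
            ChecksumValue.parse("md5:not-hex!")


class TestCanonicalize:
    def test_singleton_author_promoted_to_list(self, worked_example_record):
        rec = FhrRecord(worked_example_record)
        rec["assemblyAuthor"] = {"name": "Jane Doe"}
        out = canonicalize(rec)
        assert out["assemblyAuthor"] == [{"name": "Jane Doe"}]

    def test_idempotent(self, worked_example_record):
        once = canonicalize(worked_example_record)
        assert canonicalize(once) == once

    def test_field_order_required_then_optional_alphabetical(self):
        rec = generate_record(11, "full")
        keys = list(canonicalize(rec).keys())
        assert keys[:9] == list(REQUIRED_FIELDS)
        assert keys[9:] == sorted(OPTIONAL_FIELDS)

    def test_raises_on_invalid_record(self, worked_example_record):
        rec = FhrRecord(worked_example_record, dateCreated="not a date")
        with pytest.raises(ValidationError):
            canonicalize(rec)

    def test_whitespace_and_case_normalization(self, worked_example_record):
        rec = FhrRecord(worked_example_record)
        rec["genome"] = "  Example species  "
        rec["checksum"] = "MD5:A3D5D9146C3992B7ED6724409BA28AA9"
        out = canonicalize(rec)
        assert out["genome"] == "Example species"
        assert out["checksum"] == "md5:a3d5d9146c3992b7ed6724409ba28aa9"

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10**6), shuffle_seed=st.integers(0, 10**6))
    def test_canonical_form_is_key_order_insensitive(self, seed, shuffle_seed):
        rec = generate_record(seed, "full")
        keys = list(rec)
        random.Random(shuffle_seed).shuffle(keys)
        shuffled = FhrRecord({k: rec[k] for k in keys})
        assert list(canonicalize(shuffled).items()) == list(canonicalize(rec).items())
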