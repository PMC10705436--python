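"""Self-referential checksum: payload canonicalization, inject, verify."""

import hashlib
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fhrkit import (
    MissingChecksum,
    MissingHeader,
    UnsupportedAlgorithm,
    canonical_payload,
    compute_checksum,
    embed_header,
    extract_header,
    generate_fasta,
    generate_record,
    inject_checksum,
    parse_fasta,
    validate_record,
    verify_checksum,
)


def _embedded(seed: int, **kwargs):
    record = generate_record(seed)
    record.pop("checksum")
    return embed_header(record, generate_fasta(seed + 1, **kwargs))


class TestCanonicalPayload:
    def test_crlf_and_lf_twins_share_a_payload(self):
        assert canonical_payload(_embedded(1, newline_style="CRLF")) == canonical_payload(
            _embedded(1, newline_style="LF")
        )

    def test_checksum_line_excluded_from_payload(self):
        doc = _embedded(2)
        injected = inject_checksum(doc)
        assert canonical_payload(injected) == canonical_payload(doc)

    def test_payload_matches_hand_constructed_oracle(self):
        """Independent oracle: the canonical payload of a minimal header over
        '>s\\nACGT\\n' is written out by hand here and digested with hashlib
        directly, bypassing the package's payload construction."""
        header = (
            ";~schema: https://example.org/schema.json\n"
            ";~schemaVersion: 1\n"
            ";~genome: toy\n"
            ";~taxon:\n"
            ";~  name: Toy species\n"
            ";~  uri: https://identifiers.org/taxonomy:1\n"
            ";~version: '1.0'\n"
            ";~assemblyAuthor:\n"
            ";~- name: A\n"
            ";~metadataAuthor:\n"
            ";~- name: B\n"
            ";~dateCreated: '2022-03-21'\n"
        )
        expected_payload = (header + ">s\nACGT\n").encode()
        doc = parse_fasta(expected_payload)
        assert canonical_payload(doc) == expected_payload
        oracle = hashlib.md5(expected_payload).hexdigest()
        assert compute_checksum(doc).digest == oracle
        # frozen value so a silent payload change cannot pass unnoticed
        assert oracle == "bf734037024f20a761d1cb9ba5fbbe73"

    def test_header_key_order_does_not_change_payload(self):
        record = generate_record(5)
        fasta = generate_fasta(6)
        shuffled_keys = list(record)
        random.Random(0).shuffle(shuffled_keys)
        shuffled = {k: record[k] for k in shuffled_keys}
        assert canonical_payload(embed_header(record, fasta)) == canonical_payload(
            embed_header(shuffled, fasta)
        )


class TestComputeChecksum:
    def test_one_base_difference_changes_digest(self):
        a = _embedded(4)
        mutated = a.copy()
        last_text, last_term = mutated.lines[-1]
        flipped = ("A" if last_text[-1] != "A" else "C")
        mutated.lines[-1] = (last_text[:-1] + flipped, last_term)
        assert compute_checksum(a).digest != compute_checksum(mutated).digest

    @pytest.mark.parametrize("algorithm,length", [("md5", 32), ("sha1", 40), ("sha256", 64)])
    def test_supported_algorithms(self, algorithm, length):
        doc = _embedded(3)
        value = compute_checksum(doc, algorithm)
        assert value.algorithm == algorithm
        assert len(value.digest) == length

    def test_unsupported_algorithm_refused(self):
        with pytest.raises(UnsupportedAlgorithm):
            compute_checksum(_embedded(3), "crc32")

    def test_sidecar_record_and_embedded_header_share_checksum(self):
        """The digest identifies genome + metadata regardless of whether the
        record travels embedded or as a sidecar."""
        record = generate_record(7)
        record.pop("checksum")
        fasta = generate_fasta(8)
        embedded_digest = compute_checksum(embed_header(record, fasta))
        sidecar_digest = compute_checksum(fasta, record=record)
        assert embedded_digest == sidecar_digest


class TestInjectVerify:
    def test_inject_completes_the_record(self):
        injected = inject_checksum(_embedded(10))
        record = extract_header(injected)
        assert validate_record(record, mode="strict").valid
        ok, report = verify_checksum(injected)
        assert ok and report.valid

    def test_inject_is_idempotent(self):
        once = inject_checksum(_embedded(11))
        assert inject_checksum(once).to_bytes() == once.to_bytes()

    def test_editing_a_base_changes_the_injected_value(self):
        doc = _embedded(12)
        first = extract_header(inject_checksum(doc))["checksum"]
        mutated = parse_fasta(doc.to_bytes().replace(b">seq1", b">seq1x"))
        second = extract_header(inject_checksum(mutated))["checksum"]
        assert first != second

    def test_inject_without_header_refused(self):
        with pytest.raises(MissingHeader):
            inject_checksum(parse_fasta(b">s\nACGT\n"))

    def test_verify_flags_sequence_mutation(self):
        injected = inject_checksum(_embedded(13))
        text = injected.to_text()
        # flip one sequence base on the last line
        mutated = text[:-2] + ("A" if text[-2] != "A" else "C") + text[-1]
        ok, report = verify_checksum(parse_fasta(mutated.encode()))
        assert not ok
        assert report.errors[0].code == "checksum_mismatch"
        assert "mismatch" in report.errors[0].message

    def test_crlf_reserialization_keeps_checksum_valid(self):
        """The named brittleness case: opening a Unix file in a Windows
        editor flips LF to CRLF without changing the semantics; the FHR
        checksum survives it."""
        injected = inject_checksum(_embedded(14, newline_style="LF"))
        crlf = injected.to_text().replace("\n", "\r\n").encode()
        ok, _ = verify_checksum(parse_fasta(crlf))
        assert ok

    def test_verify_without_checksum_field_raises(self):
        with pytest.raises(MissingChecksum):
            verify_checksum(_embedded(15))

    def test_strict_bytes_mode_round_trip_and_sensitivity(self):
        doc = _embedded(16)
        injected = inject_checksum(doc, strict_bytes=True)
        ok, _ = verify_checksum(injected, strict_bytes=True)
        assert ok
        # in strict mode even a newline-style change invalidates
        crlf = injected.to_text().replace("\n", "\r\n").encode()
        ok, _ = verify_checksum(parse_fasta(crlf), strict_bytes=True)
        assert not ok


@settings(max_examples=60, deadline=None)
@given(seed=st.integers(0, 10**6))
def test_verify_after_inject_always_true(seed):
    injected = inject_checksum(_embedded(seed))
    ok, report = verify_checksum(injected)
    assert ok and report.valid


@settings(max_examples=60, deadline=None)
@given(seed=st.integers(0, 10**6), data=st.data())
def test_any_single_base_mutation_is_detected(seed, data):
    injected = inject_checksum(_embedded(seed))
    text = injected.to_text()
    # choose a random position inside a sequence line and flip the base
    seq_line_indices = [
        i for i, (t, _) in enumerate(injected.lines)
        if t and not t.startswith((";", ">"))
    ]
    line_idx = data.draw(st.sampled_from(seq_line_indices))
    line, term = injected.lines[line_idx]
    pos = data.draw(st.integers(0, len(line) - 1))
    replacement = {"A": "C", "C": "G", "G": "T", "T": "A"}[line[pos]]
    mutated = injected.copy()
    mutated.lines[line_idx] = (line[: pos] + replacement + line[pos + 1:], term)
    ok, _ = verify_checksum(mutated)
    assert not ok
    assert mutated.to_text() != text
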