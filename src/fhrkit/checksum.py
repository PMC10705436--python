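"""Self-referential FHR checksum: compute, inject, verify.

The checksum identifies the reference genome *together with* its metadata:
it is computed over the whole file minus the checksum field itself, then
written into that field.  Downstream pipelines can then cite one token that
pins both sequence and provenance.

Two payload conventions are offered:

* **canonical** (default): the header is re-serialized in canonical field
  order, the checksum line dropped, and newlines normalized to LF with a
  guaranteed trailing LF.  Semantically-neutral edits — CRLF churn from
  Windows text editors, header key re-ordering — do not change the digest.
* **strict bytes** (``strict_bytes=True``): the digest covers the file's
  raw bytes with only the ``;~checksum:`` line removed; any byte-level
  change invalidates it.
"""

from __future__ import annotations

import hashlib

from .exceptions import (
    MissingChecksum,
    MissingHeader,
    UnsupportedAlgorithm,
    ValidationError,
)
from .fasta import FHR_PREFIX, FastaDocument, embed_header, extract_header, strip_header
from .model import (
    ChecksumValue,
    DIGEST_LENGTHS,
    FhrRecord,
    ValidationIssue,
    ValidationReport,
    canonicalize,
    validate_record,
)

__all__ = [
    "canonical_payload",
    "compute_checksum",
    "inject_checksum",
    "verify_checksum",
]

_CHECKSUM_LINE_PREFIX = FHR_PREFIX + "checksum:"


def _without_checksum(record: dict) -> FhrRecord:
    out = FhrRecord(record)
    out.pop("checksum", None)
    return out


def _staged(doc: FastaDocument, record: dict | None) -> FastaDocument:
    """Document with a canonical checksum-free header in front of the
    stripped body (or just the body when no record is available)."""
    body = strip_header(doc)
    if record is None:
        return body
    return embed_header(_without_checksum(canonicalize(record)), body)


def canonical_payload(doc: FastaDocument, record: dict | None = None) -> bytes:
    """Canonical byte stream the digest is computed over.

    The header (from *doc*, or the explicit sidecar *record* if given) is
    serialized in canonical order without its checksum line; newlines are
    normalized to LF and a trailing LF is guaranteed.  A header-less
    document yields just its normalized body — so embedded and sidecar
    forms of the same genome produce identical payloads, hence identical
    checksums.
    """
    if record is None and doc.fhr_lines:
        record = extract_header(doc)
    staged = _staged(doc, record)
    texts = [text for text, _ in staged.lines]
    if texts and texts[-1] == "" and staged.lines[-1][1] == "":
        texts = texts[:-1]  # splitlines never yields this, but be safe
    return ("\n".join(texts) + "\n").encode("utf-8")


def _strict_payload(doc: FastaDocument) -> bytes:
    kept = [(t, term) for t, term in doc.lines if not t.startswith(_CHECKSUM_LINE_PREFIX)]
    return "".join(t + term for t, term in kept).encode("utf-8")


def _digest(payload: bytes, algorithm: str) -> ChecksumValue:
    if algorithm not in DIGEST_LENGTHS:
        raise UnsupportedAlgorithm(
            f"unsupported checksum algorithm {algorithm!r} (md5, sha1, sha256)"
        )
    h = hashlib.new(algorithm, payload)
    return ChecksumValue(algorithm=algorithm, digest=h.hexdigest())


def compute_checksum(
    doc: FastaDocument,
    algorithm: str = "md5",
    *,
    record: dict | None = None,
    strict_bytes: bool = False,
) -> ChecksumValue:
    """Digest of the document's checksum-free payload.

    ``record`` supplies the header for the sidecar workflow (a plain FASTA
    plus an external metadata record); it defaults to the header embedded
    in *doc*, if any.
    """
    if strict_bytes:
        return _digest(_strict_payload(doc), algorithm)
    return _digest(canonical_payload(doc, record=record), algorithm)


def inject_checksum(
    doc: FastaDocument,
    algorithm: str = "md5",
    *,
    strict_bytes: bool = False,
) -> FastaDocument:
    """Compute the checksum and write it into the embedded header.

    The header is rewritten in canonical form (any prior checksum line is
    replaced), so injection is idempotent: injecting twice yields
    byte-identical output.

    Raises
    ------
    MissingHeader
        When *doc* carries no FHR header.
    ValidationError
        When the header fails pre-injection validation.
    """
    record = extract_header(doc)  # MissingHeader propagates
    report = validate_record(record, mode="pre_injection")
    if not report.valid:
        raise ValidationError(
            "refusing to inject a checksum into an invalid header: "
            + "; ".join(str(i) for i in report.errors),
            report=report,
        )
    staged = _staged(doc, record)
    if strict_bytes:
        value = _digest(_strict_payload(staged), algorithm)
    else:
        value = _digest(canonical_payload(staged), algorithm)
    final = canonicalize(record)
    final["checksum"] = str(value)
    return embed_header(final, strip_header(doc))


def verify_checksum(
    doc: FastaDocument,
    *,
    strict_bytes: bool = False,
) -> tuple[bool, ValidationReport]:
    """Recompute the digest and compare it with the stored one.

    Returns ``(ok, report)``; on mismatch the report carries a
    ``checksum_mismatch`` error at ``/checksum``.

    Raises
    ------
    MissingHeader
        When no header is present.
    MissingChecksum
        When the header has no checksum field.
    """
    record = extract_header(doc)
    stored_raw = record.get("checksum")
    if stored_raw is None:
        raise MissingChecksum("header carries no checksum field to verify")
    issues: list[ValidationIssue] = []
    try:
        stored = ChecksumValue.parse(str(stored_raw))
    except ValueError as exc:
        issues.append(
            ValidationIssue("/checksum", "error", str(exc), "bad_checksum_format")
        )
        return False, ValidationReport(issues)
    expected = compute_checksum(doc, stored.algorithm, strict_bytes=strict_bytes)
    if expected.digest != stored.digest:
        issues.append(
            ValidationIssue(
                "/checksum",
                "error",
                f"header/data mismatch: stored {stored}, recomputed {expected}",
                "checksum_mismatch",
            )
        )
        return False, ValidationReport(issues)
    return True, ValidationReport(issues)
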