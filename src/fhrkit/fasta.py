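"""Byte-faithful FASTA codec for embedded FHR headers.

The original 1985 Pearson FASTA format permits comment lines beginning with
``;`` at the top of the file.  FHR piggybacks on that legacy feature: the
metadata record is serialized as YAML and every line is prefixed with
``;~``, distinguishing FHR content from plain semicolon comments.  Sequence
records (``>`` header plus sequence lines) are never touched.

The parser is byte-faithful: each line is stored together with its own
terminator, so serializing an unmodified :class:`FastaDocument` reproduces
the input bytes exactly — including CRLF files and files without a trailing
newline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import _yamlio
from .exceptions import (
    DecodeError,
    EmptyInput,
    HeaderParseError,
    MissingHeader,
    ReplaceRefused,
)
from .model import FhrRecord, canonicalize

logger = logging.getLogger(__name__)

FHR_PREFIX = ";~"

__all__ = [
    "FastaDocument",
    "parse_fasta",
    "extract_header",
    "embed_header",
    "strip_header",
]


def _is_fhr_line(text: str) -> bool:
    return text.startswith(FHR_PREFIX)


def _is_comment_line(text: str) -> bool:
    return text.startswith(";") and not text.startswith(FHR_PREFIX)


@dataclass
class FastaDocument:
    """A FASTA file as an ordered list of ``(text, terminator)`` lines.

    ``terminator`` is ``"\\n"``, ``"\\r\\n"`` or ``""`` (final line without a
    newline).  All views (``preamble``, ``fhr_lines``, ``records``...) are
    computed from the line list, which remains the single source of truth.
    """

    lines: list[tuple[str, str]] = field(default_factory=list)

    # -- serialization ----------------------------------------------------
    def to_text(self) -> str:
        return "".join(text + term for text, term in self.lines)

    def to_bytes(self) -> bytes:
        return self.to_text().encode("utf-8")

    # -- detected properties ---------------------------------------------
    @property
    def newline_style(self) -> str:
        """``"CRLF"`` if the first terminated line ends in CRLF, else ``"LF"``."""
        for _, term in self.lines:
            if term:
                return "CRLF" if term == "\r\n" else "LF"
        return "LF"

    @property
    def _newline(self) -> str:
        return "\r\n" if self.newline_style == "CRLF" else "\n"

    def _first_record_index(self) -> int:
        for i, (text, _) in enumerate(self.lines):
            if text.startswith(">"):
                return i
        return len(self.lines)

    @property
    def preamble(self) -> list[str]:
        """Comment/blank lines appearing before the first ``>`` header."""
        return [text for text, _ in self.lines[: self._first_record_index()]]

    @property
    def fhr_lines(self) -> list[str]:
        """FHR (';~') lines of the preamble."""
        return [t for t in self.preamble if _is_fhr_line(t)]

    @property
    def plain_comments(self) -> list[str]:
        """Plain ';' comment lines of the preamble."""
        return [t for t in self.preamble if _is_comment_line(t)]

    @property
    def misplaced_fhr_lines(self) -> list[str]:
        """';~' lines occurring after the first sequence record."""
        start = self._first_record_index()
        return [text for text, _ in self.lines[start:] if _is_fhr_line(text)]

    @property
    def records(self) -> list[tuple[str, str]]:
        """``(header_line, concatenated_sequence)`` pairs, in file order.

        Comment lines interleaved among sequence lines are excluded from the
        concatenated sequence but preserved in ``lines``.
        """
        out: list[tuple[str, str]] = []
        header: str | None = None
        seq: list[str] = []
        for text, _ in self.lines:
            if text.startswith(">"):
                if header is not None:
                    out.append((header, "".join(seq)))
                header, seq = text, []
            elif header is not None and not text.startswith(";"):
                seq.append(text.strip())
        if header is not None:
            out.append((header, "".join(seq)))
        return out

    def copy(self) -> "FastaDocument":
        return FastaDocument(lines=list(self.lines))


def parse_fasta(data: bytes) -> FastaDocument:
    """Parse FASTA bytes into a byte-faithful :class:`FastaDocument`.

    Raises
    ------
    DecodeError
        If the bytes are not valid UTF-8.
    EmptyInput
        On zero-byte input.
    """
    if isinstance(data, str):
        data = data.encode("utf-8")
    if not data:
        raise EmptyInput("cannot parse an empty FASTA file")
    try:
        text = data.decode("utf-8")
    except UnicodeDecodeError as exc:
        raise DecodeError(f"FASTA input is not valid UTF-8: {exc}") from exc

    lines: list[tuple[str, str]] = []
    for raw in text.splitlines(keepends=True):
        if raw.endswith("\r\n"):
            lines.append((raw[:-2], "\r\n"))
        elif raw.endswith("\n"):
            lines.append((raw[:-1], "\n"))
        elif raw.endswith("\r"):
            lines.append((raw[:-1], "\r"))
        else:
            lines.append((raw, ""))
    return FastaDocument(lines=lines)


def extract_header(doc: FastaDocument) -> FhrRecord:
    """Recover the FHR record from a document's ';~' preamble lines.

    The ';~' prefix (plus at most one following space) is stripped from each
    line and the joined text parsed as a YAML mapping.  The record is
    returned as parsed — un-canonicalized and un-validated.

    Raises
    ------
    MissingHeader
        When the preamble holds no ';~' lines.
    HeaderParseError
        When the joined text is not a valid mapping.
    """
    if doc.misplaced_fhr_lines:
        logger.warning(
            "ignoring %d ';~' line(s) found after the first sequence record",
            len(doc.misplaced_fhr_lines),
        )
    raw = doc.fhr_lines
    if not raw:
        raise MissingHeader("document has no FHR (';~') header lines")
    stripped = []
    for line in raw:
        body = line[len(FHR_PREFIX):]
        if body.startswith(" ") and not body.startswith("  "):
            body = body[1:]
        stripped.append(body)
    data = _yamlio.load_mapping("\n".join(stripped) + "\n")
    return FhrRecord(data)


def header_lines_for(record: dict, newline: str = "\n") -> list[tuple[str, str]]:
    """Canonical ';~'-prefixed header lines for *record* (terminator attached)."""
    text = _yamlio.dump_mapping(dict(canonicalize(record)))
    return [(FHR_PREFIX + line, newline) for line in text.splitlines()]


def embed_header(record: dict, doc: FastaDocument, overwrite: bool = False) -> FastaDocument:
    """Place the canonical serialization of *record* at the top of *doc*.

    Existing plain comments and sequence records are byte-preserved and
    follow the new ';~' block.  A record missing its checksum (pre-injection
    state) is accepted; other validation errors raise.

    Raises
    ------
    ReplaceRefused
        When *doc* already carries an FHR header and ``overwrite`` is false.
    ValidationError
        When the record has error-severity issues.
    """
    if doc.fhr_lines or doc.misplaced_fhr_lines:
        if not overwrite:
            raise ReplaceRefused(
                "document already has an FHR header; pass overwrite=True to replace it"
            )
        doc = strip_header(doc)
    new = doc.copy()
    new.lines = header_lines_for(record, new._newline) + new.lines
    return new


def strip_header(doc: FastaDocument) -> FastaDocument:
    """Remove every ';~' line, leaving all other bytes untouched.

    Stripping a header-less document is the identity.  ';~' lines found
    after the first sequence record (a misplaced header, e.g. after files
    were concatenated) are also removed, with a warning.
    """
    misplaced = doc.misplaced_fhr_lines
    if misplaced:
        logger.warning(
            "removing %d misplaced ';~' line(s) found after the first sequence record",
            len(misplaced),
        )
    return FastaDocument(lines=[(t, term) for t, term in doc.lines if not _is_fhr_line(t)])
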