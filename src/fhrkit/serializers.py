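"""Sidecar serializers: YAML, JSON and Microdata-HTML, plus format dispatch.

When the metadata cannot live inside the FASTA file itself (some FASTA
consumers choke on semicolon comments), the record travels as a sidecar
file named ``<genome file name>.fhr.<yaml|json|html>`` in the same
directory.  YAML is the human-and-machine form, JSON the interchange form,
and Microdata-embedded HTML exposes the metadata to web search engines
without exposing the sequence.

All writers emit the canonical field order, so writing the same record
twice yields byte-identical files, and every format round-trips to the same
canonical record.
"""

from __future__ import annotations

import html as _html
import json
import logging
import os
import tempfile
from pathlib import Path

from lxml import html as lxml_html

from . import _yamlio
from .exceptions import (
    HeaderParseError,
    MicrodataError,
    MissingHeader,
    RefusedConversion,
    UnsupportedFormat,
)
from .fasta import extract_header, parse_fasta
from .model import (
    AGENT_LIST_FIELDS,
    MULTI_VALUED,
    FhrRecord,
    canonicalize,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SerializationFormat",
    "FORMATS",
    "detect_format",
    "read_record",
    "write_record",
    "convert",
    "to_yaml_text",
    "to_json_text",
    "to_html_text",
    "from_yaml_text",
    "from_json_text",
    "from_html_text",
]


class SerializationFormat:
    """A format token plus the filename suffixes that select it."""

    def __init__(self, token: str, extension_patterns: tuple[str, ...]):
        self.token = token
        self.extension_patterns = extension_patterns

    def __repr__(self) -> str:  # pragma: no cover
        return f"SerializationFormat({self.token!r})"

    def __eq__(self, other) -> bool:
        if isinstance(other, str):
            return self.token == other
        return isinstance(other, SerializationFormat) and self.token == other.token

    def __hash__(self) -> int:
        return hash(self.token)


FORMATS: dict[str, SerializationFormat] = {
    "yaml": SerializationFormat("yaml", (".fhr.yaml", ".fhr.yml", ".yaml", ".yml")),
    "json": SerializationFormat("json", (".fhr.json", ".json")),
    "html": SerializationFormat("html", (".fhr.html", ".fhr.htm", ".html", ".htm")),
    "fasta": SerializationFormat("fasta", (".fhr.fasta", ".fhr.fa", ".fasta", ".fa", ".fna")),
}

# Longest suffix wins, so "x.fhr.yaml" is yaml, never mistaken for anything else.
_SUFFIX_TABLE: list[tuple[str, str]] = sorted(
    ((pat, fmt.token) for fmt in FORMATS.values() for pat in fmt.extension_patterns),
    key=lambda item: len(item[0]),
    reverse=True,
)


def detect_format(path: str | os.PathLike) -> SerializationFormat:
    """Map a filename to its serialization format by longest-suffix match.

    Raises :class:`UnsupportedFormat` for unrecognized suffixes.
    """
    name = Path(path).name.lower()
    if not name:
        raise UnsupportedFormat("empty path has no recognizable format")
    for suffix, token in _SUFFIX_TABLE:
        if name.endswith(suffix):
            return FORMATS[token]
    raise UnsupportedFormat(
        f"unrecognized file suffix on {Path(path).name!r}; "
        "expected .fasta/.fa or .fhr.<yaml|json|html>"
    )


# ---------------------------------------------------------------------------
# text-level codecs


def to_yaml_text(record: dict) -> str:
    """Canonical YAML serialization (block style, canonical field order)."""
    return _yamlio.dump_mapping(dict(canonicalize(record)))


def from_yaml_text(text: str) -> FhrRecord:
    return FhrRecord(_yamlio.load_mapping(text))


def to_json_text(record: dict) -> str:
    return json.dumps(dict(canonicalize(record)), indent=2, ensure_ascii=False) + "\n"


def from_json_text(text: str) -> FhrRecord:
    if not text.strip():
        raise HeaderParseError("empty JSON document")
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise HeaderParseError(f"not well-formed JSON: {exc}") from exc
    if not isinstance(data, dict):
        raise HeaderParseError("JSON document must be an object of field names to values")
    return FhrRecord(data)


# -- Microdata-HTML ---------------------------------------------------------
# One item whose itemtype is the record's schema URI; one itemprop per
# field; name/uri pairs (taxon, authors, accessionID) become nested items.

_PAIR_FIELDS = ("taxon", "accessionID") + AGENT_LIST_FIELDS


def _esc(value: str) -> str:
    return _html.escape(str(value), quote=True)


def _prop_html(name: str, value, indent: str) -> list[str]:
    if isinstance(value, dict):
        lines = [f'{indent}<div itemprop="{_esc(name)}" itemscope>']
        for sub, sval in value.items():
            if sub == "uri":
                lines.append(
                    f'{indent}  <a itemprop="uri" href="{_esc(sval)}">{_esc(sval)}</a>'
                )
            else:
                lines.append(f'{indent}  <span itemprop="{_esc(sub)}">{_esc(sval)}</span>')
        lines.append(f"{indent}</div>")
        return lines
    return [f'{indent}<span itemprop="{_esc(name)}">{_esc(value)}</span>']


def to_html_text(record: dict) -> str:
    """Minimal Microdata-HTML document exposing the record to web crawlers."""
    rec = canonicalize(record)
    schema_uri = rec.get("schema", "")
    genome = rec.get("genome", "genome")
    lines = [
        "<!DOCTYPE html>",
        "<html>",
        "<head>",
        '  <meta charset="utf-8">',
        f"  <title>{_esc(genome)} reference genome metadata</title>",
        "</head>",
        "<body>",
        f'  <div itemscope itemtype="{_esc(schema_uri)}">',
    ]
    for name, value in rec.items():
        if isinstance(value, list):
            for item in value:
                lines.extend(_prop_html(name, item, "    "))
        else:
            lines.extend(_prop_html(name, value, "    "))
    lines += ["  </div>", "</body>", "</html>", ""]
    return "\n".join(lines)


def _microdata_value(element):
    if element.tag in ("a", "link") and element.get("href") is not None:
        return element.get("href")
    return element.text_content().strip()


def _microdata_item(element) -> dict:
    out: dict = {}
    # walk itemprops, skipping subtrees of nested itemscopes
    stack = list(element)
    while stack:
        node = stack.pop(0)
        prop = node.get("itemprop")
        if prop is not None:
            if node.get("itemscope") is not None:
                value = _microdata_item(node)
            else:
                value = _microdata_value(node)
            if prop in out:
                if not isinstance(out[prop], list):
                    out[prop] = [out[prop]]
                out[prop].append(value)
            else:
                out[prop] = value
        if node.get("itemscope") is None:
            stack = list(node) + stack
    return out


def from_html_text(text: str) -> FhrRecord:
    if not text.strip():
        raise MicrodataError("empty HTML document")
    try:
        tree = lxml_html.fromstring(text)
    except Exception as exc:  # lxml raises several parser error types
        raise MicrodataError(f"not parseable HTML: {exc}") from exc
    items = tree.xpath("//*[@itemscope and @itemtype]")
    if not items:
        raise MicrodataError("HTML document contains no Microdata FHR item")
    raw = _microdata_item(items[0])
    data: dict = {}
    for name, value in raw.items():
        if name in MULTI_VALUED and not isinstance(value, list):
            value = [value]
        if name == "schemaVersion" and isinstance(value, str) and value.strip().isdigit():
            value = int(value.strip())
        data[name] = value
    return FhrRecord(data)


# ---------------------------------------------------------------------------
# file-level interface

_TEXT_CODECS = {
    "yaml": (to_yaml_text, from_yaml_text),
    "json": (to_json_text, from_json_text),
    "html": (to_html_text, from_html_text),
}


def read_record(path: str | os.PathLike, format: str | SerializationFormat | None = None) -> FhrRecord:
    """Read an FHR record from a sidecar file or an FHR-embedded FASTA.

    The record is returned as parsed — canonicalize it for comparisons.
    """
    path = Path(path)
    fmt = detect_format(path) if format is None else FORMATS[str(getattr(format, "token", format))]
    if fmt.token == "fasta":
        return extract_header(parse_fasta(path.read_bytes()))
    text = path.read_text(encoding="utf-8")
    _, reader = _TEXT_CODECS[fmt.token]
    return reader(text)


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=str(path.parent or "."), prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        try:
            os.unlink(tmp)
        except OSError:
            pass
        raise


def _warn_unpaired_sidecar(path: Path) -> None:
    name = path.name.lower()
    for ext in (".fhr.yaml", ".fhr.yml", ".fhr.json", ".fhr.html"):
        if name.endswith(ext):
            base = path.name[: -len(ext)]
            for fasta_ext in (".fasta", ".fa", ".fna", ".fhr.fasta"):
                if (path.parent / (base + fasta_ext)).exists() or (path.parent / base).exists():
                    return
            logger.warning(
                "sidecar %s has no adjacent FASTA named %s.<fasta|fa|fna>",
                path.name,
                base,
            )
            return


def write_record(record: dict, path: str | os.PathLike, format: str | SerializationFormat | None = None) -> None:
    """Write *record* (canonicalized) to *path* in the given/detected format.

    Writing is atomic (temp file + rename), so no partial sidecar is ever
    left behind on failure.  Writing the ``fasta`` format is refused: that
    operation needs sequence data — combine with the companion FASTA.
    """
    path = Path(path)
    fmt = detect_format(path) if format is None else FORMATS[str(getattr(format, "token", format))]
    if fmt.token == "fasta":
        raise RefusedConversion(
            "cannot write metadata alone as FASTA; use fhr-fasta-combine with the companion FASTA"
        )
    writer, _ = _TEXT_CODECS[fmt.token]
    try:
        _atomic_write(path, writer(record))
    except OSError as exc:
        raise OSError(f"failed writing {path}: {exc}") from exc
    _warn_unpaired_sidecar(path)


def convert(in_path: str | os.PathLike, out_path: str | os.PathLike) -> None:
    """Convert between serializations, formats inferred from the suffixes.

    FASTA input has its embedded header extracted (:class:`MissingHeader`
    if there is none); FASTA *output* is refused with guidance toward
    ``fhr-fasta-combine``, since metadata alone cannot supply sequences.
    """
    in_fmt = detect_format(in_path)
    out_fmt = detect_format(out_path)
    if out_fmt.token == "fasta":
        raise RefusedConversion(
            "converting metadata to FASTA would drop sequence data; "
            "use fhr-fasta-combine <metadata> <input.fasta> <output>"
        )
    record = read_record(in_path, in_fmt)
    write_record(record, out_path, out_fmt)


# re-exported for callers that catch it around convert()
_ = MissingHeader
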