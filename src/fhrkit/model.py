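"""FHR record model and validation.

The FHR (FAIR-bioHeaders Reference genome) standard attaches provenance
metadata to a reference genome: who assembled it, from which organism, when,
with which instruments and software, and a self-referential checksum that
identifies sequence and metadata together.  A record has nine required
fields::

    schema, schemaVersion, genome, taxon, version,
    assemblyAuthor, metadataAuthor, dateCreated, checksum

and up to eleven optional fields (``assemblySoftware``, ``documentation``,
``funding``, ``genomeSynonym``, ``identifier``, ``instrument``,
``reuseConditions``, ``accessionID``, ``voucherSpecimen``, ``relatedLink``,
``scholarlyArticle``).

Records are represented as ordinary mappings (an :class:`FhrRecord` is a
``dict`` subclass) because they travel through YAML, JSON, Microdata-HTML
and FASTA comment blocks; :func:`validate_record` reports rule violations
without raising, and :func:`canonicalize` produces the deterministic form
used for serialization and checksum computation.
"""

from __future__ import annotations

import datetime
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterable
from urllib.parse import urlparse

from .exceptions import ValidationError

__all__ = [
    "Agent",
    "Taxon",
    "AccessionRef",
    "ChecksumValue",
    "FhrRecord",
    "ValidationIssue",
    "ValidationReport",
    "list_required_fields",
    "list_optional_fields",
    "validate_record",
    "canonicalize",
    "schema_path",
    "load_schema",
]

# Specification order; checksum is last so that the self-referential digest
# is the final required line of an embedded header.
REQUIRED_FIELDS: tuple[str, ...] = (
    "schema",
    "schemaVersion",
    "genome",
    "taxon",
    "version",
    "assemblyAuthor",
    "metadataAuthor",
    "dateCreated",
    "checksum",
)

OPTIONAL_FIELDS: tuple[str, ...] = (
    "assemblySoftware",
    "documentation",
    "funding",
    "genomeSynonym",
    "identifier",
    "instrument",
    "reuseConditions",
    "accessionID",
    "voucherSpecimen",
    "relatedLink",
    "scholarlyArticle",
)

#: Fields that may carry several values; scalars are accepted on input and
#: promoted to one-element lists by canonicalization.
MULTI_VALUED: frozenset[str] = frozenset(
    {
        "assemblyAuthor",
        "metadataAuthor",
        "funding",
        "genomeSynonym",
        "identifier",
        "instrument",
        "relatedLink",
        "scholarlyArticle",
    }
)

#: name/uri pair fields and whether their uri is restricted to registries.
AGENT_LIST_FIELDS = ("assemblyAuthor", "metadataAuthor")
REGISTRY_HOSTS = ("identifiers.org", "bioregistry.io")

DIGEST_LENGTHS = {"md5": 32, "sha1": 40, "sha256": 64}

_DATE_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")
_CURIE_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9._-]*:\S+$")
_CHECKSUM_RE = re.compile(r"^([A-Za-z0-9]+):([0-9a-fA-F]+)$")
# en/em dash occasionally introduced by word processors into dates
_DASH_TRANSLATION = str.maketrans({"–": "-", "—": "-"})


class FhrRecord(dict):
    """An FHR metadata record: a mapping of field names to values.

    Behaves exactly like a ``dict``; the subclass exists so signatures and
    reprs say what the mapping is.  Key order is meaningful only after
    :func:`canonicalize`.
    """

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"FhrRecord({dict.__repr__(self)})"


@dataclass(frozen=True)
class Agent:
    """A person or organisation, optionally with an ORCID/ROR-style URI."""

    name: str
    uri: str | None = None

    @classmethod
    def from_mapping(cls, data: dict) -> "Agent":
        return cls(name=str(data.get("name", "")), uri=data.get("uri"))

    def to_mapping(self) -> dict:
        out = {"name": self.name}
        if self.uri is not None:
            out["uri"] = self.uri
        return out


@dataclass(frozen=True)
class Taxon:
    """Organism identification: a free-text name plus a registry URI
    (identifiers.org or bioregistry.io)."""

    name: str
    uri: str

    @classmethod
    def from_mapping(cls, data: dict) -> "Taxon":
        return cls(name=str(data.get("name", "")), uri=str(data.get("uri", "")))

    def to_mapping(self) -> dict:
        return {"name": self.name, "uri": self.uri}


@dataclass(frozen=True)
class AccessionRef:
    """Physical-sample accession: an identifier token (e.g. a BioSample ID)
    and an optional URI to the sample record."""

    name: str
    uri: str | None = None

    @classmethod
    def from_mapping(cls, data: dict) -> "AccessionRef":
        return cls(name=str(data.get("name", "")), uri=data.get("uri"))

    def to_mapping(self) -> dict:
        out = {"name": self.name}
        if self.uri is not None:
            out["uri"] = self.uri
        return out


@dataclass(frozen=True)
class ChecksumValue:
    """An ``<algorithm>:<hexdigest>`` pair, e.g.
    ``md5:a3d5d9146c3992b7ed6724409ba28aa9``."""

    algorithm: str
    digest: str

    @classmethod
    def parse(cls, text: str) -> "ChecksumValue":
        m = _CHECKSUM_RE.match(text.strip())
        if not m:
            raise ValueError(f"not an <algorithm>:<hexdigest> token: {text!r}")
        return cls(algorithm=m.group(1).lower(), digest=m.group(2).lower())

    def __str__(self) -> str:
        return f"{self.algorithm}:{self.digest}"


@dataclass(frozen=True)
class ValidationIssue:
    """One rule violation at a slash-delimited field path."""

    path: str
    severity: str  # "error" | "warning"
    message: str
    code: str

    def __str__(self) -> str:
        return f"{self.severity} {self.path} {self.message}"


@dataclass
class ValidationReport:
    """Ordered collection of issues; ``valid`` iff none is an error."""

    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    def to_dict(self) -> dict:
        return {
            "valid": self.valid,
            "issues": [
                {
                    "path": i.path,
                    "severity": i.severity,
                    "message": i.message,
                    "code": i.code,
                }
                for i in self.issues
            ],
        }


def list_required_fields() -> list[str]:
    """The nine required FHR field names, in specification order."""
    return list(REQUIRED_FIELDS)


def list_optional_fields() -> list[str]:
    """The eleven optional FHR field names."""
    return list(OPTIONAL_FIELDS)


def schema_path() -> Path:
    """Filesystem path of the vendored machine-readable FHR schema."""
    return Path(str(resources.files("fhrkit").joinpath("schema/fhr.json")))


def load_schema() -> dict:
    """Load the vendored JSON schema document."""
    return json.loads(schema_path().read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# validation


def _err(issues, path, code, message):
    issues.append(ValidationIssue(path=path, severity="error", message=message, code=code))


def _warn(issues, path, code, message):
    issues.append(ValidationIssue(path=path, severity="warning", message=message, code=code))


def _is_http_uri(value: Any) -> bool:
    if not isinstance(value, str):
        return False
    parts = urlparse(value.strip())
    return parts.scheme in ("http", "https") and bool(parts.netloc)


def _uri_host(value: str) -> str:
    return urlparse(value.strip()).netloc.lower()


def _check_nonempty_str(issues, path, value) -> bool:
    if isinstance(value, list):
        _err(issues, path, "bad_type", "expected a single value, got a list")
        return False
    if not isinstance(value, str):
        _err(issues, path, "bad_type", f"expected text, got {type(value).__name__}")
        return False
    if not value.strip():
        _err(issues, path, "empty_value", "value is empty")
        return False
    return True


def _as_list(value) -> list:
    """Scalar-or-list input convention: a scalar stands for one value."""
    if isinstance(value, list):
        return value
    return [value]


def _check_agent(issues, path, value, *, kind="author"):
    if not isinstance(value, dict):
        _err(issues, path, "bad_type", f"{kind} entry must be a name/uri mapping")
        return
    if not str(value.get("name", "")).strip():
        _err(issues, f"{path}/name", "empty_value", f"{kind} name is missing or empty")
    uri = value.get("uri")
    if uri is not None and not _is_http_uri(uri):
        _err(issues, f"{path}/uri", "bad_uri", f"{kind} uri must be an absolute http(s) URI")
    for key in value:
        if key not in ("name", "uri"):
            _warn(issues, f"{path}/{key}", "unknown_key", f"unknown {kind} key {key!r}")


def _check_date(issues, value):
    if not isinstance(value, str):
        if isinstance(value, datetime.date):
            # YAML readers hand back date objects; accepted, normalized later
            return
        _err(issues, "/dateCreated", "bad_type", "dateCreated must be a YYYY-MM-DD string")
        return
    text = value.strip()
    if text != text.translate(_DASH_TRANSLATION):
        _warn(
            issues,
            "/dateCreated",
            "nonascii_date_dash",
            "en-dash in date transliterated to ASCII hyphen",
        )
        text = text.translate(_DASH_TRANSLATION)
    if not _DATE_RE.match(text):
        _err(issues, "/dateCreated", "bad_date", f"not an ISO-8601 YYYY-MM-DD date: {value!r}")
        return
    try:
        datetime.date.fromisoformat(text)
    except ValueError:
        _err(issues, "/dateCreated", "bad_date", f"not a valid calendar date: {value!r}")


def _check_checksum(issues, value):
    if not isinstance(value, str):
        _err(issues, "/checksum", "bad_checksum_format", "checksum must be '<algorithm>:<hex>' text")
        return
    m = _CHECKSUM_RE.match(value.strip())
    if not m:
        _err(
            issues,
            "/checksum",
            "bad_checksum_format",
            f"checksum must match '<algorithm>:<hex>', got {value!r}",
        )
        return
    algorithm = m.group(1).lower()
    digest = m.group(2)
    if algorithm not in DIGEST_LENGTHS:
        _err(
            issues,
            "/checksum",
            "unsupported_algorithm",
            f"unsupported checksum algorithm {algorithm!r} (md5, sha1, sha256)",
        )
        return
    if len(digest) != DIGEST_LENGTHS[algorithm]:
        _err(
            issues,
            "/checksum",
            "bad_checksum_format",
            f"{algorithm} digest must be {DIGEST_LENGTHS[algorithm]} hex characters",
        )
    elif digest != digest.lower():
        _warn(issues, "/checksum", "uppercase_digest", "digest normalized to lowercase hex")


def validate_record(record: dict, mode: str = "strict") -> ValidationReport:
    """Check a parsed record against the FHR field rules.

    Parameters
    ----------
    record
        A mapping of (possibly unknown) keys to parsed values.  Scalars in
        multi-valued fields are accepted as one-element values.
    mode
        ``"strict"`` requires all nine required fields.  ``"pre_injection"``
        tolerates a missing ``checksum`` — the state a header is in before
        the self-referential digest has been computed and injected.

    Returns
    -------
    ValidationReport
        One issue per violation; problems are reported, never raised.
    """
    if mode not in ("strict", "pre_injection"):
        raise ValueError(f"unknown validation mode {mode!r}")
    issues: list[ValidationIssue] = []
    if not isinstance(record, dict):
        _err(issues, "/", "bad_type", "record must be a mapping")
        return ValidationReport(issues)

    for name in REQUIRED_FIELDS:
        if name not in record or record[name] is None:
            if name == "checksum" and mode == "pre_injection":
                continue
            _err(issues, f"/{name}", "missing_required", f"required field {name!r} is missing")

    for name, value in record.items():
        if value is None:
            continue
        if name == "schema":
            if _check_nonempty_str(issues, "/schema", value) and not _is_http_uri(value):
                _err(issues, "/schema", "bad_uri", "schema must be an absolute http(s) URI")
        elif name == "schemaVersion":
            if isinstance(value, bool) or not isinstance(value, (int, str)):
                _err(issues, "/schemaVersion", "bad_type", "schemaVersion must be a positive integer")
            elif isinstance(value, str) and not value.strip().isdigit():
                _err(issues, "/schemaVersion", "bad_type", "schemaVersion must be a positive integer")
            elif int(str(value).strip()) < 1:
                _err(issues, "/schemaVersion", "bad_value", "schemaVersion must be >= 1")
        elif name in ("genome", "version", "assemblySoftware", "documentation",
                      "reuseConditions", "voucherSpecimen"):
            _check_nonempty_str(issues, f"/{name}", value)
        elif name == "taxon":
            _validate_taxon(issues, value)
        elif name in AGENT_LIST_FIELDS:
            entries = _as_list(value)
            if not entries:
                _err(issues, f"/{name}", "empty_value", f"{name} must list at least one author")
            for i, entry in enumerate(entries):
                _check_agent(issues, f"/{name}/{i}", entry)
        elif name == "dateCreated":
            _check_date(issues, value)
        elif name == "checksum":
            _check_checksum(issues, value)
        elif name == "accessionID":
            if not isinstance(value, dict):
                _err(issues, "/accessionID", "bad_type", "accessionID must be a name/uri mapping")
            else:
                if not str(value.get("name", "")).strip():
                    _err(issues, "/accessionID/name", "empty_value", "accession name is missing or empty")
                uri = value.get("uri")
                if uri is not None and not _is_http_uri(uri):
                    _err(issues, "/accessionID/uri", "bad_uri", "accession uri must be absolute http(s)")
        elif name in ("relatedLink", "scholarlyArticle"):
            for i, item in enumerate(_as_list(value)):
                if not _is_http_uri(item):
                    _err(issues, f"/{name}/{i}", "bad_uri", f"{name} entries must be absolute http(s) URIs")
        elif name == "identifier":
            for i, item in enumerate(_as_list(value)):
                if not isinstance(item, str) or not _CURIE_RE.match(item.strip()):
                    _err(issues, f"/{name}/{i}", "bad_curie",
                         "identifier entries must be CURIEs of the form prefix:accession")
        elif name in ("funding", "genomeSynonym", "instrument"):
            for i, item in enumerate(_as_list(value)):
                if not isinstance(item, str) or not item.strip():
                    _err(issues, f"/{name}/{i}", "empty_value", f"{name} entries must be non-empty text")
        else:
            # extensibility: unknown keys are carried along with a warning
            _warn(issues, f"/{name}", "unknown_key", f"unknown field {name!r}")

    return ValidationReport(issues)


def _validate_taxon(issues, value):
    if not isinstance(value, dict):
        _err(issues, "/taxon", "bad_type", "taxon must be a name/uri mapping")
        return
    if not str(value.get("name", "")).strip():
        _err(issues, "/taxon/name", "empty_value", "taxon name is missing or empty")
    uri = value.get("uri")
    if uri is None:
        _err(issues, "/taxon/uri", "missing_required", "taxon uri is required")
    elif not _is_http_uri(uri):
        _err(issues, "/taxon/uri", "bad_uri", "taxon uri must be an absolute http(s) URI")
    elif _uri_host(uri) not in REGISTRY_HOSTS:
        _err(
            issues,
            "/taxon/uri",
            "bad_taxon_host",
            "taxon uri must resolve through identifiers.org or bioregistry.io",
        )
    for key in value:
        if key not in ("name", "uri"):
            _warn(issues, f"/taxon/{key}", "unknown_key", f"unknown taxon key {key!r}")


# ---------------------------------------------------------------------------
# canonical form


def _trim(value):
    if isinstance(value, str):
        return value.strip()
    return value


def _canonical_pair(value: dict, keys: Iterable[str] = ("name", "uri")) -> dict:
    out = {}
    for key in keys:
        if key in value and value[key] is not None:
            out[key] = _trim(value[key])
    for key in value:  # unknown sub-keys kept, after name/uri
        if key not in out and value[key] is not None:
            out[key] = _trim(value[key])
    return out


def canonicalize(record: dict) -> FhrRecord:
    """Return the deterministic canonical form of *record*.

    Canonical form underpins both round-trip equality across serializations
    and checksum determinism:

    * required fields first, in specification order (``checksum`` last of
      the nine), then optional fields alphabetically, then any unknown keys
      alphabetically;
    * multi-valued fields always hold lists, singletons included;
    * strings whitespace-trimmed; checksum algorithm token and digest
      lowercased; ``schemaVersion`` emitted as an integer; en-dash in
      ``dateCreated`` transliterated to ASCII hyphen.

    Raises
    ------
    ValidationError
        If the record has error-severity issues under ``pre_injection``
        validation (canonicalization never invents missing content).
    """
    report = validate_record(record, mode="pre_injection")
    if not report.valid:
        raise ValidationError(
            "cannot canonicalize an invalid record: "
            + "; ".join(str(i) for i in report.errors),
            report=report,
        )

    out = FhrRecord()
    known = set(REQUIRED_FIELDS) | set(OPTIONAL_FIELDS)
    optional_sorted = sorted(OPTIONAL_FIELDS)
    unknown_sorted = sorted(k for k in record if k not in known)
    for name in (*REQUIRED_FIELDS, *optional_sorted, *unknown_sorted):
        if name not in record or record[name] is None:
            continue
        value = record[name]
        if name == "schemaVersion":
            out[name] = int(str(value).strip())
        elif name == "dateCreated":
            if isinstance(value, datetime.date):
                out[name] = value.isoformat()
            else:
                out[name] = value.strip().translate(_DASH_TRANSLATION)
        elif name == "checksum":
            out[name] = str(ChecksumValue.parse(value))
        elif name == "taxon" or name == "accessionID":
            out[name] = _canonical_pair(value)
        elif name in AGENT_LIST_FIELDS:
            out[name] = [_canonical_pair(v) for v in _as_list(value)]
        elif name in MULTI_VALUED:
            out[name] = [_trim(v) for v in _as_list(value)]
        else:
            out[name] = _trim(value)
    return out
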