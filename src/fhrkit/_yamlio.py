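"""Shared YAML emission/parsing used by both the FASTA codec and the
sidecar serializers.

Emission is deliberately conservative: block-style mappings, keys in the
order given, plain scalars quoted only where YAML requires.  Input rejects
anchors and aliases so that every value stands on its own line — the
property the ';~' line-prefixing of embedded headers relies on.
"""

from __future__ import annotations

import datetime
from typing import Any

import yaml

from .exceptions import HeaderParseError


class _CanonicalDumper(yaml.SafeDumper):
    """Block style, insertion order, no aliases."""

    def ignore_aliases(self, data: Any) -> bool:
        return True


def dump_mapping(data: dict) -> str:
    """Serialize a plain mapping to deterministic block-style YAML text."""
    return yaml.dump(
        data,
        Dumper=_CanonicalDumper,
        sort_keys=False,
        default_flow_style=False,
        allow_unicode=True,
        width=100000,  # never wrap: one value per line
    )


def _coerce_dates(value: Any) -> Any:
    """YAML resolves unquoted YYYY-MM-DD scalars to date objects; the FHR
    wire value is the ISO string."""
    if isinstance(value, datetime.date):
        return value.isoformat()
    if isinstance(value, dict):
        return {k: _coerce_dates(v) for k, v in value.items()}
    if isinstance(value, list):
        return [_coerce_dates(v) for v in value]
    return value


def load_mapping(text: str) -> dict:
    """Parse YAML text into a mapping, rejecting anchors/aliases and
    non-mapping documents."""
    if not text.strip():
        raise HeaderParseError("empty header text")
    try:
        for event in yaml.parse(text, Loader=yaml.SafeLoader):
            if getattr(event, "anchor", None) is not None:
                raise HeaderParseError("YAML anchors/aliases are not accepted in FHR headers")
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise HeaderParseError(f"header is not well-formed YAML: {exc}") from exc
    if not isinstance(data, dict):
        raise HeaderParseError("header must be a YAML mapping of field names to values")
    return _coerce_dates(data)
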