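# Methods

## The record model

An FHR record is a flat mapping of twenty defined field names. The nine
required fields are the minimum needed to trace a reference genome's
origin: the governing `schema` URI and integer `schemaVersion`; the
`genome` name (free text, ID, or URI); a `taxon` name/URI pair; the
assembly `version`; one or more `assemblyAuthor` and `metadataAuthor`
name/URI pairs (assembly authorship and metadata authorship are kept
separate, so a third-party curator can add provenance to someone else's
assembly); the ISO-8601 `dateCreated`; and the self-referential
`checksum`. The eleven optional fields add how the genome was produced
(`assemblySoftware`, `instrument`, `accessionID`, `voucherSpecimen`),
how it is findable (`identifier` CURIEs, `genomeSynonym`, `relatedLink`,
`scholarlyArticle`), and administrative context (`documentation`,
`funding`, `reuseConditions`).

Records are plain mappings (`FhrRecord` is a `dict` subclass) because they
travel through four serializations; typed views (`Agent`, `Taxon`,
`AccessionRef`, `ChecksumValue`) are provided for callers that want them.

### Validation

`validate_record` collects every violation into a report rather than
raising: each issue carries a slash-delimited path (`/taxon/uri`), an
error/warning severity, a message, and a stable machine code. Choices made
where the rules were genuinely open:

* **Pre-injection mode.** A record is necessarily checksum-less between
  authoring and digest injection; `mode="pre_injection"` treats a missing
  checksum as acceptable while keeping every other rule. All other modes of
  incompleteness remain errors.
* **Registry restriction applies to taxon only.** `taxon.uri` must be
  hosted at identifiers.org or bioregistry.io, the two registries the
  standard names; author/accession URIs need only be absolute http(s).
  Taxon `uri` is required together with `name`; author `uri` is optional.
* **Scalar-or-list.** Multi-valued fields (`assemblyAuthor`,
  `metadataAuthor`, `funding`, `genomeSynonym`, `identifier`,
  `instrument`, `relatedLink`, `scholarlyArticle`) accept a scalar on
  input and are always emitted as lists, so round trips are stable.
* **Unknown keys warn, never fail** — the standard promises extensibility;
  a stranger's extra field should not invalidate a header.
* **Dates.** `YYYY-MM-DD` with ASCII hyphens and a real calendar check; an
  en-dash (a common word-processor artifact) is transliterated with a
  warning rather than rejected.
* **Checksum tokens.** `md5`, `sha1`, `sha256` accepted, with digest
  lengths enforced (32/40/64 hex); md5 is the default the ecosystem uses.
  Algorithm token and digest are lowercased in canonical form.
* **schemaVersion** is an integer ≥ 1; the string `"1"` is accepted on
  input and emitted as an integer.

A machine-readable JSON schema mirroring these rules is vendored at
`src/fhrkit/schema/fhr.json` and exposed via `fhrkit.schema_path()`, so
validation never requires network access; the `schema` field of a record
is checked as a URI string, not fetched.

### Canonical form

`canonicalize` makes serialization and digestion deterministic: required
fields first in specification order (checksum last of the nine), optional
fields alphabetically, then unknown keys alphabetically; singletons
promoted to lists; strings trimmed; `name` before `uri` in nested pairs.
It is idempotent and key-order-insensitive (property-tested), and raises
on records with error-severity issues — canonicalization never invents
content.

## FASTA embedding

The codec is byte-faithful: each line is stored with its own terminator,
so parse→serialize reproduces the input exactly, including CRLF files and
a missing final newline. The header block is the canonical YAML of the
record with `;~` prefixed to every line, placed before all other content;
plain `;` comments and sequence records are never modified. YAML
anchors/aliases are rejected on input so every value stays on its own
prefixed line; one optional space after `;~` is tolerated on input and
never emitted. `;~` lines found after the first sequence record (e.g.
after careless file concatenation) are ignored by extraction and removed
by stripping, each with a warning. Embedding refuses to stack a second
header unless overwrite is requested; stripping a header-less file is the
identity.

## The checksum

The digest covers the file minus the checksum itself and is injected into
the header afterwards, so one token identifies sequences and metadata
together. Two payload conventions:

* **Canonical (default):** header re-serialized in canonical order with
  the entire checksum line removed (removing key and value avoids any
  ambiguity about separators), newlines normalized to LF, trailing LF
  guaranteed. This deliberately trades bit-exact file identification for
  robustness to the classic failure mode of raw-file checksums — a
  Windows editor rewriting LF as CRLF — and to header key re-ordering.
  Verification of a CRLF re-serialization therefore still succeeds, while
  any single-byte sequence change fails (both property-tested).
* **Strict bytes (`strict_bytes=True` / `--strict-bytes`):** the digest
  covers the raw bytes with only the `;~checksum:` line excluded; any
  byte-level change, including newline style, invalidates it.

Injection rewrites the header canonically and is idempotent. For sidecar
metadata the digest is computed over the same staged construction —
canonical header plus FASTA body — so embedded and sidecar forms of one
genome carry the same checksum (`fhr-fasta-combine` produces exactly this).
The worked-example digest string in the standard's documentation is a
format example only; its source bytes are not published, so the test
suite's digest oracle is `hashlib` applied directly to a hand-constructed
payload instead.

## Sidecar serializations

YAML (human+machine), JSON (interchange) and Microdata-HTML (search-engine
exposure), all emitting canonical field order so writes are byte-
deterministic and every format round-trips to the identical canonical
record. The Microdata vocabulary is not prescribed anywhere, so the only
self-consistent choice is used: one item whose `itemtype` is the record's
`schema` URI, one `itemprop` per field, with name/URI pairs as nested
items and URIs carried on `href`. Format dispatch is by longest filename
suffix (`x.fhr.yaml` is YAML, not FASTA); converting metadata *to* FASTA
is refused with guidance toward `fhr-fasta-combine`, since metadata alone
cannot supply sequence data. Writers go through a temp-file-and-rename
path, so no partial output survives a failure. A warning (not an error) is
issued when a sidecar is written with no adjacent FASTA matching the
`<genome file name>.fhr.<ext>` naming template.

## Fixture generation

All test inputs are generated, seeded and offline. `generate_record`
draws from small templated pools shaped like real provenance (ORCID-style
author URIs, identifiers.org taxonomy URIs with genuine taxon IDs,
BioSample-style accessions, assembler/instrument names); `minimal` records
carry exactly the nine required fields, `full` all twenty. The placeholder
checksum in a generated record is well-formed but arbitrary — a genuine
digest only exists once a record meets its FASTA. `generate_fasta`
produces uniform-random ACGT sequences (default 1–3 records of 60–240 bp,
60-column wrap, LF or CRLF) — realistic in structure, deliberately not in
composition; nothing in the toolkit reads the sequence content beyond
bytes, so passing tests say nothing about alphabet handling beyond ACGT
and say everything about byte preservation. `apply_defect` plants exactly
one flaw (missing required field, bad date, wrong taxon registry host,
malformed checksum token, list-in-scalar-field, unknown key) at a stated
path, and the suite checks each yields exactly one issue there. Same seed
⇒ identical bytes on one implementation; cross-implementation byte
equality is not promised.

## Problem sizes and numerical choices

The acceptance script and the deeper property tests run populations of
200 seeded records/documents per contract — records are a few hundred
bytes and documents a few kilobytes, so the whole surface completes in
seconds on one CPU. Hypothesis profiles are derandomized for reproducible
runs. Text I/O is UTF-8 throughout; digests are lowercase hex.

## Known limitations

* Sequence content is untouched but also unvalidated: no alphabet checks,
  wrapping normalization, or `.fai` indexing.
* URIs are validated syntactically (scheme, host), never resolved; no
  check that a taxonomy ID actually matches the genome.
* The canonical-payload checksum does not detect edits that canonicalize
  away (e.g. re-ordering header keys) — by design; use strict-bytes mode
  when bit-exact identification is the goal.
* Microdata parsing handles the documents this package writes and
  reasonable hand-authored ones; it is not a general HTML5 Microdata
  extractor (no `itemref`, no `itemid`).
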