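# fhrkit

Toolkit for **FHR** (FAIR-bioHeaders Reference genome) metadata: create,
validate, serialize, checksum and interconvert provenance records for
reference-genome FASTA files.

## The problem

Reference genome FASTA files carry no intrinsic provenance. As assemblies
are copied, renamed, re-wrapped and re-hosted across repositories and
genome browsers, the link between a sequence file and its metadata —
organism, assembly version, authors, instruments, licence — erodes, and
plain file checksums break under semantically-neutral edits such as
CRLF/LF newline churn. FHR addresses this by keeping a small, structured
metadata record *inside* the FASTA file, using the legacy 1985 semicolon
comment block: each line of a YAML-serialized record is prefixed with
`;~` at the top of the file. The same record can alternatively travel as a
sidecar file named `<genome file name>.fhr.<yaml|json|html>`.

A record has nine required fields —

```
schema, schemaVersion, genome, taxon, version,
assemblyAuthor, metadataAuthor, dateCreated, checksum
```

— and up to eleven optional fields (`assemblySoftware`, `documentation`,
`funding`, `genomeSynonym`, `identifier`, `instrument`, `reuseConditions`,
`accessionID`, `voucherSpecimen`, `relatedLink`, `scholarlyArticle`).
`taxon` must point at a public registry (identifiers.org or bioregistry.io);
dates are ISO-8601; authors are name/URI pairs (ORCID/ROR-style).

The **checksum is self-referential**: with the checksum field excluded, the
header and sequences are serialized to a canonical payload (canonical field
order, LF newlines, trailing LF), digested (md5 by default; sha1/sha256
supported), and the `<algorithm>:<hexdigest>` token is injected back into
the header. One token then pins both the genome and its metadata, and the
digest survives newline churn and header re-ordering while flagging any
real change to sequence or metadata. A `--strict-bytes` mode digests raw
bytes instead, for bit-exact identification.

## Worked example

```python
from fhrkit import (FhrRecord, validate_record, parse_fasta, embed_header,
                    inject_checksum, verify_checksum, extract_header)

record = FhrRecord({
    "schema": "https://raw.githubusercontent.com/FAIR-bioHeaders/FHR-Specification/main/fhr.json",
    "schemaVersion": 1,
    "genome": "Example species",
    "taxon": {"name": "Example species", "uri": "https://identifiers.org/taxonomy:0000"},
    "version": "2.3",
    "assemblyAuthor": [{"name": "Jane Doe", "uri": "https://orcid.org/0000-0002-9511-5139"}],
    "metadataAuthor": [{"name": "John Doe", "uri": "https://orcid.org/0000-0002-1983-4588"}],
    "dateCreated": "2022-03-21",
})

report = validate_record(record, mode="pre_injection")
print(report.valid)          # True — complete but for the not-yet-computed checksum

doc = embed_header(record, parse_fasta(b">chr1\nACGTACGT\n"))
sealed = inject_checksum(doc)
print(extract_header(sealed)["checksum"])
# md5:e22561243b6fa57353cf07a87c9cc954   <- digest of sequences + metadata
print(verify_checksum(sealed)[0])        # True
```

`validate_record` never raises: it returns a report with one issue per
violation (`error /taxon/uri taxon uri must resolve through
identifiers.org or bioregistry.io`, ...), and `valid` is true iff no issue
has error severity. The `examples/` directory holds one narrative script
per capability (validation, FASTA embedding, sidecar conversion, the
checksum lifecycle).

## Command line

Five commands, with exit codes 0 (success), 1 (validation/checksum
failure), 2 (usage/format error):

```sh
fhr-convert genome.fhr.yaml genome.fhr.json   # interconvert yaml/json/html; extract from FASTA
fhr-validate genome.fhr.yaml                  # schema validation (checksum not verified)
fhr-fasta-combine genome.fhr.yaml genome.fasta genome.fhr.fasta   # embed + inject checksum
fhr-fasta-validate genome.fhr.fasta           # schema + checksum verification
fhr-fasta-strip genome.fhr.fasta plain.fasta  # remove the header, byte-preserving
```

`fhr-fixtures DIR` writes a deterministic corpus of paired
`.fasta`/`.fhr.yaml` test files.

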