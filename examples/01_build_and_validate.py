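"""Build an FHR record by hand and validate it.

An FHR record describes a reference genome's provenance: organism, version,
who assembled it, who wrote the metadata, when, and a checksum.  Validation
reports every rule violation with a field path and severity instead of
stopping at the first problem.
"""

from fhrkit import FhrRecord, canonicalize, validate_record

record = FhrRecord(
    {
        "schema": "https://raw.githubusercontent.com/FAIR-bioHeaders/FHR-Specification/main/fhr.json",
        "schemaVersion": 1,
        "genome": "Example species",
        "taxon": {"name": "Example species", "uri": "https://identifiers.org/taxonomy:0000"},
        "version": "2.3",
        "assemblyAuthor": {"name": "Jane Doe", "uri": "https://orcid.org/0000-0002-9511-5139"},
        "metadataAuthor": {"name": "John Doe", "uri": "https://orcid.org/0000-0002-1983-4588"},
        "dateCreated": "2022-03-21",
        "checksum": "md5:a3d5d9146c3992b7ed6724409ba28aa9",
    }
)

report = validate_record(record, mode="strict")
print(f"valid: {report.valid}  errors: {len(report.errors)}  warnings: {len(report.warnings)}")
# valid: True means the record carries all nine required fields correctly.

# A flawed copy: the taxon URI must point at a public identifier registry.
broken = FhrRecord(record, taxon={"name": "Example species", "uri": "https://example.com/tax"})
for issue in validate_record(broken).issues:
    print(issue)  # e.g. "error /taxon/uri taxon uri must resolve through ..."

# Canonicalization promotes the single authors above to one-element lists
# and fixes field order — the form every serializer emits.
print(list(canonicalize(record))[:3], "...")
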