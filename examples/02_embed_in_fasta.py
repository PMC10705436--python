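"""Embed a metadata record into a FASTA file and strip it back out.

The header rides in the FASTA file's legacy comment block: every line of
the YAML-serialized record is prefixed with ';~', so sequence-aware tools
that honour the 1985 comment convention skip it, and a one-line filter
removes it for tools that do not.
"""

from fhrkit import embed_header, extract_header, generate_record, parse_fasta, strip_header

fasta = parse_fasta(b">chr1 toy contig\nACGTACGTACGT\nTTGGCCAA\n")
record = generate_record(seed=1, completeness="minimal")

combined = embed_header(record, fasta)
print(combined.to_text())
# The ';~' block sits above the sequence records, untouched below it.

recovered = extract_header(combined)
print("recovered genome:", recovered["genome"])

stripped = strip_header(combined)
print("strip restores the original bytes:", stripped.to_bytes() == fasta.to_bytes())
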