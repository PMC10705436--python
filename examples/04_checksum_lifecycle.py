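"""The self-referential checksum: inject, verify, survive newline churn.

The digest covers the whole file — sequences and metadata — minus the
checksum field itself, then is written into that field.  It is computed
over a canonical payload (LF newlines, canonical field order), so the edits
that plague raw file checksums (a Windows editor flipping LF to CRLF) do
not invalidate it, while any real change to sequence or metadata does.
"""

from fhrkit import (
    embed_header,
    extract_header,
    generate_fasta,
    generate_record,
    inject_checksum,
    parse_fasta,
    verify_checksum,
)

record = generate_record(seed=2, completeness="minimal")
record.pop("checksum")  # pre-injection state: everything but the digest

doc = embed_header(record, generate_fasta(seed=3, n_records=2))
sealed = inject_checksum(doc)
print("injected:", extract_header(sealed)["checksum"])

ok, _ = verify_checksum(sealed)
print("verifies after injection:", ok)

crlf = parse_fasta(sealed.to_text().replace("\n", "\r\n").encode())
ok_crlf, _ = verify_checksum(crlf)
print("still verifies after CRLF round trip:", ok_crlf)

mutated_text = sealed.to_text().replace("ACG", "TTT", 1)
ok_mut, report = verify_checksum(parse_fasta(mutated_text.encode()))
print("verifies after mutating the sequence:", ok_mut)
if not ok_mut:
    print(report.errors[0])  # error /checksum header/data mismatch: ...
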