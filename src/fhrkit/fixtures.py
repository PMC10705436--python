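"""Deterministic fixture generation: records, FASTA documents, defects.

Everything the test surface needs is generated locally from a seed — no
downloads.  The generated values are shaped like the worked examples of the
standard (ORCID-style author URIs, identifiers.org taxonomy URIs,
BioSample-style accessions) without being biologically meaningful; sequence
composition is uniform random ACGT.

Same seed + same parameters ⇒ identical output on a given implementation
(``random.Random`` is stable across runs); byte equality across different
PRNG implementations is not promised.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

from .fasta import FastaDocument, embed_header
from .model import FhrRecord, OPTIONAL_FIELDS, REQUIRED_FIELDS
from .serializers import to_yaml_text

__all__ = [
    "DefectSpec",
    "DEFECT_KINDS",
    "generate_record",
    "generate_fasta",
    "apply_defect",
    "write_corpus",
]

SCHEMA_URI = "https://raw.githubusercontent.com/FAIR-bioHeaders/FHR-Specification/main/fhr.json"

_GIVEN = ["Ada", "Grace", "Alan", "Rosalind", "Barbara", "Linus", "Margaret", "Kary"]
_FAMILY = ["Lovelace", "Hopper", "Turing", "Franklin", "McClintock", "Pauling", "Dayhoff", "Mullis"]
_TAXA = [
    ("Caenorhabditis elegans", 6239),
    ("Drosophila melanogaster", 7227),
    ("Mus musculus", 10090),
    ("Danio rerio", 7955),
    ("Arabidopsis thaliana", 3702),
    ("Saccharomyces cerevisiae", 4932),
    ("Apis mellifera", 7460),
    ("Carya illinoinensis", 32201),
]
_ASSEMBLERS = ["hifiasm 0.19.8", "Flye 2.9.2", "SPAdes 3.15.5", "Canu 2.2", "verkko 1.4"]
_INSTRUMENTS = [
    "PacBio Sequel IIe",
    "Oxford Nanopore PromethION",
    "Illumina NovaSeq 6000",
    "PacBio Revio",
]
_LICENSES = ["CC0 1.0", "CC BY 4.0", "CC BY-SA 4.0"]

DEFECT_KINDS = (
    "missing_required",
    "bad_date",
    "bad_taxon_host",
    "bad_checksum_format",
    "scalar_where_list_forbidden",
    "unknown_key",
)


@dataclass(frozen=True)
class DefectSpec:
    """A single deliberate flaw: what kind, and at which field path."""

    kind: str
    target_path: str

    def __post_init__(self):
        if self.kind not in DEFECT_KINDS:
            raise ValueError(f"unknown defect kind {self.kind!r}")


def _agent(rng: random.Random) -> dict:
    name = f"{rng.choice(_GIVEN)} {rng.choice(_FAMILY)}"
    orcid = "-".join(f"{rng.randrange(10**4):04d}" for _ in range(4))
    return {"name": name, "uri": f"https://orcid.org/{orcid}"}


def generate_record(seed: int, completeness: str = "minimal") -> FhrRecord:
    """Generate a valid FHR record.

    ``minimal`` carries exactly the nine required fields; ``full`` all
    twenty.  The checksum field holds a well-formed md5 token (a genuine
    self-referential digest only exists once the record meets its FASTA —
    see :func:`fhrkit.checksum.inject_checksum`).
    """
    if completeness not in ("minimal", "full"):
        raise ValueError(f"completeness must be 'minimal' or 'full', got {completeness!r}")
    rng = random.Random(seed)
    taxon_name, taxid = rng.choice(_TAXA)
    genome = f"{taxon_name} isolate {rng.randrange(1, 1000)}"
    record = FhrRecord(
        {
            "schema": SCHEMA_URI,
            "schemaVersion": 1,
            "genome": genome,
            "taxon": {
                "name": taxon_name,
                "uri": f"https://identifiers.org/taxonomy:{taxid}",
            },
            "version": f"{rng.randrange(1, 9)}.{rng.randrange(0, 20)}",
            "assemblyAuthor": [_agent(rng) for _ in range(rng.randrange(1, 3))],
            "metadataAuthor": [_agent(rng)],
            "dateCreated": f"{rng.randrange(2015, 2026)}-{rng.randrange(1, 13):02d}-{rng.randrange(1, 29):02d}",
            "checksum": "md5:" + "".join(rng.choice("0123456789abcdef") for _ in range(32)),
        }
    )
    if completeness == "full":
        accession = rng.randrange(10**7, 10**8)
        record.update(
            {
                "assemblySoftware": rng.choice(_ASSEMBLERS),
                "documentation": f"Assembly of {genome}, generated for testing.",
                "funding": [f"Project number {rng.randrange(10**9, 10**10)}"],
                "genomeSynonym": [f"{taxon_name.split()[0][0]}{taxon_name.split()[1][:3]}_{rng.randrange(10)}"],
                "identifier": [f"insdc.gca:GCA_{rng.randrange(10**9):09d}.{rng.randrange(1, 5)}"],
                "instrument": rng.sample(_INSTRUMENTS, rng.randrange(1, 3)),
                "reuseConditions": rng.choice(_LICENSES),
                "accessionID": {
                    "name": f"BioSample:SAMN{accession}",
                    "uri": f"https://example.org/biosample/SAMN{accession}",
                },
                "voucherSpecimen": f"Freezer {rng.randrange(1, 50)}, drawer {rng.randrange(1, 200)}, Example Collection",
                "relatedLink": [f"https://example.org/genomes/{taxid}"],
                "scholarlyArticle": [f"https://doi.org/10.5555/{rng.randrange(10**6)}"],
            }
        )
    return record


def generate_fasta(
    seed: int,
    n_records: int = 3,
    length_range: tuple[int, int] = (60, 240),
    newline_style: str = "LF",
    plain_comments: bool = False,
    wrap: int = 60,
) -> FastaDocument:
    """Generate a plain (header-less) FASTA document of random ACGT records."""
    rng = random.Random(seed)
    newline = "\r\n" if newline_style == "CRLF" else "\n"
    lines: list[tuple[str, str]] = []
    if plain_comments:
        lines.append(("; synthetic test sequences", newline))
    for i in range(n_records):
        length = rng.randrange(length_range[0], length_range[1] + 1)
        seq = "".join(rng.choice("ACGT") for _ in range(length))
        lines.append((f">seq{i + 1} synthetic length={length}", newline))
        for start in range(0, length, wrap):
            lines.append((seq[start : start + wrap], newline))
    return FastaDocument(lines=lines)


def apply_defect(record: dict, defect: DefectSpec) -> FhrRecord:
    """Return a copy of *record* carrying exactly one deliberate flaw.

    Validation of the result reports exactly one issue, at
    ``defect.target_path``.
    """
    out = FhrRecord({k: (dict(v) if isinstance(v, dict) else list(v) if isinstance(v, list) else v)
                     for k, v in record.items()})
    field = defect.target_path.strip("/").split("/")[0]
    if defect.kind == "missing_required":
        if field not in REQUIRED_FIELDS:
            raise ValueError(f"{field!r} is not a required field")
        out.pop(field, None)
    elif defect.kind == "bad_date":
        out["dateCreated"] = "21-03-2022"
    elif defect.kind == "bad_taxon_host":
        out["taxon"]["uri"] = "https://example.com/taxonomy:6239"
    elif defect.kind == "bad_checksum_format":
        out["checksum"] = "md5;deadbeef"
    elif defect.kind == "scalar_where_list_forbidden":
        if field not in out or isinstance(out[field], (list, dict)):
            raise ValueError(f"{field!r} does not hold a scalar value")
        out[field] = [out[field], out[field]]
    elif defect.kind == "unknown_key":
        out[field] = "unexpected"
    return out


def write_corpus(out_dir: Path | str, seed: int = 0, count: int = 5) -> list[Path]:
    """Write ``count`` paired ``.fasta`` / ``.fhr.yaml`` fixtures to a
    directory; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for i in range(count):
        record = generate_record(seed * 10007 + i, "full" if i % 2 else "minimal")
        doc = generate_fasta(seed * 20011 + i, n_records=2 + i % 3)
        base = f"fixture{i:03d}"
        fasta_path = out_dir / f"{base}.fasta"
        fasta_path.write_bytes(doc.to_bytes())
        sidecar_path = out_dir / f"{base}.fhr.yaml"
        sidecar_path.write_text(to_yaml_text(record), encoding="utf-8")
        written += [fasta_path, sidecar_path]
    return written


def generate_embedded_fasta(seed: int, **fasta_kwargs) -> FastaDocument:
    """Convenience: a FASTA with an embedded (pre-injection valid) header."""
    record = generate_record(seed, "full" if seed % 2 else "minimal")
    doc = generate_fasta(seed + 1, **fasta_kwargs)
    return embed_header(record, doc)
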