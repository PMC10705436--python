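"""Write the same record as YAML, JSON and Microdata-HTML sidecars.

When a FASTA consumer cannot tolerate comment lines, the metadata travels
in a sidecar named `<genome file name>.fhr.<ext>` next to the FASTA.  All
three formats round-trip to the identical canonical record, so any of them
can serve as the source of truth.
"""

import tempfile
from pathlib import Path

from fhrkit import canonicalize, convert, generate_record, read_record, write_record

record = generate_record(seed=5, completeness="full")

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    yaml_path = tmp / "genome.fhr.yaml"
    write_record(record, yaml_path)
    print(yaml_path.read_text()[:200], "...\n")

    # Formats are inferred from the suffixes; yaml -> json -> html.
    convert(yaml_path, tmp / "genome.fhr.json")
    convert(tmp / "genome.fhr.json", tmp / "genome.fhr.html")

    forms = [read_record(tmp / f"genome.fhr.{ext}") for ext in ("yaml", "json", "html")]
    agree = all(canonicalize(f) == canonicalize(record) for f in forms)
    print("yaml/json/html all carry the identical canonical record:", agree)
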