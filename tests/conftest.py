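import pytest
from hypothesis import settings

from fhrkit import FhrRecord

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def worked_example_record() -> FhrRecord:
    """The complete worked-example record of the standard: one genome,
    one assembly author, one metadata author, an md5 checksum."""
    return FhrRecord(
        {
            "schema": "https://raw.githubusercontent.com/FAIR-bioHeaders/FHR-Specification/main/fhr.json",
            "schemaVersion": 1,
            "genome": "Example species",
            "taxon": {
                "name": "Example species",
                "uri": "https://identifiers.org/taxonomy:0000",
            },
            "version": "2.3",
            "assemblyAuthor": [
                {"name": "Jane Doe", "uri": "https://orcid.org/0000-0002-9511-5139"}
            ],
            "metadataAuthor": [
                {"name": "John Doe", "uri": "https://orcid.org/0000-0002-1983-4588"}
            ],
            "dateCreated": "2022-03-21",
            "checksum": "md5:a3d5d9146c3992b7ed6724409ba28aa9",
        }
    )
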