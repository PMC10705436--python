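{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://raw.githubusercontent.com/FAIR-bioHeaders/FHR-Specification/main/fhr.json",
  "title": "FHR",
  "description": "FAIR-bioHeaders Reference genome metadata record (local mirror of the hosted schema; vendored so validation never requires network access)",
  "type": "object",
  "required": [
    "schema",
    "schemaVersion",
    "genome",
    "taxon",
    "version",
    "assemblyAuthor",
    "metadataAuthor",
    "dateCreated",
    "checksum"
  ],
  "properties": {
    "schema": {
      "type": "string",
      "format": "uri",
      "description": "URI of the schema document the record conforms to"
    },
    "schemaVersion": {
      "type": "integer",
      "minimum": 1,
      "description": "Version of the FHR schema"
    },
    "genome": {
      "type": "string",
      "description": "Name of the genome (human-readable name, alphanumeric ID, or URI)"
    },
    "taxon": {
      "type": "object",
      "required": ["name", "uri"],
      "properties": {
        "name": {"type": "string", "description": "Name or common name of the taxon"},
        "uri": {
          "type": "string",
          "format": "uri",
          "pattern": "^https?://(identifiers\\.org|bioregistry\\.io)/",
          "description": "Registry URI of the taxon (identifiers.org or bioregistry.io)"
        }
      }
    },
    "version": {
      "type": "string",
      "description": "Version of the genome assembly"
    },
    "assemblyAuthor": {
      "type": "array",
      "minItems": 1,
      "items": {"$ref": "#/$defs/agent"},
      "description": "Assembler(s) of the genome (person or organisation)"
    },
    "metadataAuthor": {
      "type": "array",
      "minItems": 1,
      "items": {"$ref": "#/$defs/agent"},
      "description": "Author(s) of the FHR instance, not the genome"
    },
    "dateCreated": {
      "type": "string",
      "pattern": "^\\d{4}-\\d{2}-\\d{2}$",
      "description": "Date the genome assembly was created (ISO-8601 calendar date)"
    },
    "checksum": {
      "type": "string",
      "pattern": "^(md5|sha1|sha256):[0-9a-f]+$",
      "description": "Algorithm and hash of the genome plus its header, minus this field"
    },
    "assemblySoftware": {"type": "string", "description": "Assembly software used to create the genome"},
    "documentation": {"type": "string", "description": "Free-text documentation about the genome"},
    "funding": {
      "type": "array",
      "items": {"type": "string"},
      "description": "Grant line items; multiple funding lines allowed"
    },
    "genomeSynonym": {
      "type": "array",
      "items": {"type": "string"},
      "description": "Other names of the genome"
    },
    "identifier": {
      "type": "array",
      "items": {"type": "string", "pattern": "^[A-Za-z_][A-Za-z0-9._-]*:\\S+$"},
      "description": "CURIEs identifying the genome"
    },
    "instrument": {
      "type": "array",
      "items": {"type": "string"},
      "description": "Physical tools and instruments used"
    },
    "reuseConditions": {"type": "string", "description": "Licensing terms for the genomic data"},
    "accessionID": {
      "type": "object",
      "required": ["name"],
      "properties": {
        "name": {"type": "string", "description": "Physical ID of the genome assembly sample"},
        "uri": {"type": "string", "format": "uri", "description": "URL of the physical sample"}
      }
    },
    "voucherSpecimen": {"type": "string", "description": "Description of the physical sample location"},
    "relatedLink": {
      "type": "array",
      "items": {"type": "string", "format": "uri"},
      "description": "Related URLs of the genome (host site and mirrors)"
    },
    "scholarlyArticle": {
      "type": "array",
      "items": {"type": "string", "format": "uri"},
      "description": "URLs of the scholarly articles the genome was published in"
    }
  },
  "$defs": {
    "agent": {
      "type": "object",
      "required": ["name"],
      "properties": {
        "name": {"type": "string", "description": "Name of the person or organisation"},
        "uri": {"type": "string", "format": "uri", "description": "ORCID/ROR-style URL of the agent"}
      }
    }
  }
}
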