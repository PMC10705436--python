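"""Exception hierarchy for fhrkit.

Every failure the library raises deliberately derives from :class:`FhrError`
so callers (and the command-line tools) can distinguish domain failures from
programming errors.
"""


class FhrError(Exception):
    """Base class for all fhrkit errors."""


class DecodeError(FhrError):
    """Input bytes are not valid UTF-8."""


class EmptyInput(FhrError):
    """A zero-byte file was given where content is required."""


class MissingHeader(FhrError):
    """No FHR header (';~' lines) is present in the document."""


class MissingChecksum(FhrError):
    """The header exists but carries no checksum field."""


class HeaderParseError(FhrError):
    """The header text is not a well-formed YAML mapping."""


class MicrodataError(FhrError):
    """An HTML document does not contain a Microdata FHR item."""


class ReplaceRefused(FhrError):
    """An FHR header already exists and overwrite was not requested."""


class UnsupportedFormat(FhrError):
    """The filename suffix does not map to a known serialization format."""


class UnsupportedAlgorithm(FhrError):
    """The checksum algorithm token is not one of md5/sha1/sha256."""


class RefusedConversion(FhrError):
    """The requested conversion cannot produce a meaningful output.

    Converting sidecar metadata to FASTA would have to invent sequence data;
    use ``fhr-fasta-combine`` with the companion FASTA instead.
    """


class ValidationError(FhrError):
    """A record with error-severity validation issues was passed to an
    operation that requires a (pre-injection) valid record."""

    def __init__(self, message: str, report=None):
        super().__init__(message)
        self.report = report
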