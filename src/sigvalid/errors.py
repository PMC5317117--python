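"""Exception hierarchy used across the package."""


class SigvalidError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SigvalidError):
    """A file does not conform to its declared format."""


class MatchError(SigvalidError):
    """Signature-to-matrix gene matching failed or fell below threshold."""


class DegenerateDataError(SigvalidError):
    """Input data is too degenerate for the requested computation."""
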