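"""Exception hierarchy used across the package."""


class BDTTError(Exception):
    """Base class for all package errors."""


class FormatError(BDTTError):
    """Input could not be parsed in the expected format."""


class ValidationError(BDTTError):
    """Input parsed but violates a structural invariant."""
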