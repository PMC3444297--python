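"""Exception hierarchy shared across the package."""


class BeadpoolError(Exception):
    """Base class for all package-specific errors."""


class FormatError(BeadpoolError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(BeadpoolError):
    """In-memory data violates a container invariant or a precondition."""
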