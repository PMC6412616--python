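"""Exception types shared across the package.

Two failure families are distinguished: a file that cannot be decoded at
all (:class:`FormatError`) and an input that decodes but violates a
domain invariant (:class:`ContentError`).  Both derive from ``ValueError``
so generic callers may catch either uniformly.
"""


class QubeError(ValueError):
    """Base class for all package-specific errors."""


class FormatError(QubeError):
    """The file or byte stream could not be parsed in the requested format."""


class ContentError(QubeError):
    """The input parsed but violates a domain invariant (shape, range, count)."""
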