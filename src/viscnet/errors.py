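"""Exception hierarchy shared across the pipeline.

Every stage raises :class:`ValidationError` for semantically invalid input
(negative dose, missing ROI, out-of-range grade ...) and
:class:`FormatError` for structurally broken files (missing columns,
unparseable cells).  The CLI maps both to exit code 2.
"""


class ViscnetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ViscnetError):
    """A file does not have the expected structure (columns, types)."""


class ValidationError(ViscnetError):
    """Structurally valid input violates a domain invariant."""
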