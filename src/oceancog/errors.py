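"""Exception hierarchy shared across the package.

Validation problems (bad values, inconsistent tables) raise
:class:`ValidationError`; structurally unreadable input files raise
:class:`FormatError`; statistically degenerate inputs (e.g. a constant row
where variation is required) raise :class:`DegenerateDataError`.
"""


class OceanCOGError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(OceanCOGError, ValueError):
    """A value or table violates a documented invariant."""


class FormatError(OceanCOGError, ValueError):
    """An input file does not conform to the documented TSV layout."""


class DegenerateDataError(OceanCOGError, ValueError):
    """Input is structurally valid but statistically degenerate."""
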