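"""Exception hierarchy shared across the package.

All errors derive from :class:`OasigError` so callers can catch the
package's failures with a single except clause; the subclasses mirror the
contract categories of the I/O and statistics layers (format vs parse vs
validation vs degenerate-input).
"""


class OasigError(Exception):
    """Base class for all errors raised by this package."""


class TableFormatError(OasigError):
    """A required column or structural feature is missing from an input file."""


class TableParseError(OasigError):
    """A cell could not be parsed; the message cites the 1-based file line."""


class ValidationError(OasigError):
    """An in-memory object violates a domain invariant (duplicate gene, bad label...)."""


class DegenerateInputError(OasigError):
    """The computation is undefined for this input (constant scores, empty overlap...)."""


class SimConfigError(OasigError):
    """A synthetic-data configuration is out of range or internally infeasible."""
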