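"""Exception hierarchy shared across the toolkit.

``FormatError`` covers malformed input files (missing columns, empty
files), ``ValidationError`` covers inputs that parse but violate the data
model, and ``InsufficientAnchorsError`` / ``DegenerateFitError`` cover the
retention-time fitting preconditions. The CLI maps all of these to exit
code 2.
"""


class SpeclibError(Exception):
    """Base class for all toolkit errors."""


class FormatError(SpeclibError):
    """An input file does not conform to the expected format."""


class ValidationError(SpeclibError):
    """Parsed data violates an invariant of the data model."""


class InsufficientAnchorsError(SpeclibError):
    """Fewer than the minimum number of shared anchor peptides."""


class DegenerateFitError(SpeclibError):
    """A retention-time fit cannot be applied (e.g. zero slope)."""
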