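"""Exception hierarchy.

Configuration/parse problems and data problems are kept distinct so the CLI
can map them to different exit codes (2 and 3 respectively).
"""


class CcframanError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CcframanError, ValueError):
    """Invalid simulation or pipeline configuration."""


class ParameterError(CcframanError, ValueError):
    """Invalid algorithm parameter (window size, polynomial order, ...)."""


class ParseError(CcframanError, ValueError):
    """A file could not be parsed in the declared dialect."""


class ReferenceError_(CcframanError, KeyError):
    """Problem with the peak-window reference table (unknown group, bad bounds)."""


class DataError(CcframanError, ValueError):
    """Spectral data violates an invariant (non-finite, duplicate axis values)."""


class AlignmentError(CcframanError, ValueError):
    """Operation requires spectra on an identical wavenumber axis."""
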