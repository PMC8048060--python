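"""Exception hierarchy shared across the pipeline.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3; anything
else surfacing from a stage is an internal error (exit code 4).
"""


class BarcodegapError(Exception):
    """Base class for all package errors."""


class ConfigError(BarcodegapError):
    """Invalid configuration or parameter value."""


class DataError(BarcodegapError):
    """Malformed or inconsistent input data."""


class RaggedAlignmentError(DataError):
    """Alignment rows are not all the same length."""


class AlphabetError(DataError):
    """A residue outside the IUPAC DNA alphabet (plus gap) was found."""
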