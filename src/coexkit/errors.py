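"""Exception hierarchy shared across the toolkit.

``FormatError`` flags structurally malformed input files (bad headers,
wrong field counts), ``DataError`` flags well-formed files carrying
invalid content (non-numeric cells, empty intersections), and
``ConfigError`` flags pipeline configuration problems detected before any
computation starts.  Argument errors on in-memory values raise the
built-in ``ValueError``/``KeyError``.
"""


class CoexkitError(Exception):
    """Base class for all toolkit errors."""


class FormatError(CoexkitError):
    """A file does not conform to its declared dialect."""


class DataError(CoexkitError):
    """A structurally valid input carries unusable content."""


class ConfigError(CoexkitError):
    """A pipeline configuration is incomplete or inconsistent."""
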