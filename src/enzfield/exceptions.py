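"""Exception hierarchy for enzfield.

All library-raised errors derive from :class:`EnzfieldError` so callers can
catch the package's failures with a single except clause.
"""


class EnzfieldError(Exception):
    """Base class for all enzfield errors."""


class ParseError(EnzfieldError):
    """A file could not be parsed; the message names the offending line/frame."""


class SelectionError(EnzfieldError):
    """A selection expression did not resolve against the topology."""


class SingularityError(EnzfieldError):
    """An environment charge coincides with the evaluation point."""


class DegenerateGeometryError(EnzfieldError):
    """A probe vector has (near-)zero length in some frame."""


class FrontierUndefinedError(EnzfieldError):
    """Orbital data has no occupied or no virtual orbital."""


class ConfigurationError(EnzfieldError):
    """Inconsistent inputs (overlapping selections, bad spec, bad config)."""


class DegenerateDistributionError(EnzfieldError):
    """A sample has zero variance where a spread is required (e.g. KDE)."""
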