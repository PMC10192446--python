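"""Exception hierarchy for the scaffold-counting pipeline.

Each pipeline stage raises a distinct class so batch drivers can tell a
malformed input file from an impossible sampling geometry.
"""


class ScaffoldCountError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(ScaffoldCountError):
    """A scaffold / column / render specification violates its invariants."""


class GeometryError(ScaffoldCountError):
    """Sampling geometry cannot be realized (fields do not fit, shapes clash)."""


class OutOfBoundsError(GeometryError):
    """A sampled column does not lie inside the scaffold extent."""


class FormatError(ScaffoldCountError):
    """An image or table file is not in the expected on-disk format."""


class ConfigError(ScaffoldCountError):
    """A run/feature configuration is inconsistent or incomplete."""


class ReadingError(ScaffoldCountError):
    """A physically impossible instrument reading (e.g. negative displacement)."""


class AnalysisError(ScaffoldCountError):
    """A statistical operation received data it cannot analyze."""
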