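"""Exception hierarchy shared across the pipeline.

The CLI maps :class:`ConfigError` to exit code 2 and :class:`DataError`
to exit code 3; everything else is a bug.
"""


class RoadPMError(Exception):
    """Base class for all package errors."""


class ConfigError(RoadPMError):
    """Invalid configuration: bad labels, degenerate extents, bad thresholds."""


class DataError(RoadPMError):
    """Invalid or inconsistent data: geometry problems, missing columns."""


class GridMismatchError(DataError):
    """An artifact was built on a different grid than the one supplied."""


class OutsideDomainError(DataError):
    """A point or geometry falls outside the analysis domain."""


class MetricError(RoadPMError):
    """A metric is undefined for the given inputs (e.g. zero population)."""
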