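"""Exception hierarchy.

Data-level problems (malformed files, impossible day compositions) raise
subclasses of :class:`DataError`; configuration and scenario problems raise
subclasses of :class:`ConfigError`.  The CLI maps these onto exit codes 1
and 2 respectively.
"""


class ActihfError(Exception):
    """Base class for all package errors."""


class DataError(ActihfError):
    """A problem with input data."""


class FormatError(DataError):
    """Malformed input file (missing column, bad units declaration, ...)."""


class OrderingError(DataError):
    """Timestamps out of order in a raw stream."""


class IntegrityError(DataError):
    """A structural contract violated (wrong epoch count, bad day mix)."""


class EstimationError(DataError):
    """A regression cannot be estimated (aliased term, empty arm, ...)."""


class SequencingError(DataError):
    """Model-building steps requested out of order."""


class ConfigError(ActihfError):
    """Invalid run configuration."""


class ScenarioError(ConfigError):
    """Invalid or infeasible synthetic-data scenario."""
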