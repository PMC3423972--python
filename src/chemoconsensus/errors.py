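"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: configuration/parameter problems exit
with 2, data/format problems with 3.
"""


class ChemoConsensusError(Exception):
    """Base class for all package errors."""


class ParameterError(ChemoConsensusError, ValueError):
    """Invalid parameter value (bad shape, fraction out of range, unknown name)."""


class ConfigError(ParameterError):
    """Invalid run configuration (missing/conflicting fields)."""


class FormatError(ChemoConsensusError, ValueError):
    """Malformed input file; message names the offending line where possible."""


class StateError(ChemoConsensusError, ValueError):
    """Operation applied to an object in the wrong state (e.g. double transform)."""


class ConsistencyError(ChemoConsensusError, ValueError):
    """Mismatched objects passed together (e.g. dendrogram leaves vs matrix rows)."""


class IdentifierError(ChemoConsensusError, KeyError):
    """A referenced identifier is absent from the data."""
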