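"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: :class:`ConfigError` -> 2,
:class:`DataError` -> 3.  :class:`InputError` subclasses ``ValueError`` so
library callers that validate arguments themselves keep working.
"""


class ScpqbError(Exception):
    """Base class for all package errors."""


class InputError(ScpqbError, ValueError):
    """An operation was called with arguments that violate its contract."""


class ConfigError(ScpqbError):
    """A configuration file or dialect map is invalid or unknown."""


class DataError(ScpqbError):
    """Input data violate a structural requirement (missing column, duplicates...)."""
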