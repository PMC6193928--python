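"""Exception hierarchy shared across the pipeline."""


class DriftwatchError(Exception):
    """Base class for all driftwatch errors."""


class InvalidParameterError(DriftwatchError):
    """A parameter violates its documented domain (e.g. negative spacing)."""


class InsufficientDataError(DriftwatchError):
    """Not enough observations to carry out the requested estimation."""


class IngestError(DriftwatchError):
    """A fatal problem with an input file (missing column, duplicate key...)."""
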