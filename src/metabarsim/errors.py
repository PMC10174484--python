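"""Exception types shared across metabarsim."""


class InvalidParameterError(ValueError):
    """A parameter violates its documented domain (e.g. negative concentration)."""


class DegenerateReplicateError(RuntimeError):
    """Every amplicon count in a replicate is zero, so read proportions are undefined."""


class TableValidationError(ValueError):
    """A read table or input table violates its schema; message names offending rows."""


class EmptyInputError(ValueError):
    """An operation that needs at least one record received none."""
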