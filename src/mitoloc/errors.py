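"""Structured exceptions raised across the pipeline."""


class MitolocError(Exception):
    """Base class for all package errors."""


class ConfigError(MitolocError):
    """Invalid or incomplete configuration."""


class PlacementError(MitolocError):
    """Rejection sampling could not place a cell in a crowded field."""

    def __init__(self, field_id: str, attempts: int):
        self.field_id = field_id
        self.attempts = attempts
        super().__init__(
            f"could not place a non-overlapping cell in field {field_id!r} "
            f"after {attempts} attempts"
        )


class ShapeMismatchError(MitolocError):
    """Arrays that must share a shape do not."""


class EmptyStackError(MitolocError):
    """A z-stack with zero planes was supplied."""


class UndefinedCorrelationError(MitolocError):
    """Pearson correlation is undefined (zero variance in a channel)."""


class EmptyConditionError(MitolocError):
    """A condition produced no analyzable cells."""

    def __init__(self, condition: str, detail: str = ""):
        self.condition = condition
        msg = f"condition {condition!r} has no analyzable cells"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)
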