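"""Exception hierarchy shared across the pipeline."""


class IsletViewError(Exception):
    """Base class for all package errors."""


class FormatError(IsletViewError):
    """A file violates its documented format or an invariant on read."""


class ConfigError(IsletViewError):
    """An infeasible or inconsistent configuration."""


class NotFoundError(IsletViewError):
    """A requested gene/sample/file is absent from the relevant universe."""


class AmbiguityError(IsletViewError):
    """A query matched more than one record."""

    def __init__(self, message: str, candidates: list[str] | None = None):
        super().__init__(message)
        self.candidates = candidates or []


class EmptyDatasetError(IsletViewError):
    """A filter removed every sample or gene."""
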