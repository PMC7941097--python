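"""Exception hierarchy for the ISA-Tab streaming writer."""


class IsaTabError(Exception):
    """Base class for all errors raised by this package."""


class InvalidArgumentError(IsaTabError, ValueError):
    """A constructor or operation received an argument violating a model invariant."""


class DuplicateAttributeError(IsaTabError, ValueError):
    """An attribute with the same (kind, category) already exists on the entity."""


class RoleError(IsaTabError, ValueError):
    """An attribute kind is not permitted on this node role (e.g. a factor value on a source)."""


class StructureError(IsaTabError, ValueError):
    """A row chain or investigation block violates structural invariants."""


class RowStructureError(StructureError):
    """A row's derived column layout differs from the frozen header signature."""

    def __init__(self, message: str, column_index: int | None = None):
        super().__init__(message)
        self.column_index = column_index


class StreamStateError(IsaTabError, RuntimeError):
    """An operation was applied to a table stream in the wrong state (e.g. double finish)."""


class ValidationError(IsaTabError, ValueError):
    """An investigation failed a fatal pre-serialization check (e.g. duplicate filenames)."""
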