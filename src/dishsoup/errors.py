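"""Exception hierarchy."""


class DishSoupError(Exception):
    """Base class for all package errors."""


class ParseError(DishSoupError):
    """Malformed textual or JSON input; carries position info when available."""

    def __init__(self, message: str, pos: int | None = None):
        super().__init__(message if pos is None else f"{message} (at offset {pos})")
        self.pos = pos


class ValidationError(DishSoupError):
    """A knowledge base or rule violates a structural invariant."""


class SortViolation(DishSoupError):
    """A substitution binds a variable to a term outside the variable's sort."""


class UnknownSortError(DishSoupError):
    """A sort name is not declared in the hierarchy."""


class RestrictionViolation(DishSoupError):
    """A pattern breaks the supported fragment (e.g. two soup variables in one soup)."""


class StaleSolutionError(DishSoupError):
    """A search solution no longer replays against its knowledge base."""
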