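"""Structured errors raised across the package."""


class RabswitchError(Exception):
    """Base class for all package errors."""


class InvalidSlotError(RabswitchError):
    """A slot constraint or choice index does not exist in the library."""

    def __init__(self, slot: str, index, n_alternatives: int):
        self.slot = slot
        self.index = index
        self.n_alternatives = n_alternatives
        super().__init__(
            f"slot {slot!r}: choice index {index!r} is not valid "
            f"(library offers {n_alternatives} alternatives)"
        )


class MissingParameterError(RabswitchError):
    """A parameter required by a compiled structure was not supplied."""

    def __init__(self, names):
        self.names = tuple(names)
        super().__init__(f"missing parameter(s): {', '.join(self.names)}")


class DatasetError(RabswitchError):
    """A dataset violates a structural requirement (monotone times, ...)."""


class ParseError(RabswitchError):
    """A measurement file could not be parsed."""

    def __init__(self, path, line_number: int, message: str):
        self.path = path
        self.line_number = line_number
        super().__init__(f"{path}:{line_number}: {message}")


class CriterionError(RabswitchError):
    """A selection criterion was mis-specified or not computable."""


class FitError(RabswitchError):
    """Parameter estimation could not be run as configured."""
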