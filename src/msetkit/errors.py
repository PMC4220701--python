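"""Exception hierarchy shared across the pipeline stages."""


class MsetkitError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(MsetkitError, ValueError):
    """A synthetic-data specification violates its invariants."""


class InvalidInputError(MsetkitError, ValueError):
    """An input object (matrix, gene set, table) violates a precondition."""


class InvalidDesignError(MsetkitError, ValueError):
    """An experimental design cannot support the requested analysis."""


class GmtParseError(MsetkitError, ValueError):
    """A GMT file line could not be parsed.

    Carries the 1-based line number of the offending line.
    """

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number
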