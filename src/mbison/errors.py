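"""Exception hierarchy shared across the package."""


class MbisonError(Exception):
    """Base class for all package-specific errors."""


class TableFormatError(MbisonError):
    """A tabular input file is malformed; ``line`` is the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class EmptyBackgroundError(MbisonError):
    """No (family, gene) prediction pairs survived to form a background."""


class GeneSetSizeError(MbisonError):
    """The background-restricted gene set size N falls outside the run bounds."""

    def __init__(self, n: int, message: str):
        self.n = n
        super().__init__(message)


class GeneSetTooSmallError(GeneSetSizeError):
    def __init__(self, n: int, min_n: int):
        super().__init__(n, f"gene set too small: N={n} < {min_n}")


class GeneSetTooLargeError(GeneSetSizeError):
    def __init__(self, n: int, max_n: int):
        super().__init__(n, f"gene set too large: N={n} > {max_n}")


class BedError(MbisonError):
    """A BED peak file could not be parsed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
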