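"""Exception hierarchy for snpbarcode."""


class SnpBarcodeError(Exception):
    """Base class for all package errors."""


class GenotypeParseError(SnpBarcodeError):
    """Raised when a genotype file or cell cannot be interpreted."""


class ZeroCellError(SnpBarcodeError):
    """A 2x2 cell required to be positive is zero (infinite/undefined OR or CI)."""


class DegenerateTableError(SnpBarcodeError):
    """A 2x2 margin is zero or a proportion is degenerate; the statistic is undefined."""


class InfeasibleSpecError(SnpBarcodeError):
    """A synthetic-data specification cannot be realized."""


class SearchSpaceError(SnpBarcodeError):
    """Exhaustive enumeration refused because the model space exceeds the guard."""
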