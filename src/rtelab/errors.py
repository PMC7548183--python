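"""Exception hierarchy shared across the package."""


class RTEError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(RTEError):
    """A configuration problem: missing column mapping, bad grouping key,
    inconsistent simulation design, out-of-range tuning parameter."""


class DataError(RTEError):
    """Invalid data content. Carries row-addressed diagnostics when the
    problem was found while reading a file."""

    def __init__(self, message, rows=None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []


class UndefinedScoreError(DataError):
    """A per-individual score (herbivory) is undefined, e.g. no leaves."""


class UndefinedRGRError(DataError):
    """Relative growth rate undefined: fewer than two usable measurements."""


class EstimabilityError(RTEError):
    """A requested model term or adjusted-mean cell is not estimable from
    the observed design."""


class FitError(RTEError):
    """Model fitting failed (non-convergence, non-identifiability)."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace
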