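"""Exception hierarchy shared across the package."""


class StomascaleError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(StomascaleError):
    """An input table is missing mandatory columns or is otherwise malformed."""


class ValidationError(StomascaleError):
    """Rows of an input table violate field invariants.

    Carries the offending row numbers (1-based, header excluded) in ``rows``.
    """

    def __init__(self, message, rows=None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []


class InsufficientDataError(StomascaleError):
    """Too few observations for the requested statistic."""


class DegenerateFitError(StomascaleError):
    """Zero variance (or another degeneracy) makes a fit undefined."""


class UnresolvedEquationError(StomascaleError):
    """No allometric equation found for a species at any fallback level."""


class CoverageError(StomascaleError):
    """Trait coverage of the community's LAI falls below the required fraction."""
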