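"""Exception hierarchy for ccekit.

All pipeline errors derive from :class:`CcekitError` so callers can catch
one base class at CLI boundaries while tests assert on specific subclasses.
"""


class CcekitError(Exception):
    """Base class for all ccekit errors."""


class ConfigError(CcekitError, ValueError):
    """A simulation or model configuration field is invalid.

    The message always names the offending field.
    """


class FormatError(CcekitError, ValueError):
    """A delimited input file is structurally wrong (e.g. missing column)."""


class ValidationError(CcekitError, ValueError):
    """Row-level content is invalid; the message lists offending rows."""


class DegenerateInstitutionError(CcekitError, ValueError):
    """All of an institution's sampled curative income is preventive, so the
    sharing coefficient denominator a - a_p is zero and allocation is
    undefined."""


class LedgerError(CcekitError, ValueError):
    """An institution ledger violates its invariants (e.g. S_P_ALL > ST_ALL)."""


class LookupError_(CcekitError, KeyError):
    """A record references an institution with no ledger entry."""


class UnknownDimensionError(CcekitError, ValueError):
    """A grouping dimension is not available; message lists valid ones."""


class ConstantColumnError(CcekitError, ValueError):
    """A column has zero variance and cannot be standardized."""


class UnknownCategoryError(CcekitError, ValueError):
    """A category absent from the fitted encoding appeared at transform time."""


class UndefinedMetricError(CcekitError, ValueError):
    """A requested metric is undefined for the given inputs (e.g. R^2 when
    the outcome has zero variance, proportions when all totals are zero)."""


class EmptyDatasetError(CcekitError, ValueError):
    """Cleaning removed every record."""


class FitError(CcekitError, RuntimeError):
    """Model training failed (non-finite loss or too many restart failures)."""
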