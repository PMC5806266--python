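"""Exception hierarchy for enzkin.

All domain errors derive from :class:`EnzkinError` so callers can catch one
base class; most also derive from ``ValueError`` because they signal invalid
inputs or contracts.
"""


class EnzkinError(Exception):
    """Base class for all enzkin errors."""


class InvalidParameterError(EnzkinError, ValueError):
    """A kinetic or model parameter violates its physical constraints."""


class EmptyInputError(EnzkinError, ValueError):
    """An operation received an empty dataset or grid."""


class InvalidModelError(EnzkinError, ValueError):
    """Model parameters are mutually inconsistent (e.g. pKa1 >= pKa2)."""


class InvalidSelectorError(EnzkinError, ValueError):
    """Unknown equation/profile selector, or selector/model mismatch."""


class InvalidDesignError(EnzkinError, ValueError):
    """Experimental design violates a protocol precondition (regime overlap,
    mismatched assay pH between jointly fitted profiles, ...)."""


class InvalidComparisonError(EnzkinError, ValueError):
    """Two results that must refer to the same condition do not."""


class FitError(EnzkinError, RuntimeError):
    """Nonlinear fit failed to converge or the data cannot constrain it.

    Carries ``diagnostics`` (a dict) with residual information when available.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class UnderdeterminedError(EnzkinError, ValueError):
    """Fewer observations than parameters."""


class InvalidRateError(EnzkinError, ValueError):
    """A rate constant is non-positive where positivity is required."""


class NegativeBarrierError(EnzkinError, ValueError):
    """Rate exceeds the assumed pre-exponential factor: the implied
    activation barrier would be negative."""


class SchemaError(EnzkinError, ValueError):
    """Tabular input does not conform to the declared dialect."""


class AlphabetError(EnzkinError, ValueError):
    """Sequence contains residues outside the accepted alphabet."""


class InfeasibleFixtureError(EnzkinError, ValueError):
    """A requested synthetic fixture cannot be constructed (motif planting)."""
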