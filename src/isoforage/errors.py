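"""Exception hierarchy for the pipeline.

All errors raised on bad user input derive from :class:`IsoforageError`
so callers (and the CLI) can catch one base class.
"""


class IsoforageError(Exception):
    """Base class for all package errors."""


class SchemaError(IsoforageError):
    """An input table is missing required columns."""


class ValidationError(IsoforageError):
    """A row or field violates a data-model invariant."""


class ConfigurationError(IsoforageError):
    """A configuration value is missing or inconsistent."""


class DegenerateFieldError(IsoforageError):
    """All observed values identical; a variogram cannot be fit.

    A pure-nugget model (flat surface, constant se) is the only sensible
    fallback and must be requested explicitly by the caller.
    """


class SingularKrigingError(IsoforageError):
    """The kriging system is singular (typically duplicate coordinates)."""


class EmptyCohortError(IsoforageError):
    """A year/cohort selection matched no individuals."""


class EmptyHotspotError(IsoforageError):
    """A hotspot polygon contains no grid-cell centers."""


class UnderflowError(IsoforageError):
    """All densities underflowed to zero (should not occur: densities are
    computed in log space)."""
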