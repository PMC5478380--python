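"""Exception hierarchy.

All package errors derive from :class:`NestnetError` so callers can catch
one base class; subclasses distinguish schema problems, invariant
violations, degenerate geometry and statistically undefined results.
"""


class NestnetError(Exception):
    """Base class for all nestnet errors."""


class SchemaError(NestnetError):
    """An input table is missing required columns or has the wrong shape."""


class ValidationError(NestnetError):
    """An input table violates a domain invariant (duplicates, bad values)."""


class InfeasibleConfigError(NestnetError):
    """A simulation scenario cannot be realised (e.g. packing too dense)."""


class DegenerateGeometryError(NestnetError):
    """Point configuration admits no valid tessellation (e.g. collinear)."""


class UndefinedStatisticError(NestnetError):
    """A statistic is undefined on the given input (zero variance, no edges)."""
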