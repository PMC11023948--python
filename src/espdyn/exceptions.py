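"""Exception hierarchy for espdyn.

Every error raised by the library derives from :class:`EspdynError`, so
callers (and the CLI) can catch one base class. Subclasses mirror the
failure modes of the pipeline stages: nomenclature lookups, matrix
validation, geometry handling and statistical preconditions.
"""


class EspdynError(Exception):
    """Base class for all espdyn errors."""


class NomenclatureError(EspdynError, KeyError):
    """An LULC class code or ecosystem-service code is not in the nomenclature."""

    def __str__(self) -> str:  # KeyError quotes its args; keep the message readable
        return Exception.__str__(self)


class MatrixCompletenessError(EspdynError):
    """A (class, service) cell required for a complete matrix is missing."""


class ScoreRangeError(EspdynError, ValueError):
    """An ESP score falls outside the admissible [5, 100] range."""


class FeasibilityError(EspdynError, ValueError):
    """Subclass score distribution cannot preserve the mean inside the bounds."""


class EmptyInputError(EspdynError, ValueError):
    """An operation received an empty mosaic, layer or record set."""


class AreaError(EspdynError, ValueError):
    """A patch area could not be resolved from geometry or attributes."""


class CoverageError(EspdynError, ValueError):
    """Two mosaics that must cover the same study area disagree in extent."""


class ModeError(EspdynError, ValueError):
    """A scoping mode was requested that the available data cannot support."""


class AlignmentError(EspdynError, ValueError):
    """City labels of two tables to be joined share no common entries."""


class InsufficientDataError(EspdynError, ValueError):
    """Fewer complete observation pairs than a statistic requires."""


class SpecError(EspdynError, ValueError):
    """A synthetic-scenario specification is invalid."""
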