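"""Exception hierarchy shared across the package.

Everything derives from :class:`NitracerError` so callers can catch the
package's failures with a single except clause; the subclasses distinguish
schema problems (bad file layout) from domain problems (values outside the
model's admissible range) from structural problems (cyclic path graphs,
mismatched distance-matrix labels).
"""


class NitracerError(ValueError):
    """Base class for all nitracer errors."""


class SchemaError(NitracerError):
    """A required column or table component is missing."""


class ParseError(NitracerError):
    """A cell could not be parsed as the required type."""


class DomainError(NitracerError):
    """A value violates a model invariant (negative SD, off-simplex p, ...)."""


class CompletenessError(NitracerError):
    """A source x isotope combination is absent from a signature table."""


class CoverageError(NitracerError):
    """A source grouping does not cover the posterior's sources exactly."""


class AlignmentError(NitracerError):
    """Two labelled matrices do not share the same label set."""


class GraphCycleError(NitracerError):
    """A directed edge set that must be acyclic contains a cycle."""


class ConditioningError(NitracerError):
    """A regression design matrix is numerically singular."""


class InitializationError(NitracerError):
    """The MCMC sampler could not find a finite-posterior starting point."""
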