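"""Exception hierarchy.

All library errors derive from :class:`RfckaError` so callers can catch one
base class; most also derive from ``ValueError`` because they signal invalid
inputs rather than internal failures.
"""


class RfckaError(Exception):
    """Base class for all errors raised by this package."""


class InvalidInputError(RfckaError, ValueError):
    """Non-finite, malformed, or out-of-contract input data."""


class InvalidParameterError(RfckaError, ValueError):
    """A configuration parameter outside its valid range."""


class DimensionMismatchError(RfckaError, ValueError):
    """Two objects that must agree on a dimension do not."""


class AlignmentError(RfckaError, ValueError):
    """Sample identifiers of paired inputs do not match."""


class DegenerateLabelsError(RfckaError, ValueError):
    """A classifier was asked to fit labels containing a single class."""


class DegenerateRepresentationError(RfckaError, ValueError):
    """A Gram matrix with zero self-HSIC (e.g. constant kernel) was passed
    where a non-degenerate representation is required.  Raised instead of
    silently returning 0, which would masquerade as independence."""


class InvalidModelError(RfckaError, ValueError):
    """A model object violates its structural contract (e.g. empty forest)."""


class ComplexityCapError(RfckaError, ValueError):
    """Exhaustive enumeration was requested for a forest whose number of
    (tree, depth) pairs exceeds the configured cap."""


class ContractViolationError(RfckaError, RuntimeError):
    """A learner declared deterministic produced different predictions from
    two identical fits."""


class InsufficientDataError(RfckaError, ValueError):
    """Too few observations or model pairs for the requested statistic."""


class EmptyInputError(RfckaError, ValueError):
    """An input file or record stream contained no usable records."""
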