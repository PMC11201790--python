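"""Exception hierarchy shared across the toolkit."""


class SSRKitError(Exception):
    """Base class for all ssrkit errors."""


class InvalidAlphabetError(SSRKitError):
    """A sequence contains characters outside {A, C, G, T}."""


class InvalidMotifError(SSRKitError):
    """A motif is empty or is itself a repetition of a shorter unit."""


class EmptyInputError(SSRKitError):
    """An operation received an empty sequence or table."""


class DegenerateInputError(SSRKitError):
    """Input is structurally valid but degenerate (e.g. zero genome length)."""


class CoordinateError(SSRKitError):
    """Locus coordinates fall outside the template they refer to."""


class InsufficientDataError(SSRKitError):
    """Too few typed individuals / observations to compute a statistic."""


class ConsistencyError(SSRKitError):
    """Cross-references between tables do not resolve (unknown IDs etc.)."""


class ValidationError(SSRKitError):
    """A matrix, tree, config or spec violates its invariants."""


class PlacementError(SSRKitError):
    """Planted loci cannot be placed under the spacing constraints."""


class ParseError(SSRKitError):
    """A text table or config file is malformed; message names line/column."""
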