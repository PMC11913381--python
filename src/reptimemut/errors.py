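"""Exception hierarchy shared across the package."""


class ReptimeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ReptimeError, ValueError):
    """Malformed input file or record."""


class UnknownChromosomeError(ReptimeError, KeyError):
    """A chromosome name is absent from the genome or timing map."""


class DomainError(ReptimeError, ValueError):
    """An argument lies outside the operation's mathematical domain."""


class DegenerateMapError(DomainError):
    """Timing map cannot be partitioned (e.g. all times identical)."""


class RefMismatchError(ReptimeError, ValueError):
    """A mutation record's reference allele disagrees with the genome."""


class NoInformationError(DomainError):
    """A statistical test has no informative data (e.g. all paired
    differences are zero)."""


class UndefinedSimilarityError(DomainError):
    """Similarity requested for a zero or constant vector."""
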