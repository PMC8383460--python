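"""Exception hierarchy.

Every error raised by the library derives from :class:`PhenomineError` so
callers can catch library failures without masking programming errors.
"""


class PhenomineError(Exception):
    """Base class for all phenomine errors."""


class CyclicHierarchyError(PhenomineError):
    """The subclass relation contains a cycle; it must be a DAG."""


class UnknownClassError(PhenomineError, KeyError):
    """A class id was referenced that does not exist in the ontology."""


class MappingParseError(PhenomineError):
    """A cross-terminology mapping row is malformed."""


class EmptyCorpusError(PhenomineError):
    """No usable documents (or walks) were supplied."""


class InconsistentCountsError(PhenomineError):
    """Co-occurrence counts violate their own invariants (e.g. joint > marginal)."""


class InvalidThresholdError(PhenomineError):
    """A rank threshold below 1 was requested."""


class ZeroNormError(PhenomineError):
    """Cosine similarity of a zero vector is undefined."""


class UndefinedAUCError(PhenomineError):
    """ROC AUC needs at least one positive and one negative example."""


class UndefinedMetricError(PhenomineError):
    """Precision/recall are undefined on empty prediction or gold sets."""
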