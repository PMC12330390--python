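"""Exception hierarchy shared across the pipeline stages."""


class SodalakeError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(SodalakeError, ValueError):
    """An argument violates a documented precondition."""


class InvalidMetadataError(SodalakeError, ValueError):
    """Sample metadata is incomplete or inconsistent (e.g. a sample without a region)."""


class InsufficientDataError(SodalakeError, ValueError):
    """Too few usable observations for the requested statistic."""


class UndefinedDistanceError(SodalakeError, ValueError):
    """A dissimilarity is undefined for the given inputs (e.g. two all-zero vectors)."""


class InvalidTreeError(SodalakeError, ValueError):
    """A phylogeny violates a structural requirement (labels, branch lengths)."""


class DependencyError(SodalakeError, RuntimeError):
    """A pipeline stage is missing an input another stage should have produced."""
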