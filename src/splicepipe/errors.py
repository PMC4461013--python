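"""Exception hierarchy shared by all pipeline stages."""


class SplicePipeError(Exception):
    """Base class for all errors raised by this package."""


class InputError(SplicePipeError):
    """A required input file is missing or unreadable."""


class FormatError(SplicePipeError):
    """A record in an input file violates its format contract."""


class EmptyAnnotationError(SplicePipeError):
    """A GTF contained no exon features."""


class OverlappingExonsError(FormatError):
    """A transcript's exons overlap; the combinatorics require disjoint exons."""


class SequenceSourceError(SplicePipeError):
    """A chromosome is missing from the genome, or a flank runs off its end."""


class ConsistencyError(SplicePipeError):
    """Alignments disagree with the library/annotation they claim to target."""


class NormalizationError(SplicePipeError):
    """Size factors cannot be computed (no feature positive in every sample)."""


class DesignError(SplicePipeError):
    """A differential design is invalid (fewer than two conditions, ...)."""


class ZeroMarginError(SplicePipeError):
    """A contingency table has a zero margin and cannot be tested."""


class ConfigError(SplicePipeError):
    """A simulator or pipeline configuration is infeasible."""
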