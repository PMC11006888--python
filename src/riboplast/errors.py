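"""Exception hierarchy for the riboplast pipeline.

Every fatal condition raises a subclass of :class:`RiboplastError`, so the CLI
can catch one type, report module context, and exit non-zero.
"""


class RiboplastError(Exception):
    """Base class for all riboplast errors."""


class AnnotationError(RiboplastError):
    """Problem in the genome FASTA or ORF annotation (GFF3)."""


class FootprintError(RiboplastError):
    """Problem in a footprint interval file (BED6)."""


class SampleSheetError(RiboplastError):
    """Problem in the sample sheet."""


class SimulationError(RiboplastError):
    """Invalid simulation configuration or layout."""


class QCError(RiboplastError):
    """QC statistic cannot be computed (e.g. no usable footprints)."""


class QuantError(RiboplastError):
    """Quantification failure (e.g. empty sample)."""


class ProfileError(RiboplastError):
    """Coverage-profile failure (e.g. normalising a zero-coverage profile)."""


class ConfigError(RiboplastError):
    """Invalid pipeline configuration."""
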