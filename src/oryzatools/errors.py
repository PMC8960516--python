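"""Exception hierarchy shared across the toolkit.

Exit-code mapping (see :mod:`oryzatools.cli`): configuration/usage problems
exit 2, malformed input files exit 3, analysis failures exit 4.
"""


class OryzaError(Exception):
    """Base class for all toolkit errors."""


class ConfigError(OryzaError):
    """Invalid scenario or run configuration."""


class CoordinateError(OryzaError):
    """Interval or coordinate out of bounds / inverted."""


class AlphabetError(OryzaError):
    """Sequence contains characters outside the accepted alphabet."""


class AlignmentError(OryzaError):
    """Pairwise alignment could not be computed or is degenerate."""


class ModelError(OryzaError):
    """Gene model violates its structural invariants."""


class FormatError(OryzaError):
    """Malformed input file (FASTA/GFF3/TSV)."""


class AnalysisError(OryzaError):
    """A pipeline stage failed on valid inputs."""
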