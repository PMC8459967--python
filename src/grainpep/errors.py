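"""Exception hierarchy shared across the package."""


class GrainpepError(Exception):
    """Base class for all package-specific errors."""


class AlignmentFormatError(GrainpepError, ValueError):
    """Malformed alignment input (ragged records, unparsable dialect)."""


class AlphabetError(GrainpepError, ValueError):
    """A sequence contains letters outside the accepted residue alphabet."""


class ConfigError(GrainpepError, ValueError):
    """Unknown configuration key or value outside its documented bounds."""


class EmptyConsensusError(GrainpepError, ValueError):
    """Every alignment column was gap-majority; no consensus exists."""


class GenerationError(GrainpepError, RuntimeError):
    """Synthetic-data constraints could not be satisfied."""


class PipelineError(GrainpepError, RuntimeError):
    """A pipeline stage failed; message names the stage and offending record."""
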