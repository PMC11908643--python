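"""Exception hierarchy for ssblend.

All errors derive from :class:`SsblendError` so callers can catch the
package's failures with one clause; most also derive from the builtin
they most resemble (``ValueError``/``KeyError``) so generic handling
keeps working.
"""


class SsblendError(Exception):
    """Base class for all ssblend errors."""


class FormatError(SsblendError, ValueError):
    """A genotype/phenotype file could not be parsed."""


class AlignmentError(SsblendError, ValueError):
    """Genotype and phenotype sample IDs share fewer than two samples."""


class SizeError(SsblendError, ValueError):
    """A split or sample size is degenerate (empty/oversized partition)."""


class DegeneratePhenotypeError(SsblendError, ValueError):
    """The phenotype is constant and cannot be stratified or scored."""


class ConstantInputError(SsblendError, ValueError):
    """Pearson correlation is undefined because an input is constant."""


class SimulationError(SsblendError, RuntimeError):
    """Phenotype simulation failed (e.g. every sampled QTN monomorphic)."""


class LearnerError(SsblendError, RuntimeError):
    """A base learner failed to fit; the message names the learner."""


class TuningError(SsblendError, RuntimeError):
    """Holdout-rate tuning could not score any grid value."""
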