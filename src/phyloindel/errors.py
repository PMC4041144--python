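"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`PhyloindelError` so callers can
distinguish pipeline failures from programming errors.
"""


class PhyloindelError(Exception):
    """Base class for all pipeline errors."""


# --- io_formats ---------------------------------------------------------
class AlignmentRaggedError(PhyloindelError):
    """Records in an alignment do not share the same length."""


class AlphabetError(PhyloindelError):
    """A sequence contains characters outside the allowed alphabet."""


class EmptyGroupError(PhyloindelError):
    """A consensus was requested for an empty group of individuals."""


class OutgroupNotFoundError(PhyloindelError):
    """The declared outgroup label is not among the tree tips."""


class FormatError(PhyloindelError):
    """A file could not be parsed in its declared format."""


class UnitError(PhyloindelError):
    """A phenotype value violates its unit constraints (mass, percentage)."""


# --- indel_coding -------------------------------------------------------
class AlignmentDegenerateError(PhyloindelError):
    """An alignment column is gapped in every taxon."""


class FrameError(PhyloindelError):
    """An ungapped sequence length is not a multiple of three."""


# --- indel_events -------------------------------------------------------
class InvariantCharacterError(PhyloindelError):
    """An indel character has the same state in every observed taxon."""


# --- codon_evolution ----------------------------------------------------
class StopCodonError(PhyloindelError):
    """An internal stop codon was found in a coding sequence."""


class ConvergenceError(PhyloindelError):
    """A likelihood optimisation failed to converge."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class OptimizationOrderError(PhyloindelError):
    """A nested null model obtained a higher likelihood than its alternative."""


class ModelMismatchError(PhyloindelError):
    """An operation was requested on a model fit that does not support it."""


# --- comparative_stats --------------------------------------------------
class DegenerateVarianceError(PhyloindelError):
    """A descriptor submitted to PCA has zero variance."""


class CollinearityError(PhyloindelError):
    """The regression design matrix is singular."""


class SampleSizeError(PhyloindelError):
    """Too few observations for the requested statistic."""


# --- residue_stats ------------------------------------------------------
class CoordinateError(PhyloindelError):
    """Site coordinates do not match between two inputs."""


# --- pipeline -----------------------------------------------------------
class PipelineDependencyError(PhyloindelError):
    """A pipeline stage was run before its upstream dependency."""


class ConfigError(PhyloindelError):
    """A run configuration failed validation."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


# --- synthetic_data -----------------------------------------------------
class SimulationDegenerateError(PhyloindelError):
    """Simulation parameters produced a degenerate dataset."""
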