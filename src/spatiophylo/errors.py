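"""Exception types shared across the package."""


class SpatioPhyloError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SpatioPhyloError):
    """A file could not be parsed in the declared dialect."""


class IntegrityError(SpatioPhyloError):
    """Input violates a structural invariant (duplicates, bad labels)."""


class DefinitionError(SpatioPhyloError):
    """A metric definition references unknown features or is malformed."""


class DegenerateInputError(SpatioPhyloError):
    """Input is formally valid but statistically degenerate (e.g. zero variance)."""


class AlignmentError(SpatioPhyloError):
    """Taxa do not line up across response, covariates and covariance structures."""


class NumericalError(SpatioPhyloError):
    """A numerical operation failed beyond the allowed jitter/tolerance."""
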