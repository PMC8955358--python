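"""Exception hierarchy shared across cytobench modules."""


class CytobenchError(Exception):
    """Base class for all cytobench-specific errors."""


class InvalidModelError(CytobenchError, ValueError):
    """A cluster model violates its invariants (e.g. non-SPD covariance)."""


class DegenerateGeometryError(CytobenchError, ValueError):
    """Geometry makes the requested quantity undefined (coincident means,
    rank-deficient point cloud)."""


class DegenerateInputError(CytobenchError, ValueError):
    """Input data carries no information for the statistic (e.g. constant
    values passed to a skewness estimator)."""


class BracketError(CytobenchError, RuntimeError):
    """A root-bracketing search could not enclose the target value."""


class GenerationFailure(CytobenchError, RuntimeError):
    """A dataset could not be realised under the requested constraints."""


class FormatError(CytobenchError, ValueError):
    """A file violates the format rule named in the message."""


class UnsupportedFeatureError(CytobenchError, ValueError):
    """The file is valid but uses a feature outside the supported subset."""


class ConsistencyError(CytobenchError, ValueError):
    """Two paired artefacts (events vs. labels/assignments) disagree."""


class DegenerateFitError(CytobenchError, RuntimeError):
    """A model fit collapsed (singular covariance in every restart)."""
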