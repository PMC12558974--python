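"""Exception hierarchy shared across the pipeline stages."""


class HairSentinelError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HairSentinelError):
    """Invalid generation or pipeline configuration."""


class DomainError(HairSentinelError, ValueError):
    """An input value violates a documented domain bound."""


class ImputationError(HairSentinelError):
    """A field cannot be imputed (e.g. fully missing)."""


class EncodingError(HairSentinelError):
    """A value cannot be encoded under the active encoding spec."""


class ScalingError(HairSentinelError):
    """Feature scaling is impossible (e.g. zero-variance z-score column)."""


class BalancingError(HairSentinelError):
    """Class balancing preconditions are not met."""


class FittingError(HairSentinelError):
    """A model fit failed (e.g. rank-deficient design)."""


class RefinementError(HairSentinelError):
    """EM refinement preconditions are not met."""


class LookupError_(HairSentinelError, LookupError):
    """A required table entry (e.g. RDA) is missing."""


class ContractError(HairSentinelError):
    """Caller violated an interface contract (names, shapes, alignment)."""


class ClusteringError(HairSentinelError):
    """Clustering preconditions are not met."""


class TrainingError(HairSentinelError):
    """Model training failed (e.g. NaN loss)."""


class PipelineStageError(HairSentinelError):
    """Wraps a failure with the name of the pipeline stage that raised it."""

    def __init__(self, stage: str, original: BaseException):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage '{stage}' failed: {original!r}")
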