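"""Exception hierarchy for the lamellae package."""


class LamellaeError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(LamellaeError, ValueError):
    """A material or model parameter is outside its physical domain."""


class InvalidRotationError(LamellaeError, ValueError):
    """A matrix passed as a rotation is not proper orthogonal."""


class InvalidAngleError(LamellaeError, ValueError):
    """An indentation/fibril angle is outside [0, 90] degrees."""


class InfeasibleCompositionError(LamellaeError, ValueError):
    """A mass/weight fraction exceeds its stoichiometric bound."""


class CalibrationDomainError(LamellaeError, ValueError):
    """Input to the mineral-density calibration lies outside its valid branch."""


class InfeasiblePartitionError(LamellaeError, ValueError):
    """A mineral/fibril partition leaves a phase fraction outside [0, 1]."""


class DegenerateMaterialError(LamellaeError, ValueError):
    """A homogenization step produced (or received) a zero-stiffness phase."""

class NumericalConditioningError(LamellaeError, ArithmeticError):
    """A concentration-tensor system is numerically singular."""


class InvalidMaterialError(LamellaeError, ValueError):
    """A stiffness tensor is not positive definite."""


class QuadratureError(LamellaeError, ArithmeticError):
    """Angular quadrature failed to reach the requested accuracy."""


class RegistrationDomainError(LamellaeError, ValueError):
    """Images to be registered do not overlap under the initial transform."""


class UninformativeImageError(LamellaeError, ValueError):
    """The image overlap has no contrast; registration is ill-posed."""


class NoDataError(LamellaeError, ValueError):
    """A sampling region contains no valid (masked-in) pixels."""


class PlacementError(LamellaeError, ValueError):
    """An indent pattern does not fit inside the raster extent."""


class UndefinedCorrelationError(LamellaeError, ValueError):
    """Correlation requested for a constant (zero-variance) input."""


class DegenerateGroupError(LamellaeError, ValueError):
    """A statistical group is too small or constant for the requested test."""


class PipelineStageError(LamellaeError, RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
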