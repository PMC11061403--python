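"""Exception types shared across the package."""


class CtmaugError(Exception):
    """Base class for all package-specific errors."""


class NoConvergence(CtmaugError):
    """A root finder or fixed-point iteration failed to converge."""


class MultipleRoots(UserWarning):
    """More than one steady state was bracketed; the lowest-V_e root is used."""


class InfeasibleGains(CtmaugError):
    """No connection-strength set with the admissible sign pattern reproduces the gains."""


class Instability(CtmaugError):
    """The linearized corticothalamic system is unstable for these parameters."""


class ConfigError(CtmaugError):
    """Inconsistent simulation or fitting configuration."""


class DegenerateSignal(CtmaugError):
    """A signal with no power was passed where power is required."""


class TooShort(CtmaugError):
    """Signal shorter than one epoch."""


class LengthMismatch(CtmaugError):
    """Arrays that must share a length do not."""


class NyquistViolation(CtmaugError):
    """Requested band edge at or above the Nyquist frequency."""


class ShapeMismatch(CtmaugError):
    """Array dimensions incompatible with the model being applied."""


class ClassMissing(CtmaugError):
    """An operation requiring both condition labels saw only one."""


class SingularCovariance(CtmaugError):
    """Covariance matrix singular even after regularization."""


class EmptyCondition(CtmaugError):
    """A condition present in the ground truth has no trials."""


class DegenerateInput(UserWarning):
    """Degenerate input (e.g. a constant signal) handled by a defined fallback."""


class TooManyUnstableDraws(CtmaugError):
    """Jittered parameter draws kept failing the stability screen."""


class CountMismatch(CtmaugError):
    """Generated epoch counts differ across CSP sources of one condition."""


class TooFewEpochs(CtmaugError):
    """Not enough epochs per condition for the requested fold count."""


class NoStableInit(CtmaugError):
    """Could not draw a stable MCMC chain initialization from the prior box."""


class FormatError(CtmaugError):
    """A persisted container is missing a required field."""
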