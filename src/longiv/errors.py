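"""Shared exception and warning types."""


class LongIVError(Exception):
    """Base class for all estimation errors raised by this package."""


class DegenerateFitError(LongIVError):
    """A nuisance regression could not be fitted (constant response, separation,
    or a singular information matrix)."""


class WeakInstrumentError(LongIVError):
    """The instrument-residual cross-product matrix is numerically singular."""


class NonConvergenceError(LongIVError):
    """The weighted least-squares solve for the marginal structural model failed
    (singular normal matrix or degenerate weights)."""


class InferenceError(LongIVError):
    """Bootstrap inference is unreliable (too many failed resamples)."""


class DiagnosticsError(LongIVError):
    """A diagnostic quantity is undefined on the supplied data."""


class InstabilityWarning(UserWarning):
    """Compliance differences or weights close enough to zero to destabilise
    inverse-probability-of-instrument weighting."""
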