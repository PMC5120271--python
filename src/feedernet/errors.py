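"""Exception types shared across the package."""


class FeederNetError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FeederNetError):
    """An input table or value violates a structural invariant."""


class GeometryError(FeederNetError):
    """A spatial operation received degenerate or out-of-extent input."""


class ConvergenceError(FeederNetError):
    """A model fit failed to converge or the likelihood is degenerate."""
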