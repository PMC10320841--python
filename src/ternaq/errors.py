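"""Exception hierarchy.

Everything raised deliberately by ternaq derives from :class:`TernaqError`
so callers (and the CLI) can catch model errors without masking bugs.
"""


class TernaqError(Exception):
    """Base class for all ternaq errors."""


class ValidationError(TernaqError, ValueError):
    """A model parameter is outside its physical domain."""


class SolverError(TernaqError, RuntimeError):
    """A numerical routine failed to converge; the message carries diagnostics."""


class Ec50NotIdentifiableError(TernaqError, ValueError):
    """The monitored binding curve does not saturate within the search bracket."""


class AlphaRangeError(TernaqError, ValueError):
    """The observed EC50 shift cannot be explained by cooperativity alone.

    Carries the attainable EC50 range so the caller can see whether the
    measurement is below the infinite-cooperativity floor or above the
    zero-cooperativity ceiling.
    """

    def __init__(self, message: str, attainable_range: tuple[float, float]):
        super().__init__(message)
        self.attainable_range = attainable_range


class IdentifiabilityError(TernaqError, ValueError):
    """The supplied data cannot constrain the requested parameter."""
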