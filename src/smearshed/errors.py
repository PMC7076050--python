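"""Exception hierarchy shared across the package."""


class SmearshedError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(SmearshedError):
    """The measurement table is missing a required column or has a bad header."""


class ParseError(SmearshedError):
    """A cell value could not be parsed (carries row/column context)."""


class IntegrityError(SmearshedError):
    """A record or table violates an invariant (e.g. superficial > total)."""


class GeometryError(SmearshedError):
    """A polygon is degenerate, self-intersecting, or otherwise invalid."""


class GenerationError(SmearshedError):
    """Synthetic scene or cohort generation was asked for something infeasible."""


class ConfigError(SmearshedError):
    """A configuration object fails validation."""


class DomainError(SmearshedError):
    """A response violates the domain required by the model/transform."""


class UndefinedSCIError(SmearshedError):
    """SCI requested with zero scored cells."""


class EstimabilityError(SmearshedError):
    """A requested group has no usable rows for the model at hand."""


class PairingError(SmearshedError):
    """Within-subject comparison requested for subjects missing one arm."""


class ConvergenceError(SmearshedError):
    """MCMC diagnostics exceed the accepted threshold; carries the R-hat table."""

    def __init__(self, message: str, rhat: dict | None = None):
        super().__init__(message)
        self.rhat = dict(rhat or {})


class PipelineError(SmearshedError):
    """A pipeline stage failed; names the stage and chains the cause."""
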