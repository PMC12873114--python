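"""Exception types shared across the package."""


class DomainError(ValueError):
    """An argument lies outside the physical domain of the operation."""


class IntegrationError(RuntimeError):
    """The ODE integrator failed; carries solver diagnostics in ``args``."""


class FitError(RuntimeError):
    """A parameter fit failed to converge or the data are unidentifiable."""
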