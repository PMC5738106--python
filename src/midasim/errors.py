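"""Exception hierarchy shared across the package."""


class MidaError(Exception):
    """Base class for all midasim errors."""


class DomainError(MidaError, ValueError):
    """An argument is outside the physically meaningful domain."""


class EnumerationError(MidaError, KeyError):
    """An unknown fluid, food class or preset name was requested."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0] if self.args else ""


class InfeasiblePlanError(MidaError, ValueError):
    """A sampling or transfer plan withdraws more than a compartment holds."""


class ConfigurationError(MidaError, ValueError):
    """A structurally invalid configuration (empty bounds, bad plan...)."""
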