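"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A rule set, grid or network specification is invalid."""


class DomainError(ValueError):
    """An input violates a mathematical domain requirement (e.g. sigma <= 0)."""


class GenerationError(RuntimeError):
    """Stochastic generation could not satisfy its constraints (rule set
    infeasible within the configured attempt cap)."""


class ContractViolation(ValueError):
    """Mismatched grids, shapes or scaling states between pipeline stages."""
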