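"""Structured errors raised across the package."""


class PBForceError(Exception):
    """Base class for all package errors."""


class StructureParseError(PBForceError):
    """A structure file could not be parsed (carries line context)."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ChainCountError(PBForceError):
    """Input did not contain exactly two chains."""

    def __init__(self, chains: list[str]):
        self.chains = list(chains)
        super().__init__(
            f"expected exactly two chains, found {len(self.chains)}: "
            f"{', '.join(self.chains) if self.chains else '(none)'}"
        )


class ParameterLookupError(PBForceError):
    """An atom had no entry in the charge/radius parameter table (strict mode)."""


class NoInterfaceError(PBForceError):
    """No cross-partner atom pair within the contact cutoff."""


class DegenerateDirectionError(PBForceError):
    """Interface pair vectors cancel; no separation direction exists."""


class GridError(PBForceError):
    """Atom placement incompatible with the grid (outside margin etc.)."""


class ConvergenceError(PBForceError):
    """Iterative solver failed to reach tolerance."""

    def __init__(self, residual: float, iterations: int):
        self.residual = residual
        self.iterations = iterations
        super().__init__(
            f"solver did not converge: residual {residual:.3e} "
            f"after {iterations} iterations"
        )
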