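"""Exception hierarchy."""


class PepfluxError(Exception):
    """Base class for all package errors."""


class ModelParseError(PepfluxError):
    """Malformed model text; message names the offending line."""


class ModelValidationError(PepfluxError):
    """Parsed model violates a structural invariant (atom balance, carbon counts)."""


class MeasurementError(PepfluxError):
    """Malformed or inconsistent measurement table."""


class UnreachableEMUError(PepfluxError):
    """A target EMU cannot be traced back to any substrate."""


class DeadEMUError(PepfluxError):
    """An EMU receives zero production under the given flux profile."""


class InfeasibleError(PepfluxError):
    """No flux profile satisfies stoichiometry, bounds and fixed fluxes."""


class NonConvergenceError(PepfluxError):
    """All optimization starts failed to converge."""


class TopologyError(PepfluxError):
    """Community exchange topology is unsupported (cyclic)."""
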