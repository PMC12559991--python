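"""Exception types shared across the package."""


class SVTetherError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(SVTetherError, ValueError):
    """A tether or parameter specification violates its invariants."""


class DegenerateProfileError(SVTetherError, ValueError):
    """An assembly-rate profile or distance PDF has empty support."""


class DegenerateStateError(SVTetherError, ValueError):
    """A composite distance PDF vanishes everywhere for the requested occupancy."""


class UndefinedMoveError(SVTetherError, ValueError):
    """Movement probability requested where the PDF vanishes on both sides."""


class ContractError(SVTetherError, ValueError):
    """An input violates a documented precondition (normalization, grid alignment...)."""


class ModelInconsistencyError(SVTetherError, RuntimeError):
    """A trajectory entered a state from which no legal move exists."""


class AbsorbingStateError(SVTetherError, RuntimeError):
    """Total reaction rate is zero; the jump process cannot proceed."""


class ConfigError(SVTetherError, ValueError):
    """A scenario configuration could not be resolved."""
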