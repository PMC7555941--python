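"""Exception hierarchy for uedopt.

Exit-code mapping used by the CLI: ValidationError -> 2,
InfeasibleError subclasses -> 3, ObjectiveError -> 4.
"""


class UedoptError(Exception):
    """Base class for all uedopt errors."""


class ValidationError(UedoptError, ValueError):
    """Malformed input: bad table entries, illegal settings, bad config."""


class InvalidDesignError(ValidationError):
    """A design table violates the U-type invariants."""


class InfeasibleError(UedoptError):
    """A request cannot be satisfied (design or architecture)."""


class InfeasibleDesignError(InfeasibleError):
    """Requested design parameters cannot produce a U-type table."""


class InfeasibleArchitectureError(InfeasibleError):
    """A factor combination propagates to a non-positive feature-map size."""


class ObjectiveError(UedoptError):
    """An objective evaluation failed."""


class DatasetUnavailableError(UedoptError):
    """The external image dataset required by the training objective is absent."""
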