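"""Exception hierarchy used across the package."""


class MetstopError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MetstopError):
    """Input data violates a documented contract (bad code, bad column, ...)."""


class FormatError(ValidationError):
    """A token does not follow its required textual format (e.g. a flank)."""


class PlacementError(MetstopError):
    """A modification record cannot be anchored onto its sequence."""


class AmbiguityError(PlacementError):
    """A flank matches the sequence somewhere other than the stated residue."""

    def __init__(self, message: str, candidates: tuple[int, ...] = ()):
        super().__init__(message)
        self.candidates = tuple(candidates)


class DegenerateInputError(MetstopError):
    """A statistic cannot be computed (zero variance, too few points, ...)."""


class ConfigError(MetstopError):
    """A synthetic-data or site-window configuration is infeasible."""


class MissingScoreError(MetstopError):
    """A per-residue propensity score was requested for an unscored position."""
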