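"""Exception hierarchy shared across the package.

Validation problems (bad input, bad configuration) derive from
:class:`ChitosimValidationError` so the CLI can map them to exit code 2;
runtime failures (stalled reactions, no signal) derive from
:class:`ChitosimRuntimeError` and map to exit code 1.
"""


class ChitosimError(Exception):
    """Base class for all package errors."""


class ChitosimValidationError(ChitosimError, ValueError):
    """Invalid user input or configuration."""


class ChitosimRuntimeError(ChitosimError, RuntimeError):
    """A computation could not be completed on valid input."""


class InvalidSequenceError(ChitosimValidationError):
    """A residue string contains characters other than A/D or is empty."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


class InfeasibleModificationError(ChitosimValidationError):
    """Requested (de)acetylation is not chemically possible at that unit."""


class StalledReactionError(ChitosimRuntimeError):
    """No binding frame with finite energy exists; the reaction cannot proceed."""


class EnumerationTooLargeError(ChitosimValidationError):
    """Exact product enumeration would exceed the configured size cap."""


class UndefinedStatisticsError(ChitosimRuntimeError):
    """Block statistics are undefined (no signal / no interior fragments)."""


class WindowOverlapError(ChitosimValidationError):
    """Two species targets have overlapping m/z windows."""


class NoSignalError(ChitosimRuntimeError):
    """No peak or ion intensity matched any target."""


class InconsistentSpeciesError(ChitosimValidationError):
    """A product species is more acetylated than the declared substrate."""


class NormalizationError(ChitosimRuntimeError):
    """Reference/control signal is absent or non-positive."""


class DegenerateFitError(ChitosimValidationError):
    """A regression cannot be fitted (e.g. a single distinct concentration)."""


class InsufficientDataError(ChitosimValidationError):
    """Too few finite replicate values to compute a summary."""


class AmbiguousPatternsWarning(UserWarning):
    """Candidate patterns are indistinguishable from their B/Y ion ladders."""
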