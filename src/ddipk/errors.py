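"""Exception hierarchy shared across the package.

All domain failures derive from :class:`DDIPKError` so callers (and the CLI)
can distinguish scientific/validation problems (exit 1) from usage errors.
"""


class DDIPKError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DDIPKError):
    """A delimited-text input does not conform to the expected layout."""


class ValidationError(DDIPKError):
    """Input values violate a domain invariant (negative time, duplicate sample...)."""


class InsufficientDataError(DDIPKError):
    """Too few usable samples for the requested computation."""


class TerminalPhaseError(DDIPKError):
    """No terminal log-linear window with a positive elimination slope exists."""


class InfeasibleAUCRError(DDIPKError):
    """AUCR at or above the complete-inhibition ceiling 1/(1-f_m) for the given f_m."""


class NoInteractionError(DDIPKError):
    """AUCR <= 1: no inhibition signal to back-solve a potency from."""


class UnknownSpeciesError(DDIPKError):
    """Species label missing from the body-surface-area factor table."""


class FitError(DDIPKError):
    """Nonlinear regression failed to converge or produced a degenerate optimum."""
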