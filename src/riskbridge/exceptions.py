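"""Structured errors raised across riskbridge.

All validation failures derive from :class:`RiskBridgeError` so callers
(and the CLI, which maps them to exit code 2) can catch one base class.
Degenerate inputs raise rather than silently propagating NaN.
"""


class RiskBridgeError(ValueError):
    """Base class for all riskbridge validation and domain errors."""


class DegenerateMarginError(RiskBridgeError):
    """A 2x2 table margin used as a denominator is zero.

    Carries the name of the offending margin (e.g. ``"cases"``).
    """

    def __init__(self, margin: str, message: str | None = None):
        self.margin = margin
        super().__init__(message or f"degenerate margin: {margin} total is zero")


class BoundaryValueError(RiskBridgeError):
    """A probability sits at a boundary where the requested measure diverges."""


class InfeasibleModelError(RiskBridgeError):
    """No 2-of-3 independent-factor model matches the requested rates."""


class EnumerationLimitError(RiskBridgeError):
    """Factor model too large to enumerate exhaustively."""


class NoKneeError(RiskBridgeError):
    """The exposed-group incidence never crosses 0.5 on the symmetric path."""


class UnreachableTargetError(RiskBridgeError):
    """Requested cohort difference cannot be reached on the symmetric path."""
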