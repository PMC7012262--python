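"""Shared probability validation helpers."""

from __future__ import annotations

from .exceptions import RiskBridgeError

#: Absolute tolerance for all floating-point probability comparisons.
ATOL = 1e-12


def check_probability(value: float, name: str, *, atol: float = ATOL) -> float:
    """Validate ``value`` as a probability, clamping floating-point dust.

    Values in ``[-atol, 0)`` or ``(1, 1+atol]`` are clamped to the boundary;
    anything further out raises :class:`RiskBridgeError`.
    """
    value = float(value)
    if value != value:  # NaN
        raise RiskBridgeError(f"{name} is NaN")
    if -atol <= value < 0.0:
        return 0.0
    if 1.0 < value <= 1.0 + atol:
        return 1.0
    if not 0.0 <= value <= 1.0:
        raise RiskBridgeError(f"{name} must be a probability in [0, 1], got {value!r}")
    return value
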