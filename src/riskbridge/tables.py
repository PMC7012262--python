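"""2x2 contingency tables and the standard measures derived from them.

The table orientation is fixed: rows are exposure status, columns are
disease status::

                  case    non-case
    exposed         a         b
    unexposed       c         d

From a fully observed (cross-sectional) table all five rates tying the
two study designs together are available at once:

* cohort view     -- incidences ``Pe = a/(a+b)`` and ``Pn = c/(c+d)``
* case-control view -- exposure frequencies ``Pd = a/(a+c)`` and
  ``Pc = b/(b+d)``
* the bridge      -- population incidence ``m = (a+c)/(a+b+c+d)``
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from ._validate import ATOL, check_probability
from .exceptions import BoundaryValueError, DegenerateMarginError, RiskBridgeError

__all__ = [
    "ContingencyTable2x2",
    "RateSet",
    "rates_from_table",
    "odds_ratio",
    "relative_risk",
    "risk_difference",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of a 2x2 exposure-by-disease table.

    Parameters
    ----------
    a : int
        Exposed cases.
    b : int
        Exposed non-cases.
    c : int
        Unexposed cases.
    d : int
        Unexposed non-cases.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            value = getattr(self, name)
            if not isinstance(value, int) or isinstance(value, bool):
                raise RiskBridgeError(f"count {name} must be an integer, got {value!r}")
            if value < 0:
                raise RiskBridgeError(f"count {name} must be nonnegative, got {value}")
        if self.total == 0:
            raise RiskBridgeError("table is empty: a+b+c+d must be positive")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_cases(self) -> int:
        return self.a + self.c

    @property
    def n_noncases(self) -> int:
        return self.b + self.d

    @property
    def n_exposed(self) -> int:
        return self.a + self.b

    @property
    def n_unexposed(self) -> int:
        return self.c + self.d


@dataclass(frozen=True)
class RateSet:
    """The five probabilities linking cohort and case-control designs.

    ``pe``/``pn`` are disease incidences among exposed/unexposed (cohort
    view); ``pd``/``pc`` are exposure frequencies among cases/controls
    (case-control view); ``m`` is the population incidence.
    """

    pe: float
    pn: float
    pd: float
    pc: float
    m: float

    def __post_init__(self) -> None:
        for name in ("pe", "pn", "pd", "pc", "m"):
            object.__setattr__(self, name, check_probability(getattr(self, name), name))


def rates_from_table(table: ContingencyTable2x2) -> RateSet:
    """Compute all five rates of a fully observed table.

    Raises
    ------
    DegenerateMarginError
        If any margin used as a denominator is zero; the error names the
        margin rather than letting a NaN escape.
    """
    if table.n_exposed == 0:
        raise DegenerateMarginError("exposed", "no exposed individuals: Pe undefined")
    if table.n_unexposed == 0:
        raise DegenerateMarginError("unexposed", "no unexposed individuals: Pn undefined")
    if table.n_cases == 0:
        raise DegenerateMarginError("cases", "no cases: Pd undefined")
    if table.n_noncases == 0:
        raise DegenerateMarginError("noncases", "no non-cases: Pc undefined")
    return RateSet(
        pe=table.a / table.n_exposed,
        pn=table.c / table.n_unexposed,
        pd=table.a / table.n_cases,
        pc=table.b / table.n_noncases,
        m=table.n_cases / table.total,
    )


def odds_ratio(rates: RateSet, *, allow_infinite: bool = False) -> float:
    """Case-control odds ratio ``Pd(1-Pc) / (Pc(1-Pd))``.

    For rates derived from a table this equals the cross-product ``ad/bc``.

    Parameters
    ----------
    allow_infinite
        If True, boundary values of ``pd``/``pc`` yield ``inf`` or ``0.0``
        instead of raising. Off by default: a boundary odds ratio usually
        signals a degenerate design, not an interesting estimate.
    """
    pd, pc = rates.pd, rates.pc
    if pd in (0.0, 1.0) or pc in (0.0, 1.0):
        if allow_infinite:
            num = pd * (1.0 - pc)
            den = pc * (1.0 - pd)
            if den == 0.0:
                return math.inf if num > 0.0 else math.nan
            return num / den
        raise BoundaryValueError(
            f"odds ratio undefined at boundary: pd={pd}, pc={pc} "
            "(pass allow_infinite=True to map to inf/0)"
        )
    return pd * (1.0 - pc) / (pc * (1.0 - pd))


def relative_risk(rates: RateSet) -> float:
    """Cohort relative risk ``Pe / Pn``."""
    if rates.pn == 0.0:
        raise BoundaryValueError("relative risk undefined: unexposed incidence Pn is zero")
    return rates.pe / rates.pn


def risk_difference(rates: RateSet) -> float:
    """Absolute risk difference ``Pe - Pn`` (in [-1, 1])."""
    return rates.pe - rates.pn


# re-export the shared comparison tolerance for users of this module
TOLERANCE = ATOL
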