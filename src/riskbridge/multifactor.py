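"""Multiple-pathogenic-factor disease model.

``n`` independent binary risk factors with frequencies ``f1..fn``; disease
occurs iff at least ``r`` factors are present ("r-of-n" sufficient-cause
rule, no interaction terms). The canonical instance is 2-of-3: three
factors, any two of which together induce the disease while one alone does
not. All study-design quantities are computed by exhaustive enumeration of
the ``2^n`` presence patterns; for 2-of-3 the enumeration agrees with the
closed forms (e.g. ``fd = f1(1-f2)(1-f3)``, ``fe = (1-f1) f2 f3``,
``m = f1 f2 + f1 f3 + f2 f3 - 2 f1 f2 f3``) to machine precision.

Factor indices are 1-based in every public interface, matching the usual
X1, X2, X3 notation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._validate import ATOL, check_probability
from .exceptions import EnumerationLimitError, RiskBridgeError

__all__ = [
    "FactorModel",
    "CombinationTable",
    "enumerate_combinations",
    "population_incidence",
    "cohort_rates",
    "casecontrol_rates",
]

#: Largest factor count enumerated exhaustively (2^20 ~ 1e6 rows).
MAX_FACTORS = 20


@dataclass(frozen=True)
class FactorModel:
    """Independent binary risk factors with a disease threshold.

    Parameters
    ----------
    freqs : sequence of float
        Population frequency of each factor, ``f1..fn``.
    r : int, default 2
        Minimum number of simultaneously present factors that causes
        disease.
    """

    freqs: tuple[float, ...]
    r: int = 2

    def __post_init__(self) -> None:
        freqs = tuple(check_probability(f, f"f{i + 1}") for i, f in enumerate(self.freqs))
        object.__setattr__(self, "freqs", freqs)
        if len(freqs) < 1:
            raise RiskBridgeError("model needs at least one factor")
        if not isinstance(self.r, int) or isinstance(self.r, bool):
            raise RiskBridgeError(f"threshold r must be an integer, got {self.r!r}")
        if not 1 <= self.r <= len(freqs):
            raise RiskBridgeError(
                f"threshold r={self.r} must satisfy 1 <= r <= n={len(freqs)}"
            )

    @property
    def n(self) -> int:
        return len(self.freqs)


@dataclass(frozen=True)
class CombinationTable:
    """All ``2^n`` factor-presence combinations of a model.

    ``patterns`` is a ``(2^n, n)`` boolean array (row k is the binary
    expansion of k, factor 1 in column 0), ``freq`` the product probability
    mass of each pattern, ``diseased`` the r-of-n disease indicator.
    For 2-of-3 the rows map onto the conventional cells A-H; in particular
    the exposed-healthy cell D is pattern (1,0,0) and the
    unexposed-diseased cell E is pattern (0,1,1).
    """

    patterns: np.ndarray = field(repr=False)
    freq: np.ndarray = field(repr=False)
    diseased: np.ndarray = field(repr=False)

    def mass(self, pattern: tuple[int, ...]) -> float:
        """Probability mass of one presence pattern, e.g. ``(1, 0, 0)``."""
        match = (self.patterns == np.asarray(pattern, dtype=bool)).all(axis=1)
        return float(self.freq[match][0])

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: columns ``pattern`` (e.g. "101"), ``frequency``, ``diseased``."""
        labels = ["".join("1" if b else "0" for b in row) for row in self.patterns]
        return pd.DataFrame(
            {"pattern": labels, "frequency": self.freq, "diseased": self.diseased}
        )


def enumerate_combinations(model: FactorModel) -> CombinationTable:
    """Enumerate every presence pattern with its mass and disease label.

    Masses are products of ``f_i`` / ``(1-f_i)`` under independence and sum
    to 1 to machine precision. Raises :class:`EnumerationLimitError` above
    ``n = 20``.
    """
    n = model.n
    if n > MAX_FACTORS:
        raise EnumerationLimitError(
            f"n={n} factors exceeds the enumeration limit of {MAX_FACTORS}"
        )
    codes = np.arange(2**n, dtype=np.int64)
    # column i is the presence bit of factor i+1
    patterns = (codes[:, None] >> np.arange(n)) & 1
    patterns = patterns.astype(bool)
    f = np.asarray(model.freqs)
    freq = np.where(patterns, f, 1.0 - f).prod(axis=1)
    diseased = patterns.sum(axis=1) >= model.r
    return CombinationTable(patterns=patterns, freq=freq, diseased=diseased)


def population_incidence(model: FactorModel) -> float:
    """Disease incidence ``m`` in the whole population: total diseased mass."""
    table = enumerate_combinations(model)
    return float(table.freq[table.diseased].sum())


def _factor_column(model: FactorModel, factor: int) -> int:
    if not isinstance(factor, int) or isinstance(factor, bool):
        raise RiskBridgeError(f"factor index must be an integer, got {factor!r}")
    if not 1 <= factor <= model.n:
        raise RiskBridgeError(f"factor index {factor} out of range 1..{model.n}")
    return factor - 1


def cohort_rates(model: FactorModel, factor: int = 1) -> tuple[float, float]:
    """Cohort incidences for one factor: ``(Pe, Pn)``.

    ``Pe = P(disease | factor present)``, ``Pn = P(disease | factor
    absent)``, by conditioning the combination table. For 2-of-3 and
    factor 1 these reduce to ``Pe = 1-(1-f2)(1-f3)`` and ``Pn = f2 f3``.
    """
    col = _factor_column(model, factor)
    fi = model.freqs[col]
    if fi <= 0.0 or fi >= 1.0:
        raise RiskBridgeError(
            f"cannot condition on factor {factor}: frequency {fi} leaves an empty group"
        )
    table = enumerate_combinations(model)
    present = table.patterns[:, col]
    pe = float(table.freq[present & table.diseased].sum()) / fi
    pn = float(table.freq[~present & table.diseased].sum()) / (1.0 - fi)
    return min(pe, 1.0), min(pn, 1.0)


def casecontrol_rates(model: FactorModel, factor: int = 1) -> tuple[float, float]:
    """Case-control exposure frequencies for one factor: ``(Pd, Pc)``.

    ``Pd = P(factor present | diseased)``, ``Pc = P(factor present | not
    diseased)``. Requires ``0 < m < 1`` so that neither the case nor the
    control group is empty.
    """
    col = _factor_column(model, factor)
    table = enumerate_combinations(model)
    m = float(table.freq[table.diseased].sum())
    if m <= 0.0:
        raise RiskBridgeError("no cases: population incidence m = 0")
    if m >= 1.0 - ATOL:
        raise RiskBridgeError("no controls: population incidence m = 1")
    present = table.patterns[:, col]
    pd_ = float(table.freq[present & table.diseased].sum()) / m
    pc_ = float(table.freq[present & ~table.diseased].sum()) / (1.0 - m)
    return min(pd_, 1.0), min(pc_, 1.0)
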