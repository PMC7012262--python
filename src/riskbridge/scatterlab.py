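"""When does a case-control difference overstate the cohort difference?

Plots and analyses the map from the case-control contrast ``x = Pd - Pc``
to the cohort contrast ``y = Pe - Pn`` at fixed population incidence ``m``.

Along the symmetric one-parameter path ``Pc = 1 - Pd`` the map is a
monotone S-curve through the origin. Two landmarks are computed:

* the **knee**, where the exposed-group incidence crosses ``Pe = 0.5``;
  in closed form ``Pd = 1 - m``, so ``x = 1 - 2m`` and
  ``y = 0.5 - m^2/(m^2 + (1-m)^2)``;
* the **threshold**: the smallest ``x`` at which ``y`` reaches a target
  cohort difference (e.g. 0.5), found by root bracketing.

For a rare disease the knee sits near ``x = 1``: an enormous case-control
contrast is required before the cohort contrast becomes large, which is the
quantitative sense in which case-control differences overstate cohort
differences. A full ``(Pd, Pc)`` grid variant is provided so points off the
symmetric path (large ``y`` at moderate ``x``) remain visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._validate import check_probability
from .convert import cc_to_cohort, cc_to_cohort_arrays
from .exceptions import NoKneeError, RiskBridgeError, UnreachableTargetError

__all__ = [
    "PathCurve",
    "symmetric_path_curve",
    "full_scatter",
    "knee_point",
    "threshold_to_reach",
]

#: Default bisection tolerance on x and default grid spacing.
X_TOL = 1e-9
DEFAULT_STEP = 0.001


@dataclass(frozen=True)
class PathCurve:
    """Sampled (Pd, Pc, x, y) points at one population incidence."""

    m: float
    points: pd.DataFrame = field(repr=False)  # columns: pd, pc, x, y

    def __len__(self) -> int:
        return len(self.points)


def _check_m(m: float) -> float:
    m = check_probability(m, "m")
    if not 0.0 < m < 1.0:
        raise RiskBridgeError(f"population incidence m must be in (0, 1), got {m}")
    return m


def _symmetric_y(pd_: float, m: float) -> float:
    pe, pn = cc_to_cohort(pd_, 1.0 - pd_, m)
    return pe - pn


def symmetric_path_curve(m: float, step: float = DEFAULT_STEP) -> PathCurve:
    """Evaluate the symmetric path ``Pc = 1 - Pd`` for ``Pd`` in [0, 1].

    Along this path ``x = 2*Pd - 1`` sweeps [-1, 1] and ``y`` is continuous
    and increasing in ``x``.
    """
    m = _check_m(m)
    if not 0.0 < step <= 0.5:
        raise RiskBridgeError(f"step must be in (0, 0.5], got {step}")
    n_steps = int(round(1.0 / step))
    pd_grid = np.linspace(0.0, 1.0, n_steps + 1)
    pc_grid = 1.0 - pd_grid
    pe, pn = cc_to_cohort_arrays(pd_grid, pc_grid, m)
    frame = pd.DataFrame(
        {"pd": pd_grid, "pc": pc_grid, "x": pd_grid - pc_grid, "y": pe - pn}
    )
    return PathCurve(m=m, points=frame)


def full_scatter(m: float, step: float = 0.01) -> PathCurve:
    """Evaluate ``(x, y)`` over the full ``(Pd, Pc)`` unit-square grid.

    An unordered point cloud for plotting; corner points whose conversion
    is undefined (both groups empty) are dropped. Demonstrates that off the
    symmetric path a moderate ``x`` can already carry a large ``y``.
    """
    m = _check_m(m)
    if not 0.0 < step <= 0.5:
        raise RiskBridgeError(f"step must be in (0, 0.5], got {step}")
    n_steps = int(round(1.0 / step))
    axis = np.linspace(0.0, 1.0, n_steps + 1)
    pd_grid, pc_grid = np.meshgrid(axis, axis, indexing="ij")
    pd_flat, pc_flat = pd_grid.ravel(), pc_grid.ravel()
    pe, pn = cc_to_cohort_arrays(pd_flat, pc_flat, m)
    y = pe - pn
    ok = ~np.isnan(y)
    frame = pd.DataFrame(
        {
            "pd": pd_flat[ok],
            "pc": pc_flat[ok],
            "x": pd_flat[ok] - pc_flat[ok],
            "y": y[ok],
        }
    )
    return PathCurve(m=m, points=frame)


def knee_point(m: float) -> tuple[float, float]:
    """Landmark on the symmetric path where ``Pe`` crosses 0.5.

    Closed form: ``x = 1 - 2m``, ``y = 0.5 - m^2/(m^2 + (1-m)^2)``. For
    ``m >= 0.5`` the crossing does not exist with ``Pd >= Pc`` and a
    :class:`NoKneeError` is raised.
    """
    m = _check_m(m)
    if m >= 0.5:
        raise NoKneeError(f"Pe = 0.5 unreachable with Pd >= Pc when m = {m} >= 0.5")
    x = 1.0 - 2.0 * m
    y = 0.5 - m * m / (m * m + (1.0 - m) * (1.0 - m))
    return x, y


def knee_point_numeric(m: float, tol: float = X_TOL) -> tuple[float, float]:
    """Bisection counterpart of :func:`knee_point` (independent of it).

    Solves ``Pe(Pd) = 0.5`` along the symmetric path by root bracketing on
    ``Pd`` in [0.5, 1]; used as the numerical cross-check of the closed
    form.
    """
    m = _check_m(m)
    if m >= 0.5:
        raise NoKneeError(f"Pe = 0.5 unreachable with Pd >= Pc when m = {m} >= 0.5")

    def pe_minus_half(pd_: float) -> float:
        pe, _ = cc_to_cohort(pd_, 1.0 - pd_, m)
        return pe - 0.5

    # solve Pd near machine precision: dy/dPd ~ 1/(4m) amplifies any slack,
    # so the requested x-tolerance alone would not carry over to y
    pd_star = brentq(pe_minus_half, 0.5, 1.0, xtol=min(tol / 2.0, 1e-14))
    return 2.0 * pd_star - 1.0, _symmetric_y(pd_star, m)


def threshold_to_reach(m: float, y_target: float, tol: float = X_TOL) -> float:
    """Smallest ``x = Pd - Pc`` on the symmetric path with ``y >= y_target``.

    ``y`` is continuous and strictly increasing in ``x`` on the path, with
    ``y(0) = 0`` and ``y(1) = 1``, so the crossing is unique; it is located
    by root bracketing to tolerance ``tol`` on ``x``.
    """
    m = _check_m(m)
    if not 0.0 < y_target < 1.0:
        raise UnreachableTargetError(
            f"target cohort difference must be in (0, 1), got {y_target}"
        )

    def gap(pd_: float) -> float:
        return _symmetric_y(pd_, m) - y_target

    # y(pd=0.5) = 0 < y_target and y(pd=1) = 1 > y_target bracket the root
    pd_star = brentq(gap, 0.5, 1.0, xtol=tol / 2.0)
    return 2.0 * pd_star - 1.0
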