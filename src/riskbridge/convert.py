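"""Closed-form translation between case-control and cohort study results.

A case-control study reports exposure frequencies among cases (``Pd``) and
controls (``Pc``). A cohort study reports disease incidences among exposed
(``Pe``) and unexposed (``Pn``). Given the population incidence ``m`` the two
are linked exactly (Bayes inversion of the shared joint distribution):

    Pe = Pd*m / (Pc*(1-m) + Pd*m)
    Pn = m*(1-Pd) / (1 - Pc*(1-m) - Pd*m)

In the rare-disease limit ``m -> 0`` the relative risk ``Pe/Pn`` collapses to
the familiar odds ratio ``Pd(1-Pc)/(Pc(1-Pd))``; the conversion makes the
approximation exact at any incidence.

The same identities arise from a multifactor disease model in which a factor
of frequency ``f1`` combines with co-factors to cause disease: the latent
cell masses ``fd`` (exposed and healthy) and ``fe`` (unexposed and diseased)
are recoverable in closed form from ``(Pd, Pc, m)`` — see
:func:`recover_latent`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._validate import ATOL, check_probability
from .exceptions import BoundaryValueError, InfeasibleModelError, RiskBridgeError

__all__ = [
    "LatentTriple",
    "cc_to_cohort",
    "cohort_to_cc",
    "rr_from_cc",
    "recover_latent",
    "recover_cofactors",
]


@dataclass(frozen=True)
class LatentTriple:
    """Latent multifactor-model parameters behind a case-control result.

    ``f1`` is the frequency of the observed factor, ``fd`` the probability
    mass of the exposed-and-healthy cell, ``fe`` that of the
    unexposed-and-diseased cell. The population incidence is
    ``m = f1 - fd + fe``.
    """

    f1: float
    fd: float
    fe: float

    def __post_init__(self) -> None:
        for name in ("f1", "fd", "fe"):
            object.__setattr__(self, name, check_probability(getattr(self, name), name))
        if self.fd > self.f1 + ATOL:
            raise RiskBridgeError("fd (exposed-healthy mass) cannot exceed f1")
        if self.fe > 1.0 - self.f1 + ATOL:
            raise RiskBridgeError("fe (unexposed-diseased mass) cannot exceed 1 - f1")

    @property
    def m(self) -> float:
        """Population incidence implied by the triple."""
        return self.f1 - self.fd + self.fe


def _clamp_unit(x: float) -> float:
    """Clamp to [0, 1] only when within ATOL of the boundary."""
    if -ATOL <= x < 0.0:
        return 0.0
    if 1.0 < x <= 1.0 + ATOL:
        return 1.0
    return x


def cc_to_cohort(pd: float, pc: float, m: float) -> tuple[float, float]:
    """Convert case-control frequencies into cohort incidences.

    Parameters
    ----------
    pd, pc
        Exposure frequency among cases and among controls.
    m
        Disease incidence in the total population.

    Returns
    -------
    (pe, pn)
        Incidence among exposed and among unexposed.

    Raises
    ------
    BoundaryValueError
        When a denominator vanishes: ``Pd*m + Pc*(1-m) = 0`` leaves ``Pe``
        undefined (no exposed individuals at all);
        ``1 - Pc*(1-m) - Pd*m = 0`` leaves ``Pn`` undefined.
    """
    pd = check_probability(pd, "pd")
    pc = check_probability(pc, "pc")
    m = check_probability(m, "m")
    q_exposed = pd * m + pc * (1.0 - m)  # P(exposed)
    if q_exposed <= 0.0:
        raise BoundaryValueError("Pe undefined: Pd*m + Pc*(1-m) = 0 (nobody exposed)")
    if q_exposed >= 1.0:
        raise BoundaryValueError("Pn undefined: 1 - Pc*(1-m) - Pd*m = 0 (nobody unexposed)")
    pe = pd * m / q_exposed
    pn = m * (1.0 - pd) / (1.0 - q_exposed)
    return _clamp_unit(pe), _clamp_unit(pn)


def cohort_to_cc(pe: float, pn: float, q: float) -> tuple[float, float, float]:
    """Exact inverse of :func:`cc_to_cohort`.

    Converts cohort incidences plus the exposure prevalence ``q`` into
    case-control frequencies and the population incidence:
    ``m = q*Pe + (1-q)*Pn``, ``Pd = q*Pe/m``, ``Pc = q*(1-Pe)/(1-m)``.
    """
    pe = check_probability(pe, "pe")
    pn = check_probability(pn, "pn")
    q = check_probability(q, "q")
    if not 0.0 < q < 1.0:
        raise RiskBridgeError(f"exposure prevalence q must be in (0, 1), got {q}")
    m = q * pe + (1.0 - q) * pn
    if m == 0.0:
        raise BoundaryValueError("Pd undefined: population incidence m = 0 (no cases)")
    if m == 1.0:
        raise BoundaryValueError("Pc undefined: population incidence m = 1 (no controls)")
    pd = q * pe / m
    pc = q * (1.0 - pe) / (1.0 - m)
    return _clamp_unit(pd), _clamp_unit(pc), _clamp_unit(m)


def rr_from_cc(pd: float, pc: float, m: float) -> float:
    """Relative risk implied by case-control results at incidence ``m``.

    At ``m = 0`` the analytic limit is returned: the odds ratio
    ``Pd(1-Pc)/(Pc(1-Pd))``. The limit branch is exact; no tiny-``m``
    numerical evaluation is involved.
    """
    pd = check_probability(pd, "pd")
    pc = check_probability(pc, "pc")
    m = check_probability(m, "m")
    if pd == 1.0:
        raise BoundaryValueError("relative risk infinite: Pd = 1 means no unexposed cases")
    if m == 0.0:
        if pc == 0.0:
            raise BoundaryValueError("odds ratio undefined at boundary: pc = 0")
        return pd * (1.0 - pc) / (pc * (1.0 - pd))
    pe, pn = cc_to_cohort(pd, pc, m)
    if pn == 0.0:
        raise BoundaryValueError("relative risk infinite: unexposed incidence Pn = 0")
    return pe / pn


def recover_latent(pd: float, pc: float, m: float) -> LatentTriple:
    """Recover the latent multifactor parameters from case-control data.

    Solves the defining relations
    ``Pd = (f1-fd)/(f1-fd+fe)``, ``Pc = fd/(1-f1-fe+fd)``, ``m = f1-fd+fe``
    in closed form::

        fe = m*(1-Pd);  fd = Pc*(1-m);  f1 = Pd*m + Pc*(1-m)

    The solution is a convex combination of probabilities, so it is always
    in range; back-substitution reproduces the inputs to ~1e-12.
    """
    pd = check_probability(pd, "pd")
    pc = check_probability(pc, "pc")
    m = check_probability(m, "m")
    fe = m * (1.0 - pd)
    fd = pc * (1.0 - m)
    f1 = pd * m + pc * (1.0 - m)
    return LatentTriple(f1=f1, fd=fd, fe=fe)


def recover_cofactors(pe: float, pn: float) -> tuple[float, float]:
    """Invert the 2-of-3 model: co-factor frequencies from cohort rates.

    Under three independent factors with disease requiring any two, the
    cohort rates for factor 1 are ``Pe = 1-(1-f2)(1-f3)`` and
    ``Pn = f2*f3``, so ``f2`` and ``f3`` are the roots of
    ``t^2 - (Pe+Pn)*t + Pn = 0``.

    Returns the roots sorted ascending — the model cannot tell which root
    is which factor (the labels are exchangeable).

    Raises
    ------
    InfeasibleModelError
        If the discriminant is negative or a root falls outside [0, 1]:
        no 2-of-3 independent-factor model matches these rates.
    """
    pe = check_probability(pe, "pe")
    pn = check_probability(pn, "pn")
    s = pe + pn
    disc = s * s - 4.0 * pn
    if disc < 0.0:
        if disc >= -ATOL:  # floating-point noise near tangency: double root
            disc = 0.0
        else:
            raise InfeasibleModelError(
                "no 2-of-3 independent-factor model matches these rates "
                f"(discriminant {disc:.3g} < 0 for Pe={pe}, Pn={pn})"
            )
    root = math.sqrt(disc)
    lo, hi = (s - root) / 2.0, (s + root) / 2.0
    lo, hi = _clamp_unit(lo), _clamp_unit(hi)
    if not (0.0 <= lo <= 1.0 and 0.0 <= hi <= 1.0):
        raise InfeasibleModelError(
            "no 2-of-3 independent-factor model matches these rates "
            f"(root outside [0, 1] for Pe={pe}, Pn={pn})"
        )
    return lo, hi


def cc_to_cohort_arrays(
    pd: np.ndarray, pc: np.ndarray, m: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`cc_to_cohort` over arrays of (pd, pc) at fixed m.

    Grid points whose denominator vanishes (pd=pc=0 or pd=pc=1 at interior
    m) yield NaN rather than raising; callers mask them. Used for scatter
    grids where per-point exceptions would be impractical.
    """
    pd = np.asarray(pd, dtype=float)
    pc = np.asarray(pc, dtype=float)
    q = pd * m + pc * (1.0 - m)
    with np.errstate(divide="ignore", invalid="ignore"):
        pe = np.where(q > 0.0, pd * m / q, np.nan)
        pn = np.where(q < 1.0, m * (1.0 - pd) / (1.0 - q), np.nan)
    return pe, pn
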