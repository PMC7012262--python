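"""Finite-sample study simulator.

Draws case-control, cohort and cross-sectional 2x2 tables (and
per-individual populations) from known rates or from a
:class:`~riskbridge.multifactor.FactorModel`, so every estimator and
conversion in the package can be exercised against sampling noise without
external data.

All randomness flows through :func:`numpy.random.default_rng` (PCG64)
seeded with a single caller-supplied integer; identical inputs and seed
reproduce identical draws. Case-control sampling fixes the case and
control group sizes — the design's defining feature — rather than drawing
from the joint distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._validate import check_probability
from .exceptions import RiskBridgeError
from .multifactor import FactorModel, casecontrol_rates, cohort_rates, population_incidence
from .tables import ContingencyTable2x2, RateSet

__all__ = [
    "StudyDraw",
    "sample_case_control",
    "sample_cohort",
    "sample_cross_sectional",
    "sample_population",
]


@dataclass(frozen=True)
class StudyDraw:
    """One simulated study: its design, sampled table, seed and truth."""

    design: str  # "case_control" | "cohort" | "cross_sectional"
    table: ContingencyTable2x2
    seed: int
    true_rates: RateSet


def _check_size(n: int, name: str) -> int:
    if not isinstance(n, int) or isinstance(n, bool) or n <= 0:
        raise RiskBridgeError(f"{name} must be a positive integer, got {n!r}")
    return n


def sample_case_control(
    pd_: float, pc: float, n_cases: int, n_controls: int, seed: int
) -> StudyDraw:
    """Draw a case-control table: exposure is binomial within each group.

    ``a ~ Binomial(n_cases, Pd)``, ``b ~ Binomial(n_controls, Pc)``;
    ``c`` and ``d`` are the group remainders. The case/control margins are
    fixed by design, so the table carries no information about ``m``; the
    placeholder true rates record ``m`` as the case fraction of the draw.
    """
    pd_ = check_probability(pd_, "pd")
    pc = check_probability(pc, "pc")
    n_cases = _check_size(n_cases, "n_cases")
    n_controls = _check_size(n_controls, "n_controls")
    rng = np.random.default_rng(seed)
    a = int(rng.binomial(n_cases, pd_))
    b = int(rng.binomial(n_controls, pc))
    table = ContingencyTable2x2(a=a, b=b, c=n_cases - a, d=n_controls - b)
    truth = RateSet(pe=0.0, pn=0.0, pd=pd_, pc=pc, m=n_cases / (n_cases + n_controls))
    return StudyDraw(design="case_control", table=table, seed=seed, true_rates=truth)


def sample_cohort(
    pe: float, pn: float, n_exposed: int, n_unexposed: int, seed: int
) -> StudyDraw:
    """Draw a cohort table: disease is binomial within each exposure group.

    ``a ~ Binomial(n_exposed, Pe)``, ``c ~ Binomial(n_unexposed, Pn)``.
    """
    pe = check_probability(pe, "pe")
    pn = check_probability(pn, "pn")
    n_exposed = _check_size(n_exposed, "n_exposed")
    n_unexposed = _check_size(n_unexposed, "n_unexposed")
    rng = np.random.default_rng(seed)
    a = int(rng.binomial(n_exposed, pe))
    c = int(rng.binomial(n_unexposed, pn))
    table = ContingencyTable2x2(a=a, b=n_exposed - a, c=c, d=n_unexposed - c)
    q = n_exposed / (n_exposed + n_unexposed)
    truth = RateSet(pe=pe, pn=pn, pd=0.0, pc=0.0, m=q * pe + (1.0 - q) * pn)
    return StudyDraw(design="cohort", table=table, seed=seed, true_rates=truth)


def sample_population(model: FactorModel, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` individuals from a factor model.

    Each factor is an independent Bernoulli(f_i) per individual; disease
    occurs iff at least ``r`` factors are present. Returns a frame with
    columns ``id``, ``x1..xn``, ``diseased`` (all 0/1 integers).
    """
    n = _check_size(n, "n")
    rng = np.random.default_rng(seed)
    f = np.asarray(model.freqs)
    presence = rng.random((n, model.n)) < f
    diseased = presence.sum(axis=1) >= model.r
    data = {"id": np.arange(n)}
    for i in range(model.n):
        data[f"x{i + 1}"] = presence[:, i].astype(int)
    data["diseased"] = diseased.astype(int)
    return pd.DataFrame(data)


def sample_cross_sectional(model: FactorModel, n: int, seed: int, factor: int = 1) -> StudyDraw:
    """Draw one cross-sectional 2x2 table for one factor of a model.

    Individuals are sampled with :func:`sample_population`; the table
    cross-tabulates presence of ``factor`` against disease.
    """
    frame = sample_population(model, n, seed)
    present = frame[f"x{factor}"].to_numpy(dtype=bool)
    diseased = frame["diseased"].to_numpy(dtype=bool)
    table = ContingencyTable2x2(
        a=int((present & diseased).sum()),
        b=int((present & ~diseased).sum()),
        c=int((~present & diseased).sum()),
        d=int((~present & ~diseased).sum()),
    )
    pe, pn = cohort_rates(model, factor)
    pd_, pc = casecontrol_rates(model, factor)
    truth = RateSet(pe=pe, pn=pn, pd=pd_, pc=pc, m=population_incidence(model))
    return StudyDraw(design="cross_sectional", table=table, seed=seed, true_rates=truth)
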