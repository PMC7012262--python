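"""Case-control <-> cohort conversion identities and latent recovery."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riskbridge import (
    ContingencyTable2x2,
    RateSet,
    cc_to_cohort,
    cohort_to_cc,
    odds_ratio,
    rates_from_table,
    recover_cofactors,
    recover_latent,
    rr_from_cc,
)
from riskbridge.exceptions import BoundaryValueError, InfeasibleModelError

probs = st.floats(0.0, 1.0, allow_nan=False)
open_probs = st.floats(0.001, 0.999)


def latent_to_rates(f1, fd, fe):
    """Independent oracle: the defining conditional-probability relations."""
    pd_ = (f1 - fd) / (f1 - fd + fe)
    pc = fd / (1.0 - f1 - fe + fd)
    m = f1 - fd + fe
    return pd_, pc, m


class TestCcToCohort:
    def test_no_association_gives_population_incidence(self):
        for p in (0.1, 0.5, 0.9):
            for m in (0.01, 0.3, 0.99):
                pe, pn = cc_to_cohort(p, p, m)
                assert pe == pytest.approx(m, abs=1e-12)
                assert pn == pytest.approx(m, abs=1e-12)

    def test_strong_exposure_scenario(self):
        pe, pn = cc_to_cohort(0.95, 0.05, 0.05)
        assert pe == pytest.approx(0.5, abs=1e-12)
        assert pn == pytest.approx(0.0025 / 0.905, abs=1e-12)

    def test_all_cases_exposed_gives_zero_unexposed_incidence(self):
        _, pn = cc_to_cohort(1.0, 0.5, 0.1)
        assert pn == 0.0

    def test_agrees_with_large_table_oracle(self):
        # a 10^6-person cross-sectional table with Pd=0.95, Pc=0.05, m=0.05
        a, c = 47500, 2500          # 50,000 cases, 95% exposed
        b, d = 47500, 902500        # 950,000 non-cases, 5% exposed
        r = rates_from_table(ContingencyTable2x2(a, b, c, d))
        pe, pn = cc_to_cohort(r.pd, r.pc, r.m)
        assert pe == pytest.approx(r.pe, abs=1e-12)
        assert pn == pytest.approx(r.pn, abs=1e-12)

    def test_undefined_denominators_raise(self):
        with pytest.raises(BoundaryValueError):
            cc_to_cohort(0.0, 0.0, 0.5)  # nobody exposed
        with pytest.raises(BoundaryValueError):
            cc_to_cohort(1.0, 1.0, 0.5)  # nobody unexposed


class TestCohortToCc:
    def test_null_and_deterministic_cases(self):
        assert cohort_to_cc(0.3, 0.3, 0.7) == pytest.approx((0.7, 0.7, 0.3), abs=1e-12)
        assert cohort_to_cc(1.0, 0.0, 0.2) == pytest.approx((1.0, 0.0, 0.2), abs=1e-12)

    def test_inverts_worked_example(self):
        pd_, pc, m = cohort_to_cc(0.5, 0.0025 / 0.905, 0.095)
        assert pd_ == pytest.approx(0.95, abs=1e-10)
        assert pc == pytest.approx(0.05, abs=1e-10)
        assert m == pytest.approx(0.05, abs=1e-10)

    def test_degenerate_incidence_raises(self):
        with pytest.raises(BoundaryValueError):
            cohort_to_cc(0.0, 0.0, 0.5)
        with pytest.raises(BoundaryValueError):
            cohort_to_cc(1.0, 1.0, 0.5)


@settings(derandomize=True, max_examples=300)
@given(open_probs, open_probs, open_probs)
def test_round_trip_cohort_cc_cohort(pe, pn, q):
    """cohort -> case-control -> cohort is the identity."""
    pd_, pc, m = cohort_to_cc(pe, pn, q)
    pe2, pn2 = cc_to_cohort(pd_, pc, m)
    assert pe2 == pytest.approx(pe, abs=1e-10)
    assert pn2 == pytest.approx(pn, abs=1e-10)


class TestRrFromCc:
    def test_matches_direct_ratio(self):
        assert rr_from_cc(0.95, 0.05, 0.05) == pytest.approx(
            0.5 / (0.0025 / 0.905), rel=1e-12
        )

    def test_null_association_for_every_incidence(self):
        for m in (0.0, 0.001, 0.3, 0.9):
            assert rr_from_cc(0.4, 0.4, m) == pytest.approx(1.0, abs=1e-12)

    def test_zero_incidence_returns_odds_ratio_exactly(self):
        r = RateSet(pe=0.0, pn=0.0, pd=0.95, pc=0.05, m=0.0)
        assert rr_from_cc(0.95, 0.05, 0.0) == odds_ratio(r)

    def test_all_cases_exposed_raises(self):
        with pytest.raises(BoundaryValueError):
            rr_from_cc(1.0, 0.5, 0.1)

    @settings(derandomize=True, max_examples=200)
    @given(open_probs, st.floats(0.02, 0.98))
    def test_rare_disease_limit(self, pd_, pc):
        """RR converges to OR as the disease becomes rare.

        The leading error term is m*(Pd-Pc)*(1/Pc + 1/(1-Pc)), so the
        1e-6 bound at m=1e-8 needs Pc bounded away from the edges.
        """
        or_ = pd_ * (1 - pc) / (pc * (1 - pd_))
        rr = rr_from_cc(pd_, pc, 1e-8)
        assert abs(rr - or_) / or_ < 1e-6

    @settings(derandomize=True, max_examples=200)
    @given(open_probs, open_probs, open_probs)
    def test_or_bounds_rr_when_cases_more_exposed(self, pd_, pc, m):
        if pd_ < pc:
            pd_, pc = pc, pd_
        or_ = pd_ * (1 - pc) / (pc * (1 - pd_))
        assert rr_from_cc(pd_, pc, m) <= or_ * (1 + 1e-9)


class TestRecoverLatent:
    def test_null_association_closed_form(self):
        for p, m in [(0.3, 0.1), (0.7, 0.5)]:
            t = recover_latent(p, p, m)
            assert t.f1 == pytest.approx(p, abs=1e-12)
            assert t.fd == pytest.approx(p * (1 - m), abs=1e-12)
            assert t.fe == pytest.approx(m * (1 - p), abs=1e-12)

    def test_worked_example(self):
        t = recover_latent(0.95, 0.05, 0.05)
        assert t.f1 == pytest.approx(0.095, abs=1e-12)
        assert t.fd == pytest.approx(0.0475, abs=1e-12)
        assert t.fe == pytest.approx(0.0025, abs=1e-12)
        # back-substitution through the defining relations
        assert latent_to_rates(t.f1, t.fd, t.fe) == pytest.approx(
            (0.95, 0.05, 0.05), abs=1e-12
        )

    def test_no_disease_mass(self):
        t = recover_latent(0.4, 0.25, 0.0)
        assert (t.f1, t.fd, t.fe) == (0.25, 0.25, 0.0)

    @settings(derandomize=True, max_examples=300)
    @given(open_probs, open_probs, open_probs)
    def test_back_substitution_identity(self, pd_, pc, m):
        """Recovered latent masses reproduce (Pd, Pc, m) exactly."""
        t = recover_latent(pd_, pc, m)
        assert t.m == pytest.approx(m, abs=1e-12)
        pd2, pc2, m2 = latent_to_rates(t.f1, t.fd, t.fe)
        assert (pd2, pc2, m2) == pytest.approx((pd_, pc, m), abs=1e-12)


class TestRecoverCofactors:
    def test_double_root(self):
        assert recover_cofactors(0.75, 0.25) == pytest.approx((0.5, 0.5), abs=1e-12)

    def test_distinct_roots(self):
        # forward: f2=0.3, f3=0.6 gives Pe=1-(0.7)(0.4)=0.72, Pn=0.18
        assert recover_cofactors(0.72, 0.18) == pytest.approx((0.3, 0.6), abs=1e-12)

    def test_infeasible_rates(self):
        with pytest.raises(InfeasibleModelError):
            recover_cofactors(0.1, 0.2)

    @settings(derandomize=True, max_examples=200)
    @given(open_probs, open_probs)
    def test_inverts_forward_model(self, f2, f3):
        pe = 1 - (1 - f2) * (1 - f3)
        pn = f2 * f3
        lo, hi = recover_cofactors(pe, pn)
        assert (lo, hi) == pytest.approx(tuple(sorted((f2, f3))), abs=1e-7)
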