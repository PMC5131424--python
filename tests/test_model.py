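"""CoDe and Siler curve evaluation: closed forms, continuity, collapse."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from codemort import (CoDeParams, InputError, ParameterDomainError,
                      SilerParams, asymptote, code_q, code_schedule,
                      continuity_constants, siler_m)
from conftest import random_code_params

# frozen high-precision evaluations of the printed closed forms
C1_ORACLE = 0.00167998620836293530715873002361
C2_ORACLE = -0.0125476560680598289204835463991
SILER60_ORACLE = 0.0145338355342789355998878836127


def params_strategy():
    return st.builds(
        CoDeParams,
        A=st.floats(1e-4, 0.05),
        B=st.floats(0.1, 5.0),
        a=st.floats(1e-5, 0.01),
        b1=st.floats(0.05, 0.3),
        b2=st.floats(0.05, 0.3),
        b3=st.floats(0.05, 0.3),
        M=st.floats(70.0, 95.0),
    )


class TestContinuityConstants:
    def test_equal_first_two_slopes_zero_c1(self):
        p = CoDeParams(A=0.01, B=1, a=0.001, b1=0.1, b2=0.1, b3=0.12, M=80)
        cc = continuity_constants(p)
        assert cc.c1 == 0.0

    def test_full_collapse_zero_constants(self):
        p = CoDeParams(A=0.01, B=1, a=0.001, b1=0.1, b2=0.1, b3=0.1, M=80)
        cc = continuity_constants(p)
        assert cc.c1 == 0.0
        assert cc.c2 == 0.0

    def test_against_arithmetic_oracle(self):
        p = CoDeParams(A=0.01, B=1, a=0.001, b1=0.10, b2=0.12, b3=0.14,
                       M=80, h=30, g=0.7)
        cc = continuity_constants(p)
        assert cc.c1 == pytest.approx(C1_ORACLE, abs=1e-15)
        assert cc.c2 == pytest.approx(C2_ORACLE, abs=1e-15)

    def test_invalid_parameter_names_offending_field(self):
        with pytest.raises(ParameterDomainError, match="b2"):
            CoDeParams(A=0.01, B=1, a=0.001, b1=0.1, b2=-0.1, b3=0.1, M=80)


class TestCodeQ:
    def test_equal_slopes_single_logistic_value_at_mode(self):
        p = CoDeParams(A=1e-300, B=1, a=0.0, b1=0.1, b2=0.1, b3=0.1, M=80)
        # at x = M the logistic equals b/(1 + b/g) = 0.1/(1 + 1/7)
        assert code_q(80.0, p) == pytest.approx(0.0875, abs=1e-12)

    def test_young_age_term_alone(self):
        # A/(x+B) dominates when every other component is negligible
        p = CoDeParams(A=0.01, B=1.0, a=0.0, b1=0.5, b2=0.5, b3=0.5, M=105)
        assert code_q(0.0, p) == pytest.approx(0.01, rel=1e-6)
        assert code_q(1.0, p) == pytest.approx(0.005, rel=1e-6)

    def test_term_by_term_oracle_on_late_preset(self, late_params):
        p = late_params
        cc = continuity_constants(p)
        for x in (0.0, 16.0, p.M - p.h, p.M, 100.0):
            young = p.A / (x + p.B)
            z = math.exp(x - p.m_hump)
            adolescent = p.a * z / (1.0 + z)
            if x <= p.M - p.h:
                b, off = p.b1, 0.0
            elif x <= p.M:
                b, off = p.b2, cc.c1
            else:
                b, off = p.b3, cc.c2
            e = math.exp(b * (x - p.M))
            expected = young + adolescent + b * e / (1 + (b / p.g) * e) + off
            assert code_q(x, p) == pytest.approx(expected, rel=1e-12)

    def test_negative_age_rejected(self, late_params):
        with pytest.raises(ParameterDomainError):
            code_q(-1.0, late_params)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(params_strategy())
    def test_continuous_at_both_breakpoints(self, p):
        eps = 1e-9
        for x0 in (p.M - p.h, p.M):
            assert abs(code_q(x0 - eps, p) - code_q(x0 + eps, p)) < 1e-9

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.floats(0.05, 0.3), st.floats(70, 95))
    def test_collapse_to_single_logistic(self, b, M):
        p = CoDeParams(A=0.01, B=1.0, a=0.001, b1=b, b2=b, b3=b, M=M)
        x = np.linspace(0, 110, 223)
        z = b * np.exp(b * (x - M))
        single = p.A / (x + p.B) + p.a / (1 + np.exp(-(x - 16))) + z / (1 + z / p.g)
        np.testing.assert_allclose(code_q(x, p), single, atol=1e-12)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(params_strategy())
    def test_regime_terms_bounded_and_monotone(self, p):
        from codemort.model import _logistic_term

        x = np.linspace(0, 120, 241)
        assert np.all(np.asarray(code_q(x, p)) >= 0)
        # each logistic regime term lies in (0, g) and rises strictly
        for b in (p.b1, p.b2, p.b3):
            term = _logistic_term(x, b, p.M, p.g)
            assert np.all((term > 0) & (term < p.g))
            assert np.all(np.diff(term) > 0)
        # the adolescent term increases and approaches the background level
        from scipy.special import expit
        # nondecreasing (expit saturates to exactly a in float at old ages)
        ado = p.a * expit(x - p.m_hump)
        assert np.all(np.diff(ado) >= 0)
        assert ado[-1] == pytest.approx(p.a, rel=1e-10)


class TestCodeSchedule:
    def test_elementwise_consistency(self, late_params):
        s = code_schedule(np.arange(101), late_params)
        assert len(s) == 101
        assert s.value_kind == "probability"
        assert s.values[80] == pytest.approx(code_q(80.0, late_params))

    def test_single_age_grid(self, late_params):
        s = code_schedule(np.array([0]), late_params)
        assert len(s) == 1

    def test_empty_grid_rejected(self, late_params):
        with pytest.raises(InputError):
            code_schedule(np.array([], dtype=int), late_params)

    def test_monotone_nondecreasing_in_adulthood(self, late_params):
        s = code_schedule(np.arange(121), late_params)
        adult = s.ages >= 30
        assert np.all(np.diff(s.values[adult]) >= -1e-12)

    def test_values_above_one_clipped_with_warning(self):
        # b2 >> b3 inflates c2, pushing old-age values above 1
        p = CoDeParams(A=0.01, B=1, a=0.05, b1=0.02, b2=0.5, b3=0.3, M=80,
                       g=1.0)
        assert asymptote(p) > 1
        with pytest.warns(RuntimeWarning, match="clip"):
            s = code_schedule(np.arange(121), p)
        assert s.values.max() == 1.0
        # the scalar op still returns the raw sum
        assert code_q(120.0, p) > 1.0


class TestAsymptote:
    def test_collapse_gives_g(self):
        p = CoDeParams(A=0.01, B=1, a=0.0, b1=0.1, b2=0.1, b3=0.1, M=80)
        assert asymptote(p) == pytest.approx(0.7, abs=1e-15)

    def test_additive_background(self):
        p = CoDeParams(A=0.01, B=1, a=0.01, b1=0.1, b2=0.1, b3=0.1, M=80)
        assert asymptote(p) == pytest.approx(0.71, abs=1e-15)

    def test_numerical_limit(self, rng):
        # the young-age term decays like A/x, so the limit is approached
        # only algebraically; 1e9 pushes it below the tolerance
        for _ in range(5):
            p = random_code_params(rng)
            assert abs(code_q(1e9, p) - asymptote(p)) < 1e-9


class TestSiler:
    def test_senescent_term_at_mode(self):
        s = SilerParams(a1=0.0, a2=0.2, c=0.0, b=0.1, M=80)
        assert siler_m(80.0, s) == pytest.approx(0.1, abs=1e-15)

    def test_infant_term_at_zero_with_vanishing_slope(self):
        s = SilerParams(a1=0.05, a2=0.2, c=0.0, b=1e-12, M=80)
        assert siler_m(0.0, s) == pytest.approx(0.05, abs=1e-12)

    def test_against_arithmetic_oracle(self):
        s = SilerParams(a1=0.05, a2=0.2, c=0.001, b=0.1, M=80)
        assert siler_m(60.0, s) == pytest.approx(SILER60_ORACLE, rel=1e-14)

    def test_strictly_positive(self):
        s = SilerParams(a1=0.05, a2=0.2, c=0.001, b=0.1, M=80)
        x = np.linspace(0, 120, 50)
        assert np.all(np.asarray(siler_m(x, s)) > 0)


class TestSerialization:
    def test_params_dict_round_trip(self, late_params):
        d = late_params.to_dict()
        assert set(d) == {"A", "B", "a", "b1", "b2", "b3", "M", "h", "g",
                          "m_hump"}
        assert CoDeParams.from_dict(d) == late_params

    def test_unknown_key_rejected(self):
        with pytest.raises(ParameterDomainError):
            CoDeParams.from_dict({"A": 0.01, "Z": 1.0})

    def test_schedule_invariants_enforced(self):
        with pytest.raises(InputError):
            # non unit-spaced ages
            from codemort import MortalitySchedule
            MortalitySchedule(ages=np.array([0, 2, 4]),
                              values=np.array([0.1, 0.1, 0.1]))
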