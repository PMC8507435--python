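"""Cellular status: quotas, Q10 rates, nutrient statuses, respiration,
voiding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as sts

from planktos import status as st


class TestQuotas:
    def test_direct_ratio(self):
        NC, PC = st.quotas(1.0, 0.1, 0.02)
        assert NC == pytest.approx(0.1)
        assert PC == pytest.approx(0.02)

    def test_quota_at_optimum(self, diatom):
        NC, _ = st.quotas(2.0, diatom.NCopt * 2.0, 0.01)
        assert NC == pytest.approx(diatom.NCopt)

    def test_dormant_sentinel_no_division(self):
        NC, PC, SC = st.quotas(0.0, 0.1, 0.1, 0.1)
        assert NC == 0.0 and PC == 0.0 and SC == 0.0


class TestTemperatureScaling:
    def test_reference_temperature_returns_reference_rate(self):
        assert st.temperature_scaled_rate(0.81, 20.0, 2.0, 20.0) == 0.81

    def test_plus_ten_degrees_multiplies_by_q10(self):
        assert st.temperature_scaled_rate(0.5, 30.0, 2.0, 20.0) == \
            pytest.approx(1.0)

    def test_minus_ten_degrees_divides_by_q10(self):
        assert st.temperature_scaled_rate(0.5, 10.0, 2.0, 20.0) == \
            pytest.approx(0.25)

    @given(sts.floats(-5, 25), sts.floats(-5, 25))
    @settings(max_examples=50, deadline=None)
    def test_exactly_multiplicative(self, t1, t2):
        r = st.temperature_scaled_rate(0.81, 20.0 + t1 + t2, 2.0, 20.0)
        expected = 0.81 * 2.0 ** ((t1 + t2) / 10.0)
        assert r == pytest.approx(expected, rel=1e-12)


class TestNitrogenStatus:
    def test_one_at_optimal_quota(self, diatom):
        assert st.nitrogen_status(diatom.NCopt, diatom.NCmin,
                                  diatom.NCopt) == 1.0

    def test_zero_at_minimum_quota(self, diatom):
        assert st.nitrogen_status(diatom.NCmin, diatom.NCmin,
                                  diatom.NCopt) == 0.0

    def test_half_at_midpoint(self, diatom):
        mid = 0.5 * (diatom.NCmin + diatom.NCopt)
        assert st.nitrogen_status(mid, diatom.NCmin, diatom.NCopt) == \
            pytest.approx(0.5)

    def test_saturates_above_optimum(self, diatom):
        assert st.nitrogen_status(diatom.NCmax, diatom.NCmin,
                                  diatom.NCopt) == 1.0


class TestPhosphorusStatus:
    def test_endpoints(self, diatom):
        assert st.phosphorus_status(diatom.PCopt, diatom.PCmin,
                                    diatom.PCopt) == pytest.approx(1.0,
                                                                   abs=1e-6)
        assert st.phosphorus_status(diatom.PCmin, diatom.PCmin,
                                    diatom.PCopt) == pytest.approx(0.0,
                                                                   abs=1e-6)

    def test_monotone_nondecreasing_on_grid(self, diatom):
        pc = np.linspace(0.0, 2 * diatom.PCopt, 100)
        v = st.phosphorus_status(pc, diatom.PCmin, diatom.PCopt)
        assert np.all(np.diff(v) >= -1e-15)

    def test_sigmoid_flat_near_ends(self, diatom):
        # near-zero slope at both ends distinguishes the sigmoid from
        # the linear nitrogen ramp (polyphosphate storage)
        lo, hi = diatom.PCmin, diatom.PCopt
        eps = (hi - lo) * 1e-3
        slope_lo = (st.phosphorus_status(lo + eps, lo, hi)
                    - st.phosphorus_status(lo, lo, hi)) / eps
        mid = 0.5 * (lo + hi)
        slope_mid = (st.phosphorus_status(mid + eps, lo, hi)
                     - st.phosphorus_status(mid, lo, hi)) / eps
        assert slope_lo < 0.1 * slope_mid


class TestSilicaStatus:
    def test_zero_without_external_silica(self):
        assert st.silica_status(0.0, 0.028) == 0.0

    def test_half_saturation(self):
        assert st.silica_status(0.028, 0.028) == pytest.approx(0.5)

    def test_saturation_limit(self):
        assert st.silica_status(1e6, 0.028) == pytest.approx(1.0, abs=1e-4)


class TestLiebigAndBounds:
    @given(sts.floats(0, 0.4), sts.floats(0, 0.1), sts.floats(0, 3))
    @settings(max_examples=200, deadline=None)
    def test_statuses_bounded_and_liebig(self, nc, pc, si):
        NCu = st.nitrogen_status(nc, 0.07, 0.15)
        PCu = st.phosphorus_status(pc, 0.005, 0.02)
        SCu = st.silica_status(si, 0.028)
        for v in (NCu, PCu, SCu):
            assert 0.0 <= v <= 1.0
        assert st.limiting_status(NCu, PCu, SCu) == min(NCu, PCu, SCu)


class TestRespiration:
    def test_basal_only_when_no_uptake(self):
        BR = st.basal_respiration(0.81, 0.05)
        assert st.total_respiration(0, 0, 0, 0, BR, 1.71, 0.5, 0.3) == BR

    def test_linearity_in_nitrate_uptake(self):
        BR = 0.04
        base = st.total_respiration(0.1, 0.02, 0, 0, BR, 1.71, 0.5, 0.3)
        doubled = st.total_respiration(0.2, 0.02, 0, 0, BR, 1.71, 0.5, 0.3)
        assert doubled - base == pytest.approx(1.71 * 0.1)

    def test_heterotroph_term_sum(self):
        # protozoo: no dissolved uptake, only assimilation costs
        BR, AR, SDA = 0.04, 0.5, 0.3
        assN, assC = 0.08, 0.5
        expected = AR * assN + SDA * assC + BR
        assert st.total_respiration(0.0, 0.0, assN, assC, BR, 1.71, AR,
                                    SDA) == pytest.approx(expected)


class TestVoiding:
    def test_no_excess_at_exact_maximum(self, diatom):
        C = 1.0
        _, _, _, cv, nout, pout = st.void_excess(C, diatom.NCmax * C,
                                                 diatom.PCopt * C, diatom)
        assert cv == 0.0 and nout == 0.0 and pout == 0.0

    def test_nitrogen_excess_voided_and_conserved(self, diatom):
        C = 1.0
        N = 1.1 * diatom.NCmax
        C2, N2, P2, cv, nout, pout = st.void_excess(C, N, diatom.PCopt,
                                                    diatom)
        assert N2 / C2 == pytest.approx(diatom.NCmax)
        assert N2 + nout == pytest.approx(N)  # mass balance exact

    def test_low_nitrogen_voids_carbon(self, diatom):
        C = 1.0
        N = 0.5 * diatom.NCmin
        C2, N2, _, cv, nout, _ = st.void_excess(C, N, diatom.PCopt, diatom)
        assert N2 / C2 == pytest.approx(diatom.NCmin)
        assert C2 + cv == pytest.approx(C)

    @given(sts.floats(0.01, 2.0), sts.floats(0.0, 0.5), sts.floats(0.0, 0.1))
    @settings(max_examples=100, deadline=None)
    def test_voiding_respects_caps_and_mass(self, C, N, P):
        from planktos.params import default_parameters
        p = default_parameters()["green"]
        C2, N2, P2, cv, nout, pout = st.void_excess(C, N, P, p)
        assert C2 + cv == pytest.approx(C)
        assert N2 + nout == pytest.approx(N)
        assert P2 + pout == pytest.approx(P)
        if C2 > st.C_FLOOR:
            assert N2 / C2 <= p.NCmax * (1 + 1e-9)
            assert P2 / C2 <= p.PCmax * (1 + 1e-9)
            assert N2 / C2 >= p.NCmin * (1 - 1e-9)
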