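"""Closed-form factor functions against independent arithmetic oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from radioresponse import RadiobiologyParams, kernels


class TestOER:
    @pytest.mark.parametrize(
        "pO2, m, k, expected",
        [
            (0.0, 3.0, 3.0, 1.0),  # anoxic limit
            (3.0, 3.0, 3.0, 2.0),  # pO2 = k gives the half-rise (m+1)/2
            (1e6, 3.0, 3.0, 3.0),  # plateau at m
        ],
    )
    def test_anchors(self, pO2, m, k, expected):
        assert kernels.oer(pO2, m, k) == pytest.approx(expected, rel=1e-5)

    def test_bounded_and_strictly_increasing(self):
        grid = np.linspace(0.0, 100.0, 500)
        vals = kernels.oer(grid)
        assert np.all(vals >= 1.0) and np.all(vals <= 3.0)
        assert np.all(np.diff(vals) > 0)

    def test_negative_po2_rejected(self):
        with pytest.raises(ValueError):
            kernels.oer(-0.1)


class TestSurvivalFractions:
    def test_zero_dose_is_unity(self, params):
        assert kernels.survival_fraction_tumour(0.0, 5.0, params) == 1.0
        assert kernels.survival_fraction_normal(0.0, params) == 1.0

    def test_tumour_printed_convention_value(self, params):
        # OER plateau: effective dose m*d*OER = 3*2*3 = 18 Gy
        expected = math.exp(-(0.273 * 18.0 + 0.045 * 18.0**2))
        got = kernels.survival_fraction_tumour(2.0, 1e7, params)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_tumour_effective_dose_convention_recovers_plain_lq(self, params):
        p = params.replace(oer_convention="effective_dose")
        # fully oxygenated: effective dose d*OER/m -> d
        expected = math.exp(-(0.273 * 2.0 + 0.045 * 4.0))  # ~0.4838
        got = kernels.survival_fraction_tumour(2.0, 1e9, p)
        assert got == pytest.approx(expected, rel=1e-6)
        # anoxic: effective dose d/m
        deff = 2.0 / 3.0
        expected0 = math.exp(-(0.273 * deff + 0.045 * deff**2))
        assert kernels.survival_fraction_tumour(2.0, 0.0, p) == pytest.approx(
            expected0, rel=1e-12
        )

    def test_hypoxic_cells_survive_more(self, params):
        lo = kernels.survival_fraction_tumour(2.0, 1.0, params)
        hi = kernels.survival_fraction_tumour(2.0, 40.0, params)
        assert lo > hi

    def test_normal_matches_expanded_lq(self):
        p = RadiobiologyParams(alpha_n=0.273, beta_n=0.045)
        expected = math.exp(-(0.273 * 2 + 0.045 * 4))
        assert kernels.survival_fraction_normal(2.0, p) == pytest.approx(
            expected, rel=1e-12
        )

    @given(
        d=st.floats(0.0, 10.0),
        alpha=st.floats(0.01, 1.0),
        beta=st.floats(0.001, 0.2),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_ratio_form_identity(self, d, alpha, beta):
        """exp(-a d (1 + d b/a)) == exp(-a d - b d^2) to 1e-12."""
        p = RadiobiologyParams(alpha_n=alpha, beta_n=beta)
        ratio_form = math.exp(-alpha * d * (1.0 + d * beta / alpha))
        assert kernels.survival_fraction_normal(d, p) == pytest.approx(
            ratio_form, rel=1e-12, abs=1e-15
        )

    def test_fractionation_identity(self, params):
        """n fractions of d at fixed pO2 equal SF(d)^n (full repair)."""
        sf1 = kernels.survival_fraction_tumour(1.5, 5.0, params)
        sf_total = sf1**4
        seq = 1.0
        for _ in range(4):
            seq *= kernels.survival_fraction_tumour(1.5, 5.0, params)
        assert seq == pytest.approx(sf_total, rel=1e-12)

    def test_monotone_decreasing_in_dose(self, params):
        doses = np.linspace(0, 10, 50)
        sf = kernels.survival_fraction_tumour(doses, 5.0, params)
        assert np.all(np.diff(sf) < 0)
        assert np.all((sf > 0) & (sf <= 1))

    def test_negative_dose_rejected(self, params):
        with pytest.raises(ValueError):
            kernels.survival_fraction_tumour(-1.0, 5.0, params)


class TestProliferationFactor:
    def test_inflection_value(self, params):
        assert kernels.proliferation_factor(26.3, params) == pytest.approx(
            1.0 / math.e, rel=1e-12
        )

    def test_asymptote_and_anoxia(self, params):
        assert kernels.proliferation_factor(1e6, params) == pytest.approx(1.0)
        expected = math.exp(-math.exp(0.075 * 26.3))
        assert kernels.proliferation_factor(0.0, params) == pytest.approx(
            expected, rel=1e-12
        )

    def test_monotone_and_bounded(self, params):
        grid = np.linspace(0, 80, 200)
        pf = kernels.proliferation_factor(grid, params)
        assert np.all(np.diff(pf) > 0)
        assert np.all((pf >= 0) & (pf <= params.C))


class TestStepFactors:
    def test_angiogenesis_anchors(self):
        assert kernels.angiogenesis_factor(612.0, 0.0) == 1.0
        assert kernels.angiogenesis_factor(612.0, 612.0) == pytest.approx(2.0)
        assert kernels.angiogenesis_factor(612.0, 1.0) == pytest.approx(
            math.exp(math.log(2) / 612.0), rel=1e-12
        )

    def test_resorption_anchors(self):
        assert kernels.resorption_fraction(168.0, 0.0) == 0.0
        assert kernels.resorption_fraction(168.0, 168.0) == pytest.approx(0.5)
        assert kernels.resorption_fraction(168.0, 1.0) == pytest.approx(
            1.0 - math.exp(-math.log(2) / 168.0), rel=1e-12
        )

    def test_repopulation_switch(self, params):
        assert kernels.repopulation_factor(100.0, 0.0, params) == 1.0
        early = kernels.repopulation_factor(100.0, 1.0, params)
        late = kernels.repopulation_factor(400.0, 1.0, params)
        assert early == pytest.approx(math.exp(math.log(2) / 1200.0), rel=1e-12)
        assert late == pytest.approx(math.exp(math.log(2) / 120.0), rel=1e-12)
        assert late > early

    def test_invalid_times_rejected(self):
        with pytest.raises(ValueError):
            kernels.angiogenesis_factor(0.0, 1.0)
        with pytest.raises(ValueError):
            kernels.resorption_fraction(-1.0, 1.0)


def test_all_factors_match_brute_force_oracle():
    """Spot-check every closed form against direct math evaluation to 1e-12
    on 100 random parameter draws."""
    rng = np.random.default_rng(42)
    for _ in range(100):
        m = rng.uniform(1.0, 5.0)
        k = rng.uniform(0.5, 10.0)
        pO2 = rng.uniform(0.0, 80.0)
        d = rng.uniform(0.0, 8.0)
        a_t, b_t = rng.uniform(0.05, 0.5), rng.uniform(0.005, 0.1)
        B, M, C = rng.uniform(0.01, 0.2), rng.uniform(5, 50), rng.uniform(0.3, 1.0)
        ta, tr = rng.uniform(100, 2000), rng.uniform(24, 500)
        p = RadiobiologyParams(
            alpha_t=a_t, beta_t=b_t, m=m, k=k, B=B, M=M, C=C, ta=ta, tr=tr
        )
        o = (m * pO2 + k) / (pO2 + k)
        assert kernels.oer(pO2, m, k) == pytest.approx(o, rel=1e-12)
        deff = m * d * o
        assert kernels.survival_fraction_tumour(d, pO2, p) == pytest.approx(
            math.exp(-a_t * deff - b_t * deff**2), rel=1e-12
        )
        assert kernels.proliferation_factor(pO2, p) == pytest.approx(
            C * math.exp(-math.exp(-B * (pO2 - M))), rel=1e-12, abs=1e-300
        )
        assert kernels.angiogenesis_factor(ta, 1.0) == pytest.approx(
            math.exp(math.log(2) / ta), rel=1e-12
        )
        assert kernels.resorption_fraction(tr, 1.0) == pytest.approx(
            1 - math.exp(-math.log(2) / tr), rel=1e-12
        )
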