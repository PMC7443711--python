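"""Optical-property models: printed anchors, hand-derived values, shape laws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paovox import optics


class TestPowerLaws:
    @pytest.mark.parametrize(
        "fn, at500, at1000",
        [
            (optics.epidermis_mu_s_prime, 68.7, 30.744111186375854),
            (optics.dermis_mu_s_prime, 45.3, 18.499817648642015),
            (optics.blood_mu_s_prime, 22.0, 13.92332253367308),
        ],
    )
    def test_reference_and_halved_wavelength(self, fn, at500, at1000):
        assert fn(500.0) == pytest.approx(at500, abs=1e-12)
        assert fn(1000.0) == pytest.approx(at1000, rel=1e-12)

    def test_epidermis_value_at_784(self):
        assert optics.epidermis_mu_s_prime(784.0) == pytest.approx(
            40.77137042342782, rel=1e-12
        )

    @pytest.mark.parametrize(
        "fn",
        [
            optics.epidermis_mu_s_prime,
            optics.dermis_mu_s_prime,
            optics.blood_mu_s_prime,
        ],
    )
    def test_strictly_decreasing_over_excitation_set(self, fn):
        vals = [fn(l) for l in optics.WAVELENGTHS_NM]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert all(np.isfinite(v) and v > 0 for v in vals)

    @pytest.mark.parametrize("fn", [optics.epidermis_mu_s_prime, optics.dermis_mu_s_prime])
    def test_nonpositive_wavelength_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(0.0)


class TestEpidermisAbsorption:
    def test_baseline_exponential_anchor(self):
        # at 154 nm the exponential term is exactly 1: 0.244 + 85.3
        assert optics.skin_baseline_mu_a(154.0) == pytest.approx(85.544)

    def test_pure_melanin_power_law(self):
        assert optics.epidermis_mu_a(800.0, 1.0) == pytest.approx(
            141.98886213168814, rel=1e-12
        )

    def test_two_term_mixture_matches_independent_evaluation(self):
        lam, c_m = 784.0, 0.06
        expected = c_m * 6.6e11 * lam**-3.33 + (1 - c_m) * (
            0.244 + 85.3 * np.exp(-(lam - 154.0) / 66.2)
        )
        assert optics.epidermis_mu_a(lam, c_m) == pytest.approx(expected, rel=1e-12)
        assert expected > 0

    def test_out_of_window_wavelength_rejected(self):
        with pytest.raises(ValueError):
            optics.epidermis_mu_a(154.0, 0.1)
        with pytest.raises(ValueError):
            optics.epidermis_mu_a(1200.0, 0.1)

    def test_bad_melanin_fraction_rejected(self):
        with pytest.raises(ValueError):
            optics.epidermis_mu_a(800.0, 1.5)


class TestBloodAndDermisAbsorption:
    def test_blood_endpoints_are_pure_chromophores(self):
        table = optics.DEFAULT_BLOOD_TABLE
        for lam in optics.WAVELENGTHS_NM:
            a_hb, a_hbo2 = table.lookup(lam)
            assert optics.blood_mu_a(lam, 0.0) == pytest.approx(a_hb)
            assert optics.blood_mu_a(lam, 1.0) == pytest.approx(a_hbo2)

    @given(so2=st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_blood_exactly_linear_in_so2(self, so2):
        lam = 796.0
        lo = optics.blood_mu_a(lam, 0.0)
        hi = optics.blood_mu_a(lam, 1.0)
        chord = (1 - so2) * lo + so2 * hi
        assert optics.blood_mu_a(lam, so2) == pytest.approx(chord, abs=1e-14)

    def test_blood_midpoint_is_mean_of_endpoints(self):
        lam = 808.0
        mid = optics.blood_mu_a(lam, 0.5)
        assert mid == pytest.approx(
            0.5 * (optics.blood_mu_a(lam, 0.0) + optics.blood_mu_a(lam, 1.0))
        )

    def test_unsupported_wavelength_raises_lookup_error(self):
        with pytest.raises(KeyError):
            optics.blood_mu_a(500.0, 0.5)

    def test_dermis_reduces_to_baseline_without_blood(self):
        for lam in optics.WAVELENGTHS_NM:
            assert optics.dermis_mu_a(lam, 0.0, 0.7) == pytest.approx(
                float(optics.skin_baseline_mu_a(lam))
            )

    def test_dermis_pure_blood_endpoint(self):
        lam = 820.0
        assert optics.dermis_mu_a(lam, 1.0, 1.0) == pytest.approx(
            optics.blood_mu_a(lam, 1.0)
        )

    def test_dermis_convex_combination_hand_arithmetic(self):
        lam, c_b, so2 = 796.0, 0.035, 0.7
        expected = c_b * optics.blood_mu_a(lam, so2) + (1 - c_b) * float(
            optics.skin_baseline_mu_a(lam)
        )
        assert optics.dermis_mu_a(lam, c_b, so2) == pytest.approx(expected)


class TestHypodermisAndIndices:
    def test_anchor_values(self):
        lo = optics.hypodermis_props(770.0)
        hi = optics.hypodermis_props(830.0)
        assert (lo.mu_a, lo.mu_s_prime) == pytest.approx((1.1, 20.7))
        assert (hi.mu_a, hi.mu_s_prime) == pytest.approx((1.0, 19.6))
        assert lo.g == 0.8 and lo.n == 1.44

    def test_linear_interpolation_midpoint(self):
        mid = optics.hypodermis_props(800.0)
        assert mid.mu_a == pytest.approx(1.05)
        assert mid.mu_s_prime == pytest.approx((20.7 + 19.6) / 2)

    def test_extrapolation_clamps_with_warning(self):
        with pytest.warns(UserWarning):
            out = optics.hypodermis_props(700.0)
        assert out.mu_a == pytest.approx(1.1)

    def test_dermis_refractive_index(self):
        assert optics.dermis_refractive_index(784.0) == pytest.approx(
            1.3759723516291695, rel=1e-12
        )
        # Cauchy form: decreasing towards the infinite-wavelength limit
        ns = [optics.dermis_refractive_index(l) for l in (700, 800, 900)]
        assert ns[0] > ns[1] > ns[2] > 1.3696

    def test_anisotropy_band(self):
        for lam in optics.WAVELENGTHS_NM:
            g = optics.soft_tissue_anisotropy(lam)
            assert 0.9 < g < 0.95


class TestScatteringConversion:
    def test_blood_example(self):
        assert optics.mu_s_from_reduced(22.0, 0.994) == pytest.approx(
            3666.6666666666665
        )

    def test_identity_and_zero(self):
        assert optics.mu_s_from_reduced(5.0, 0.0) == 5.0
        assert optics.mu_s_from_reduced(0.0, 0.9) == 0.0

    def test_forward_scattering_rejected_at_one(self):
        with pytest.raises(ValueError):
            optics.mu_s_from_reduced(10.0, 1.0)

    @given(
        mu=st.floats(0.0, 1e3, allow_nan=False),
        g=st.floats(0.0, 0.999, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, mu, g):
        assert optics.mu_s_from_reduced(mu, g) * (1 - g) == pytest.approx(
            mu, rel=1e-12, abs=1e-12
        )


def test_layer_properties_positive_and_finite():
    sample = optics.LayerSample(0.2, 0.03, 0.8, 0.2, 2.0, 1.5)
    for tissue in ("epidermis", "dermis", "hypodermis", "vessel"):
        for lam in optics.WAVELENGTHS_NM:
            p = optics.layer_optical_properties(tissue, lam, sample, vessel_so2=0.5)
            assert np.isfinite([p.mu_a, p.mu_s]).all()
            assert p.mu_a > 0 and p.mu_s > 0 and 0 <= p.g < 1 and p.n >= 1
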