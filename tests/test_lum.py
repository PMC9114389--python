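"""Luminescence age models: CAM, MAM, fading and dose-rate assembly."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from paleomolar import lum, synth
from paleomolar.core import AgeEstimate, Quantity, ValidationError


class TestCentralAgeModel:
    def test_identical_grains(self):
        d = lum.DeDistribution(de=np.full(10, 100.0),
                               de_sigma=np.full(10, 5.0))
        r = lum.central_age_model(d)
        assert r.delta_gy == pytest.approx(100.0, rel=1e-6)
        assert r.od == pytest.approx(0.0, abs=0.02)

    def test_od_recovery(self):
        d, truth = synth.gen_de_distribution(burial_dose=500.0, od=0.25,
                                             n=200, rel_err=0.05, seed=2)
        r = lum.central_age_model(d)
        assert r.od == pytest.approx(0.25, abs=0.05)
        assert r.delta_gy == pytest.approx(500.0, rel=0.1)

    def test_od_recovery_unbiased_across_levels(self):
        # 100 simulations per overdispersion level, n = 100 grains
        for od in (0.1, 0.25, 0.4):
            est = []
            for rep in range(100):
                d, _ = synth.gen_de_distribution(burial_dose=500.0, od=od,
                                                 n=100, rel_err=0.03,
                                                 seed=1000 * rep + int(od * 100))
                est.append(lum.central_age_model(d).od)
            assert np.mean(est) == pytest.approx(od, abs=0.03)

    def test_minimum_grain_count(self):
        with pytest.raises(ValidationError):
            lum.central_age_model(lum.DeDistribution([1.0, 2.0], [0.1, 0.1]))

    def test_nonpositive_dose_falls_back_unlogged(self):
        d = lum.DeDistribution(de=[-1.0, 2.0, 3.0, 4.0],
                               de_sigma=[0.5] * 4)
        r = lum.central_age_model(d)
        assert "unlogged" in r.flags
        assert not r.log_space


class TestMinimumAgeModel:
    def test_fully_bleached_equals_cam(self):
        d, _ = synth.gen_de_distribution(burial_dose=500.0, od=0.2, n=100,
                                         bleach_frac=1.0, seed=7)
        mam = lum.minimum_age_model(d, sigma_b=0.2)
        cam = lum.central_age_model(d)
        assert abs(mam.gamma_gy - cam.delta_gy) < \
            max(mam.gamma_sd_gy, cam.delta_sd_gy)

    def test_partial_bleaching_recovers_burial_dose(self):
        d, _ = synth.gen_de_distribution(burial_dose=500.0, od=0.15, n=100,
                                         bleach_frac=0.7,
                                         inflation_max=1500.0, seed=5)
        mam = lum.minimum_age_model(d, sigma_b=0.2)
        assert abs(mam.gamma_gy - 500.0) < 2 * mam.gamma_sd_gy

    def test_mam_never_exceeds_cam(self):
        for seed in (1, 2, 3):
            d, _ = synth.gen_de_distribution(burial_dose=600.0, od=0.3,
                                             n=80, bleach_frac=0.8, seed=seed)
            mam = lum.minimum_age_model(d, sigma_b=0.15)
            cam = lum.central_age_model(d)
            assert mam.gamma_gy <= cam.delta_gy * (1 + 1e-6)

    def test_minimum_grain_count(self):
        with pytest.raises(ValidationError):
            lum.minimum_age_model(lum.DeDistribution([1, 2, 3, 4],
                                                     [0.1] * 4))

    def test_censored_sample_rejected(self):
        d = lum.DeDistribution(de=[100.0] * 6, de_sigma=[250.0] * 6)
        with pytest.raises(ValidationError):
            lum.minimum_age_model(d)

    def test_mam4_runs(self):
        d, _ = synth.gen_de_distribution(burial_dose=500.0, od=0.15, n=100,
                                         bleach_frac=0.7, seed=5)
        r = lum.minimum_age_model(d, sigma_b=0.2, n_params=4)
        assert r.n_params == 4
        assert r.gamma_gy > 0


class TestFading:
    def test_constant_ratios_no_fading(self):
        f, _ = synth.gen_fading_series(0.0)
        g, _se, flags = lum.g_value(f)
        assert g == pytest.approx(0.0, abs=1e-9)

    def test_exact_recovery_of_two_percent(self):
        f, _ = synth.gen_fading_series(2.0)
        g, se, flags = lum.g_value(f)
        assert g == pytest.approx(2.0, abs=1e-9)
        assert not flags

    def test_short_span_flagged(self):
        f = lum.FadingSeries(delays_h=[48, 96, 192], ratios=[1, 0.99, 0.98],
                             tc_h=48)
        _g, _se, flags = lum.g_value(f)
        assert "span_below_one_decade" in flags

    def test_too_few_points(self):
        with pytest.raises(ValidationError):
            lum.g_value(lum.FadingSeries(delays_h=[48, 480],
                                         ratios=[1, 0.98], tc_h=48))

    def test_huntley_lamothe_value_against_root_finder(self):
        corr = lum.fading_correct(AgeEstimate(100.0, 0.0), g=2.0, tc_h=48.0,
                                  n_mc=0)
        kappa = 2.0 / (100.0 * math.log(10.0))

        def resid(t_kyr):
            return t_kyr * (1 - kappa * (math.log(
                t_kyr * lum.HOURS_PER_KYR / 48.0) - 1)) - 100.0

        t_oracle = brentq(resid, 50.0, 500.0, xtol=1e-10)
        assert corr.age == pytest.approx(t_oracle, rel=1e-3)
        assert round(corr.age) == 116

    def test_round_trip(self):
        kappa = 1.5 / (100.0 * math.log(10.0))
        for t_true in (50.0, 120.0, 300.0):
            t_meas = t_true * (1 - kappa * (math.log(
                t_true * lum.HOURS_PER_KYR / 48.0) - 1))
            corr = lum.fading_correct(AgeEstimate(t_meas, 0.0), g=1.5,
                                      tc_h=48.0, n_mc=0)
            assert corr.age == pytest.approx(t_true, rel=1e-3)

    def test_monotone_in_g(self):
        ages = [lum.fading_correct(AgeEstimate(100.0, 0.0), g=g, n_mc=0).age
                for g in (0.0, 1.0, 2.0, 3.0)]
        assert all(a < b for a, b in zip(ages, ages[1:]))
        assert ages[0] == pytest.approx(100.0)

    def test_excessive_fading_outside_validity(self):
        with pytest.raises(ValidationError):
            lum.fading_correct(AgeEstimate(100.0, 0.0), g=15.0, n_mc=0)


class TestDoseRates:
    def test_cosmic_monotone_in_depth(self):
        shallow = lum.cosmic_dose_rate(500.0, 1000.0, 20.0, 103.0)
        deep = lum.cosmic_dose_rate(2000.0, 1000.0, 20.0, 103.0)
        assert 0 < deep < shallow

    def test_cosmic_surface_value_matches_configured_constants(self):
        c = lum.COSMIC_CONSTANTS
        hard0 = c["hard_a"] / ((c["hard_b"] ** c["hard_c"] + c["hard_d"])
                               * c["hard_e"])
        expected = (hard0 + c["soft_amp"]) * (c["F"] + c["J_pole"])
        assert lum.cosmic_dose_rate(0.0, 0.0, 90.0, 291.0) == pytest.approx(
            expected, rel=1e-6)

    def test_site_configuration_small_positive(self):
        # ~20 m limestone at 1.2 g/cm^3 plus 0.3-1.3 m sediment at 2.0
        rates = [lum.cosmic_dose_rate(2000 * 1.2 + h * 100 * 2.0, 1116.0,
                                      20.0, 103.0) for h in (0.3, 1.3)]
        assert 0 < rates[1] < rates[0] < 0.1

    def test_assemble_hand_value(self):
        spec = lum.DoseRateSpec(beta_dry=Quantity(2.0, 0),
                                gamma_dry=Quantity(1.0, 0),
                                internal=Quantity(0.84, 0),
                                water_w=Quantity(0.04, 0),
                                cosmic=Quantity(0.1, 0))
        total = lum.assemble_dose_rate(spec)
        assert total.value == pytest.approx(
            2.0 / 1.05 + 1.0 / 1.0456 + 0.84 + 0.1, abs=1e-3)

    def test_dry_sum_and_water_monotone(self):
        def total(w):
            return lum.assemble_dose_rate(lum.DoseRateSpec(
                beta_dry=Quantity(2.0, 0), gamma_dry=Quantity(1.0, 0),
                internal=Quantity(0.84, 0), water_w=Quantity(w, 0))).value

        assert total(0.0) == pytest.approx(2.0 + 1.0 + 0.84)
        ws = np.linspace(0, 0.3, 7)
        vals = [total(w) for w in ws]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_linear_in_dry_components(self):
        def total(beta):
            return lum.assemble_dose_rate(lum.DoseRateSpec(
                beta_dry=Quantity(beta, 0), gamma_dry=Quantity(0.0, 0),
                internal=Quantity(0.0, 0), water_w=Quantity(0.05, 0))).value

        assert total(4.0) == pytest.approx(2 * total(2.0), rel=1e-12)


class TestLumAge:
    def test_simple_division(self):
        age = lum.lum_age(Quantity(500.0, 0.0), Quantity(5.0, 0.0))
        assert age.age == pytest.approx(100.0)
        assert age.sigma == 0.0

    def test_error_propagation(self):
        age = lum.lum_age(Quantity(515.0, 60.0), Quantity(3.6, 0.4))
        expected = (515 / 3.6) * math.hypot(60 / 515, 0.4 / 3.6)
        assert age.age == pytest.approx(143.06, abs=0.01)
        assert age.sigma == pytest.approx(expected, rel=1e-9)

    def test_zero_de(self):
        assert lum.lum_age(Quantity(0.0, 0.0), Quantity(3.6, 0.4)).age == 0.0

    def test_zero_rate_rejected(self):
        with pytest.raises(ValidationError):
            lum.lum_age(Quantity(500.0, 10.0), Quantity(0.0, 0.0))
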