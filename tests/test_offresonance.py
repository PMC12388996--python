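"""Effective-field geometry, the K(τc) dispersion law, and its inversion."""

import math

import numpy as np
import pytest

from liporelax import (
    DomainError,
    FitFailureError,
    NoiseSpec,
    OffResonanceProfile,
    analyze_offresonance,
    compute_k_factor,
    delta_b,
    fit_k,
    gen_offres_profile,
    invert_k_for_tau,
    model_offres_ratio,
    tilt_angle,
)
from liporelax.reference import OFFRESONANCE_PARAMS


class TestEffectiveFieldGeometry:
    def test_delta_b_vanishes_on_resonance(self, config):
        assert delta_b(0.0, config) == 0.0

    def test_delta_b_equals_b1_at_the_b1_frequency(self, config):
        assert delta_b(config.b1_frequency_hz, config) == pytest.approx(
            config.b1_tesla, rel=1e-12
        )

    def test_delta_b_at_21_kilohertz_is_five_gauss(self, config):
        # (γ/2π) = 42.5774 kHz/mT ⇒ 21.2887 kHz offset ↔ 0.5 mT
        assert delta_b(21288.7, config) == pytest.approx(5.0000e-4, abs=1e-8)

    def test_tilt_is_right_angle_on_resonance(self, config):
        assert tilt_angle(0.0, config) == math.pi / 2

    def test_tilt_is_45_degrees_when_delta_b_equals_b1(self, config):
        assert tilt_angle(config.b1_frequency_hz, config) == pytest.approx(math.pi / 4)

    def test_tilt_vanishes_far_off_resonance(self, config):
        assert tilt_angle(1e12, config) == pytest.approx(0.0, abs=1e-6)

    def test_tilt_is_obtuse_for_negative_offsets(self, config):
        theta = tilt_angle(-config.b1_frequency_hz, config)
        assert theta == pytest.approx(3 * math.pi / 4)


class TestKFactor:
    def test_fast_motion_limit_is_unity(self, config):
        assert compute_k_factor(0.0, config) == 1.0

    def test_reported_pairs_reproduced_within_their_uncertainty(self, config):
        # full-table forward consistency: K(τc_reported) within reported ±
        for name, p in OFFRESONANCE_PARAMS.items():
            k = compute_k_factor(p["tau_c_ns"] * 1e-9, config)
            assert abs(k - p["k"]) <= p["k_err"], name

    def test_fastest_system_rounds_to_the_reported_k(self, config):
        # the 1.8 ns system is the one pair that also matches to 2 decimals
        assert round(compute_k_factor(1.8e-9, config), 2) == 1.22

    def test_slow_motion_asymptote(self, config):
        tau = 1e-3  # ω·τc ≫ 1
        x = (config.omega0 * tau) ** 2
        assert compute_k_factor(tau, config) / x == pytest.approx(12.0 / 16.0, rel=1e-6)

    def test_strict_monotonicity_on_a_dense_grid(self, config):
        taus = np.geomspace(1e-12, 1e-7, 2000)
        ks = compute_k_factor(taus, config)
        assert np.all(np.diff(ks) > 0)

    def test_negative_tau_rejected(self, config):
        with pytest.raises(Exception):
            compute_k_factor(-1e-9, config)


class TestInversion:
    def test_unity_k_maps_to_zero_tau(self, config):
        assert invert_k_for_tau(1.0, config).tau_c_s == 0.0

    @pytest.mark.parametrize("tau", [1e-12, 1e-10, 1e-9, 1e-8, 1e-7])
    def test_round_trip_identity(self, tau, config):
        k = compute_k_factor(tau, config)
        back = invert_k_for_tau(k, config).tau_c_s
        assert back == pytest.approx(tau, rel=1e-9)

    def test_k_below_the_physical_floor_is_a_domain_error(self, config):
        with pytest.raises(DomainError):
            invert_k_for_tau(0.9, config)

    def test_k_beyond_the_bracket_is_a_domain_error(self, config):
        huge = compute_k_factor(1e-5, config)
        with pytest.raises(DomainError):
            invert_k_for_tau(huge, config)

    def test_omega_tau_diagnostic_populated(self, config):
        res = invert_k_for_tau(1.22, config)
        assert res.omega_tau == pytest.approx(config.omega0 * res.tau_c_s)

    def test_regime_warning_above_threshold(self, config):
        with pytest.warns(UserWarning, match="fast-motion"):
            invert_k_for_tau(1.61, config)


class TestRatioModel:
    def test_zero_offset_is_fully_saturated(self, config):
        assert model_offres_ratio(0.0, 1.22, config) == 0.0

    def test_large_offset_approaches_unity(self, config):
        assert model_offres_ratio(1e9, 1.22, config) == pytest.approx(1.0, abs=1e-6)

    def test_half_saturation_by_construction(self, config):
        k = 1.72
        f_half = config.b1_frequency_hz * math.sqrt(k)
        assert model_offres_ratio(f_half, k, config) == pytest.approx(0.5, rel=1e-12)

    def test_monotone_in_offset_and_antitone_in_k(self, config):
        offs = np.geomspace(1e2, 1e6, 200)
        r1 = model_offres_ratio(offs, 1.22, config)
        r2 = model_offres_ratio(offs, 1.72, config)
        assert np.all(np.diff(r1) > 0)
        assert np.all(r2 < r1)


class TestKFit:
    def test_noiseless_profile_recovers_k_exactly(self, config):
        tau = 3.6e-9
        k_true = compute_k_factor(tau, config)
        res = fit_k(gen_offres_profile(tau, config, noise=NoiseSpec(0.0, 0)), config)
        assert res.k == pytest.approx(k_true, abs=1e-6)
        assert not res.below_unity

    def test_two_percent_noise_recovery(self, config):
        # median over 40 seeded repeats, the simulation the 0.05 bound comes from
        k_true = compute_k_factor(1.8e-9, config)
        errs = [
            abs(fit_k(gen_offres_profile(1.8e-9, config, noise=NoiseSpec(0.02, s)),
                      config).k - k_true)
            for s in range(40)
        ]
        assert np.median(errs) < 0.05

    def test_saturated_profile_cannot_constrain_k(self, config):
        offs = np.geomspace(1e6, 1e8, 8)
        profile = OffResonanceProfile(offs, np.ones(8), label="saturated")
        with pytest.raises(FitFailureError, match="saturat"):
            fit_k(profile, config)

    def test_too_few_points_rejected(self, config):
        offs = np.geomspace(1e3, 1e5, 5)
        profile = OffResonanceProfile(offs, model_offres_ratio(offs, 1.5, config))
        with pytest.raises(FitFailureError):
            fit_k(profile, config)


class TestFullAnalysis:
    def test_noiseless_round_trip_through_both_stages(self, config):
        tau = 3.2e-9
        profile = gen_offres_profile(tau, config, noise=NoiseSpec(0.0, 0))
        kfit, taures = analyze_offresonance(profile, config)
        assert kfit.k == pytest.approx(compute_k_factor(tau, config), abs=1e-6)
        assert taures.tau_c_ns == pytest.approx(3.2, abs=1e-4)

    def test_motionless_narrowing_limit(self, config):
        profile = gen_offres_profile(0.0, config, noise=NoiseSpec(0.0, 0))
        kfit, taures = analyze_offresonance(profile, config)
        assert kfit.k == pytest.approx(1.0, abs=1e-6)
        assert taures.tau_c_s == pytest.approx(0.0, abs=1e-12)

    def test_two_percent_noise_tau_recovery(self, config):
        errs = []
        for s in range(10):
            profile = gen_offres_profile(2.8e-9, config, noise=NoiseSpec(0.02, s))
            _, taures = analyze_offresonance(profile, config)
            errs.append(abs(taures.tau_c_ns - 2.8))
        assert np.median(errs) < 0.3
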