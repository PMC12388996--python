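"""Laboratory-frame fitters: exact recovery, noise robustness, invariances."""

import math

import numpy as np
import pytest

from liporelax import (
    CurveKind,
    FitFailureError,
    InvalidParameterError,
    NoiseSpec,
    RelaxationCurve,
    T2MixtureFitResult,
    fit_t1,
    fit_t2_mixture,
    gen_t1_curve,
    gen_t2_decay,
    model_t1,
    model_t2_mixture,
)
from liporelax.relaxometry import results_to_table

# (M0G %, T2G s, T2L s) truth grids covering the reported decompositions
MIXTURES = {
    "ACT": (58.0, 0.184, 0.300),
    "ACT+CBD": (77.0, 0.232, 0.0076),
    "ACT+NG": (86.0, 0.188, 0.118),
    "DOTAP:POPC": (62.0, 0.186, 0.352),
}


class TestT1Model:
    def test_half_recovery_at_ln2_times_t1(self):
        assert model_t1(2.0 * math.log(2), 2.0, 1.0) == pytest.approx(0.5, rel=1e-12)

    def test_zero_time_gives_zero(self):
        assert model_t1(0.0, 2.5, 1.0) == 0.0

    def test_one_t1_of_recovery(self):
        assert model_t1(2.5, 2.5, 1.0) == pytest.approx(0.63212, abs=5e-6)

    def test_nonpositive_t1_rejected(self):
        with pytest.raises(InvalidParameterError):
            model_t1(1.0, 0.0, 1.0)


class TestT2Model:
    def _params(self, g_pct, t2g, t2l, total=1.0):
        return T2MixtureFitResult(
            m0g_percent=g_pct, t2g_s=t2g, m0l_percent=100.0 - g_pct,
            t2l_s=t2l, m0_total=total,
        )

    def test_full_amplitude_at_time_zero(self):
        p = self._params(77.0, 0.232, 0.0076, total=2.5)
        assert model_t2_mixture(0.0, p) == pytest.approx(2.5, rel=1e-12)

    def test_pure_gaussian_reaches_one_over_e(self):
        p = self._params(100.0, 0.2, 0.05, total=1.0)
        assert model_t2_mixture(0.2, p) == pytest.approx(1.0 / math.e, rel=1e-12)

    def test_mixed_evaluation_for_the_act_decomposition(self):
        # 0.58 e^-1 + 0.42 e^(-184/300) evaluated directly
        p = self._params(58.0, 0.184, 0.300)
        assert model_t2_mixture(0.184, p) == pytest.approx(0.440818, abs=5e-6)

    def test_percent_sum_enforced(self):
        with pytest.raises(InvalidParameterError):
            T2MixtureFitResult(m0g_percent=60.0, t2g_s=0.2, m0l_percent=50.0,
                               t2l_s=0.1, m0_total=1.0)


class TestT1Fit:
    def test_noiseless_curve_recovers_exactly(self):
        res = fit_t1(gen_t1_curve(2.5, 1.0, noise=NoiseSpec(0.0, 0)))
        assert res.t1_s == pytest.approx(2.5, abs=1e-6)
        assert res.m0 == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("t1,m0", [(2.5, 1.0), (2.7, 3.0), (0.1, 0.5)])
    def test_fit_inverts_model_over_parameter_grid(self, t1, m0):
        res = fit_t1(gen_t1_curve(t1, m0, noise=NoiseSpec(0.0, 0)))
        assert res.t1_s == pytest.approx(t1, rel=1e-6)
        assert res.m0 == pytest.approx(m0, rel=1e-6)

    def test_one_percent_noise_recovery_within_five_percent(self):
        errs = [
            abs(fit_t1(gen_t1_curve(2.7, noise=NoiseSpec(0.01, s))).t1_s / 2.7 - 1.0)
            for s in range(10)
        ]
        assert np.median(errs) < 0.05

    def test_residual_rms_tracks_injected_noise(self):
        sigma = 0.01
        res = fit_t1(gen_t1_curve(2.5, noise=NoiseSpec(sigma, 5)))
        assert res.residual_rms <= 1.5 * sigma

    def test_constant_curve_is_a_fit_failure(self):
        curve = RelaxationCurve(np.linspace(0, 10, 10), np.zeros(10),
                                CurveKind.SATURATION_RECOVERY, label="flat")
        with pytest.raises(FitFailureError, match="flat"):
            fit_t1(curve)

    def test_wrong_curve_kind_rejected(self):
        curve = gen_t2_decay(77.0, 0.232, 0.0076, noise=NoiseSpec(0.0, 0))
        with pytest.raises(InvalidParameterError):
            fit_t1(curve)


class TestT2MixtureFit:
    @pytest.mark.parametrize("name", list(MIXTURES))
    def test_noiseless_recovery_across_reported_decompositions(self, name):
        g_pct, t2g, t2l = MIXTURES[name]
        res = fit_t2_mixture(gen_t2_decay(g_pct, t2g, t2l, noise=NoiseSpec(0.0, 0)))
        assert res.m0g_percent == pytest.approx(g_pct, abs=0.1)
        assert res.t2g_s == pytest.approx(t2g, rel=1e-3)
        assert res.t2l_s == pytest.approx(t2l, rel=1e-3)
        assert res.m0g_percent + res.m0l_percent == pytest.approx(100.0, abs=1e-9)

    def test_one_percent_noise_recovery_of_the_bimodal_decay(self):
        # 77%/23%, 232 ms / 7.6 ms: the widest time-scale separation reported
        g_errs, l_errs = [], []
        for s in range(10):
            res = fit_t2_mixture(gen_t2_decay(77.0, 0.232, 0.0076, noise=NoiseSpec(0.01, s)))
            g_errs.append(abs(res.t2g_ms / 232.0 - 1.0))
            l_errs.append(abs(res.t2l_ms / 7.6 - 1.0))
        assert np.median(g_errs) < 0.05
        assert np.median(l_errs) < 0.15

    def test_single_exponential_input_yields_negligible_gaussian_share(self):
        res = fit_t2_mixture(gen_t2_decay(0.0, 0.2, 0.3, noise=NoiseSpec(0.0, 0)))
        assert res.m0g_percent <= 1.0

    def test_percentages_invariant_to_magnetization_rescaling(self):
        curve = gen_t2_decay(77.0, 0.232, 0.0076, m0_total=1.0, noise=NoiseSpec(0.005, 3))
        scaled = RelaxationCurve(curve.times, 40.0 * curve.magnetization,
                                 CurveKind.TRANSVERSE_DECAY)
        a, b = fit_t2_mixture(curve), fit_t2_mixture(scaled)
        assert b.m0g_percent == pytest.approx(a.m0g_percent, abs=1e-6)
        assert b.t2g_s == pytest.approx(a.t2g_s, rel=1e-6)
        assert b.t2l_s == pytest.approx(a.t2l_s, rel=1e-6)
        assert b.m0_total == pytest.approx(40.0 * a.m0_total, rel=1e-6)

    def test_near_degenerate_time_constants_fall_back_to_single_kernel(self):
        res = fit_t2_mixture(gen_t2_decay(50.0, 0.200, 0.205, noise=NoiseSpec(0.01, 1)))
        assert res.degenerate
        assert res.m0g_percent in (0.0, 100.0)

    def test_too_few_points_rejected(self):
        t = np.geomspace(1e-3, 1.0, 10)
        curve = RelaxationCurve(t, np.exp(-t / 0.2), CurveKind.TRANSVERSE_DECAY)
        with pytest.raises(InvalidParameterError):
            fit_t2_mixture(curve)


def test_results_table_reports_conventional_units():
    t1res = fit_t1(gen_t1_curve(2.5, noise=NoiseSpec(0.0, 0)))
    t2res = fit_t2_mixture(gen_t2_decay(77.0, 0.232, 0.0076, noise=NoiseSpec(0.0, 0)))
    table = results_to_table([("ACT + CBD", t1res, t2res)])
    row = table.iloc[0]
    assert row["T1_s"] == pytest.approx(2.5, abs=1e-6)
    assert row["T2G_ms"] == pytest.approx(232.0, rel=1e-3)
    assert row["T2L_ms"] == pytest.approx(7.6, rel=1e-3)
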