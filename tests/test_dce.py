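"""DCE curve metrics and extended Tofts estimation."""

import numpy as np
import pytest

from glymphkit import synth
from glymphkit.config import RunConfig
from glymphkit.dce import (
    BiexpAif,
    TimeIntensityCurve,
    ToftsParams,
    enhancement,
    fit_extended_tofts,
    qc_filter,
    roi_mean_curve,
    semiquant,
    tofts_model,
)


def _curve(e, t=None, injection_index=1):
    t = np.arange(len(e)) * 10.0 if t is None else t
    return TimeIntensityCurve(
        t=t, s=100.0 * (1.0 + np.asarray(e, float)),
        baseline_window=tuple(range(injection_index + 1)),
        injection_index=injection_index,
    )


class TestEnhancement:
    def test_flat_curve_zero(self):
        e = enhancement(_curve(np.zeros(23)))
        assert np.allclose(e, 0.0)

    def test_simple_arithmetic(self):
        curve = TimeIntensityCurve(
            t=np.arange(5.0), s=np.array([100.0, 100.0, 120.0, 150.0, 130.0]),
            baseline_window=(0, 1), injection_index=1,
        )
        e = enhancement(curve)
        assert np.isclose(e.max(), 0.5)

    def test_nonpositive_baseline_rejected(self):
        curve = TimeIntensityCurve(
            t=np.arange(5.0), s=np.array([0.0, 0.0, 1.0, 2.0, 1.0]),
            baseline_window=(0, 1), injection_index=1,
        )
        with pytest.raises(ValueError, match="S0"):
            enhancement(curve)

    def test_generator_round_trip(self):
        p = ToftsParams(0.05, 0.5, 0.01)
        curve, _ = synth.gen_dce_curve(p)
        e = enhancement(curve)
        model = tofts_model(curve.t, p, BiexpAif(), RunConfig().injection_time)
        np.testing.assert_allclose(e, model, atol=1e-12)

    def test_baseline_after_injection_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            TimeIntensityCurve(t=np.arange(5.0), s=np.ones(5), baseline_window=(0, 3), injection_index=1)


class TestSemiquant:
    def test_null_curve_flagged_degenerate(self):
        sq = semiquant(_curve(np.zeros(30)))
        assert sq.degenerate and sq.wash_in == 0 and sq.ttp == 0 and sq.auc == 0

    def test_linear_ramp_wash_in_and_ttp(self):
        # e rises 0.01/s for 60 s after injection at t=10 s, then flat
        t = np.arange(0, 200.0, 10.0)
        e = np.clip((t - 10.0), 0, 60) * 0.01
        sq = semiquant(_curve(e, t=t), auc_window_s=120.0)
        assert np.isclose(sq.wash_in, 0.01)
        assert np.isclose(sq.ttp, 1.0)

    def test_triangle_pulse_auc_closed_form(self):
        # symmetric triangle peaking at 0.4, base 80 s, inside a 120-s window
        t = np.arange(0, 200.0, 10.0)
        e = np.interp(t, [10, 50, 90], [0, 0.4, 0.0])
        sq = semiquant(_curve(e, t=t), auc_window_s=120.0)
        assert np.isclose(sq.auc, 0.5 * 80 * 0.4 / 120.0)

    def test_window_beyond_acquisition_rejected(self):
        t = np.arange(0, 100.0, 10.0)
        with pytest.raises(ValueError, match="window"):
            semiquant(_curve(np.linspace(0, 1, 10), t=t), auc_window_s=120.0)

    def test_scaling_linearity(self):
        p = ToftsParams(0.05, 0.5, 0.01)
        curve, _ = synth.gen_dce_curve(p)
        e = enhancement(curve)
        sq1 = semiquant(curve)
        sq2 = semiquant(_curve(2.0 * e, t=curve.t))
        assert np.isclose(sq2.wash_in, 2 * sq1.wash_in)
        assert np.isclose(sq2.auc, 2 * sq1.auc)
        assert np.isclose(sq2.ttp, sq1.ttp)


class TestToftsFit:
    def test_noiseless_recovery(self):
        truth = ToftsParams(0.05, 0.5, 0.01)
        curve, _ = synth.gen_dce_curve(truth)
        fit = fit_extended_tofts(curve)
        assert abs(fit.ktrans - 0.05) / 0.05 < 0.01
        assert abs(fit.kep - 0.5) / 0.5 < 0.01
        assert np.isclose(fit.ve, 0.1, rtol=0.02)

    def test_ve_kep_identity_exact(self):
        for seed in range(5):
            curve, _ = synth.gen_dce_curve(ToftsParams(0.08, 0.6, 0.02), noise_sd=0.01, seed=seed)
            fit = fit_extended_tofts(curve)
            if fit.ktrans > 1e-4:
                assert np.isclose(fit.ve * fit.kep, fit.ktrans, rtol=1e-10)

    def test_null_kinetics_flagged(self):
        curve, _ = synth.gen_dce_curve(ToftsParams(0.0, 0.5, 0.02))
        fit = fit_extended_tofts(curve)
        assert fit.ktrans <= 1e-4
        assert fit.ve == 0.0 and any("ve" in f for f in fit.flags)

    def test_zero_curve_truth_records_null(self):
        curve, truth = synth.gen_dce_curve(ToftsParams(0.0, 0.5, 0.0))
        assert np.allclose(curve.s, curve.s[0])
        assert truth["ve"] == 0.0

    def test_forward_model_matches_numeric_convolution(self):
        for p in (ToftsParams(0.05, 0.5, 0.01), ToftsParams(0.1, 1.2, 0.03)):
            curve, _ = synth.gen_dce_curve(p)
            e = enhancement(curve)
            oracle = synth.dce_oracle_curve(p, refine=4000)
            mask = oracle > 1e-6
            assert np.max(np.abs(e[mask] - oracle[mask]) / oracle[mask]) < 1e-3

    def test_noise_monotonically_degrades_rmse(self):
        truth = ToftsParams(0.05, 0.5, 0.01)
        rmse = []
        for sd in (0.002, 0.01, 0.05):
            errs = []
            for seed in range(40):
                curve, _ = synth.gen_dce_curve(truth, noise_sd=sd, seed=seed)
                fit = fit_extended_tofts(curve, seed=seed)
                errs.append((fit.ktrans - truth.ktrans) ** 2)
            rmse.append(np.sqrt(np.mean(errs)))
        assert rmse[0] < rmse[1] < rmse[2]

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            ToftsParams(-0.1, 0.5, 0.0)


class TestQcFilter:
    def test_strict_threshold(self):
        from glymphkit.dce import ToftsFit

        fits = [
            ToftsFit(0.05, 0.5, 0.1, 0.01, dev, True) for dev in (0.01, 0.049, 0.05, 0.2)
        ]
        retained, log = qc_filter(fits)
        assert len(retained) == 2 and len(log) == 2
        assert all(f.fit_deviation < 0.05 for f in retained)

    def test_noiseless_fits_all_retained(self):
        fits = []
        for kt in (0.03, 0.06):
            curve, _ = synth.gen_dce_curve(ToftsParams(kt, 0.5, 0.01))
            fits.append(fit_extended_tofts(curve))
        retained, log = qc_filter(fits)
        assert len(retained) == len(fits) and not log

    def test_retention_declines_with_noise(self):
        truth = ToftsParams(0.05, 0.5, 0.01)
        fractions = []
        for sd in (0.001, 0.01, 0.08):
            kept = 0
            for seed in range(25):
                curve, _ = synth.gen_dce_curve(truth, noise_sd=sd, seed=seed)
                fit = fit_extended_tofts(curve, seed=seed)
                kept += fit.fit_deviation < 0.05
            fractions.append(kept / 25)
        assert fractions[0] >= fractions[1] >= fractions[2]
        assert fractions[0] == 1.0


class TestRoiExtraction:
    def test_voxel_mean_curve(self):
        t = np.arange(5.0)
        series = np.zeros((4, 4, 1, 5))
        series[0, 0, 0] = 10.0
        series[1, 1, 0] = 20.0
        mask = np.zeros((4, 4, 1), bool)
        mask[0, 0, 0] = mask[1, 1, 0] = True
        curve = roi_mean_curve(series, mask, t, injection_index=1)
        assert np.allclose(curve.s, 15.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            roi_mean_curve(np.zeros((2, 2, 1, 3)), np.zeros((2, 2, 1), bool), np.arange(3.0))
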