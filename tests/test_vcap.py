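import numpy as np
import pytest

from pulmotrack.io import AirwaySignals, Breath
from pulmotrack.vcap import (
    BreathTooSmallError,
    Expirogram,
    FlatExpirogramError,
    build_expirogram,
    dead_spaces,
    fit_phases,
    gas_exchange,
)


def square_wave_expirogram(vt=500.0, step=150.0, plateau=40.0) -> Expirogram:
    """Ideal square-wave expirogram with a near-instant rise at ``step``."""
    v = np.concatenate(
        [np.arange(0.0, step + 0.25, 0.5), [step + 1e-6], np.arange(step + 0.5, vt, 0.5), [vt]]
    )
    p = np.where(v > step, plateau, 0.0)
    return Expirogram(volume=v, pco2=p, vt=vt)


def sigmoid_expirogram(vt=500.0, center=150.0, plateau=40.0, width=10.0) -> Expirogram:
    v = np.arange(0.0, vt + 0.5, 0.5)
    p = plateau / (1.0 + np.exp(-(v - center) / width))
    return Expirogram(volume=v, pco2=p, vt=vt)


class TestBuildExpirogram:
    def _signals(self, flow, pco2, sr=100.0):
        n = len(flow)
        return AirwaySignals(
            time=np.arange(n) / sr,
            flow=np.asarray(flow, dtype=float),
            paw=np.zeros(n),
            pco2=np.asarray(pco2, dtype=float),
            sample_rate=sr,
        )

    def test_constant_flow_rectangle_integral(self):
        # 0.5 L/s expiratory flow for 1 s -> 500 mL
        flow = np.concatenate([np.full(50, 1.0), np.full(101, -0.5)])
        pco2 = np.concatenate([np.zeros(50), np.full(101, 40.0)])
        breath = Breath(ordinal=1, insp_start=0, insp_end=49, exp_end=150)
        e = build_expirogram(self._signals(flow, pco2), breath)
        assert e.vt == pytest.approx(500.0, rel=5e-3)

    def test_zero_co2_gives_zero_curve(self):
        flow = np.concatenate([np.full(50, 1.0), np.full(101, -0.5)])
        breath = Breath(ordinal=1, insp_start=0, insp_end=49, exp_end=150)
        e = build_expirogram(self._signals(flow, np.zeros(151)), breath)
        assert np.allclose(e.pco2, 0.0)

    def test_small_breath_flagged_incomplete(self):
        flow = np.concatenate([np.full(50, 0.04), np.full(101, -0.02)])
        breath = Breath(ordinal=1, insp_start=0, insp_end=49, exp_end=150)
        with pytest.raises(BreathTooSmallError):
            build_expirogram(self._signals(flow, np.zeros(151)), breath)

    def test_synthetic_breath_vt_matches_config(self, nonoise_tables):
        tables, truth = nonoise_tables
        got = tables["features_vcap"]["vt_ml"].iloc[1]
        assert got == pytest.approx(truth["vt"].iloc[1], rel=5e-3)


class TestFitPhases:
    def test_linear_phase3_slope_recovered(self):
        e = sigmoid_expirogram()
        v = e.volume
        p = 30.0 + 10.0 / 1000.0 * v  # exactly linear, 10 mmHg/L
        fits = fit_phases(Expirogram(volume=v, pco2=p, vt=e.vt))
        assert fits.s3 == pytest.approx(10.0, abs=0.1)
        assert fits.y_int == pytest.approx(30.0, abs=0.1)

    def test_identical_phase_lines_give_180_degrees(self):
        v = np.arange(0.0, 500.5, 0.5)
        p = 0.02 * v + 1.0  # one straight line: phase II tangent == phase III
        fits = fit_phases(Expirogram(volume=v, pco2=p, vt=500.0), smooth_ml=1.0)
        assert fits.alpha_deg == pytest.approx(180.0, abs=0.5)

    def test_square_wave_s2_capped_and_x_int_at_rise(self):
        fits = fit_phases(square_wave_expirogram(), smooth_ml=1.0)
        assert fits.s2 == 2000.0
        assert fits.x_int == pytest.approx(150.0, abs=12.0)

    def test_flat_curve_raises(self):
        v = np.arange(0.0, 500.5, 0.5)
        with pytest.raises(FlatExpirogramError):
            fit_phases(Expirogram(volume=v, pco2=np.zeros_like(v), vt=500.0))

    def test_alpha_monotone_in_s3_with_s2_fixed(self):
        # identical lines give 180 deg, so a steeper phase III (closer to the
        # phase II direction) opens the angle toward 180: alpha grows with
        # SIII, matching the reported alpha-angle rise with airway narrowing
        alphas = []
        v = np.arange(0.0, 500.5, 0.5)
        for s3 in (2.0, 6.0, 12.0, 20.0):
            p = (20.0 + s3 / 1000.0 * (v - 150.0)) / (1.0 + np.exp(-(v - 150.0) / 10.0))
            fits = fit_phases(Expirogram(volume=v, pco2=np.clip(p, 0, None), vt=500.0))
            alphas.append(fits.alpha_deg)
        assert alphas == sorted(alphas)
        assert all(0.0 < a < 180.0 for a in alphas)


class TestDeadSpaces:
    def test_square_wave_inflection_at_step(self):
        e = square_wave_expirogram()
        fits = fit_phases(e, smooth_ml=1.0)
        vd_aw, vt_alv = dead_spaces(e, fits)
        assert vd_aw == pytest.approx(150.0, abs=2.0)
        assert vd_aw + vt_alv == pytest.approx(e.vt)

    def test_sigmoid_inflection_at_center(self):
        e = sigmoid_expirogram(center=150.0)
        fits = fit_phases(e)
        vd_aw, _ = dead_spaces(e, fits)
        assert vd_aw == pytest.approx(150.0, abs=1.0)


class TestGasExchange:
    def test_square_wave_bohr_arithmetic(self):
        # VT 500, VDaw 150, flat 40 mmHg plateau:
        # PECO2 = 40*350/500 = 28; VDBohr = (40-28)/40 = 0.30; VDalv = 0
        e = square_wave_expirogram()
        fits = fit_phases(e, smooth_ml=1.0)
        gx = gas_exchange(e, 150.0, fits)
        assert gx.pe_co2 == pytest.approx(28.0, abs=1e-3)
        assert gx.pa_co2 == pytest.approx(40.0, abs=1e-6)
        assert gx.vd_bohr == pytest.approx(0.30, abs=1e-4)
        assert gx.vd_alv == pytest.approx(0.0, abs=0.1)

    def test_zero_co2_eliminates_nothing(self):
        v = np.arange(0.0, 500.5, 0.5)
        e = Expirogram(volume=v, pco2=np.zeros_like(v), vt=500.0)
        fco2 = np.trapezoid(e.pco2 / (760 - 47), e.volume)
        assert fco2 == 0.0

    def test_scaling_pco2_scales_vco2_not_bohr(self):
        e1 = sigmoid_expirogram(plateau=40.0)
        e2 = sigmoid_expirogram(plateau=80.0)
        f1, f2 = fit_phases(e1), fit_phases(e2)
        g1 = gas_exchange(e1, 150.0, f1)
        g2 = gas_exchange(e2, 150.0, f2)
        assert g2.vco2_br == pytest.approx(2 * g1.vco2_br, rel=1e-6)
        assert g2.pe_co2 == pytest.approx(2 * g1.pe_co2, rel=1e-6)
        assert g2.vd_bohr == pytest.approx(g1.vd_bohr, abs=1e-9)

    def test_pe_below_end_tidal_for_monotone_curves(self):
        e = sigmoid_expirogram()
        gx = gas_exchange(e, 150.0, fit_phases(e))
        assert gx.pe_co2 <= e.end_tidal


class TestGeneratorRecovery:
    def test_configured_vdaw_and_siii_recovered(self, nonoise_tables):
        tables, truth = nonoise_tables
        v = tables["features_vcap"].iloc[1]
        assert v["vd_aw_ml"] == pytest.approx(truth["vdaw"].iloc[1], rel=0.02)
        assert v["s3_mmhg_per_l"] == pytest.approx(truth["siii"].iloc[1], rel=0.02)

    def test_bohr_ratio_matches_analytic_truth(self, nonoise_tables):
        tables, truth = nonoise_tables
        v = tables["features_vcap"].iloc[1]
        assert v["vd_bohr"] == pytest.approx(truth["vd_bohr"].iloc[1], rel=0.02)
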