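"""Kymograph construction, condensate quantification, WLC tension, FRAP."""

import numpy as np
import pytest

from parbcond.synthetic_data import KymoSynthConfig, gen_condensation_kymograph
from parbcond.trace_quant import (Kymograph, QuantParams, build_kymograph,
                                  condensate_intensity, condensate_size_kb,
                                  external_tension_pN, frap_recovery,
                                  quantify_kymograph, track_condensate)


class TestBuildKymograph:
    def test_uniform_stack_near_zero_after_background(self):
        stack = np.full((4, 21, 40), 50.0)
        kym = build_kymograph(stack, ((2, 10), (37, 10)))
        # constant background is removed by the tophat
        assert np.all(kym.intensity <= 1e-6 * 50 * 11)

    def test_band_width_is_11_pixels(self):
        q = QuantParams()
        assert 2 * q.band_halfwidth + 1 == 11
        stack = np.zeros((2, 21, 40))
        stack[:, 10, :] = 100.0   # a bright 1-px line on the DNA axis
        kym = build_kymograph(stack, ((0, 10), (39, 10)))
        assert kym.intensity.shape == (40, 2)

    def test_spot_appears_at_projected_position(self):
        cfg = KymoSynthConfig(n_frames=6, fraction=(0.6,),
                              position_step_px=0.0)
        stack, truth = gen_condensation_kymograph(cfg, seed=1)
        kym = build_kymograph(stack, truth["dna_ends"])
        peaks = np.argmax(kym.intensity, axis=0)
        assert np.allclose(peaks, truth["position_px"], atol=1.5)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            build_kymograph(np.zeros((0, 5, 5)), ((0, 2), (4, 2)))
        with pytest.raises(ValueError):
            build_kymograph(np.zeros((2, 5, 5)), ((0, 2), (9, 2)))


class TestTracking:
    def test_static_spot_constant_track(self):
        cfg = KymoSynthConfig(n_frames=10, fraction=(0.5,),
                              position_step_px=0.0)
        stack, truth = gen_condensation_kymograph(cfg, seed=2)
        kym = build_kymograph(stack, truth["dna_ends"])
        track = track_condensate(kym)
        assert np.nanstd(track.position_px) < 1.0

    def test_drifting_spot_recovered(self):
        """Linear drift recovered within 1 px RMS (generator ground truth)."""
        cfg = KymoSynthConfig(n_frames=25, fraction=(0.5,),
                              position_step_px=0.8)
        stack, truth = gen_condensation_kymograph(cfg, seed=3)
        kym = build_kymograph(stack, truth["dna_ends"])
        track = track_condensate(kym)
        ok = ~np.isnan(track.position_px)
        assert ok.mean() > 0.8
        rms = np.sqrt(np.nanmean(
            (track.position_px[ok] - truth["position_px"][ok]) ** 2))
        assert rms < 1.0

    def test_no_spot_empty_track(self):
        cfg = KymoSynthConfig(n_frames=8, fraction=(0.0,))
        stack, truth = gen_condensation_kymograph(cfg, seed=4)
        kym = build_kymograph(stack, truth["dna_ends"])
        track = track_condensate(kym)
        assert np.isnan(track.position_px).mean() > 0.5


class TestCondensateSize:
    def test_trivial_fractions(self):
        assert condensate_size_kb(1.0, 1.0) == pytest.approx(42.5)
        assert condensate_size_kb(0.0, 1.0) == 0.0
        assert condensate_size_kb(0.588, 1.0) == pytest.approx(25.0, abs=0.05)

    def test_conservation(self):
        """Condensate and outside DNA sum to L exactly."""
        q = QuantParams()
        for frac in (0.0, 0.25, 0.588, 1.0):
            inside = condensate_size_kb(frac, 1.0, q)
            outside = condensate_size_kb(1.0 - frac, 1.0, q)
            assert inside + outside == pytest.approx(q.L_kb, rel=1e-12)

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            condensate_size_kb(2.0, 1.0)
        with pytest.raises(ValueError):
            condensate_size_kb(0.5, 0.0)


class TestTension:
    def test_zero_extension_zero_force(self):
        assert external_tension_pN(0.0, 0.0) == pytest.approx(0.0, abs=1e-15)

    def test_half_extension_value(self):
        """Independent term-by-term evaluation at r = 0.5."""
        q = QuantParams()
        L_out_um = q.alpha_dye * q.L_kb * 1e3 * 0.342e-3
        r = 0.5
        bracket = 1.0 / (4 * 0.25) - 0.25 + sum(
            a * r ** (i + 1) for i, a in enumerate(q.wlc_coeffs))
        expected = q.kBT_pN_um / (q.Lp_nm * 1e-3) * bracket
        got = external_tension_pN(r * L_out_um, 0.0, q)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.11, abs=0.005)

    def test_monotone_on_fine_grid(self):
        q = QuantParams()
        L_out_um = q.alpha_dye * q.L_kb * 1e3 * 0.342e-3
        r = np.linspace(1e-4, 0.95, 2000)
        F = external_tension_pN(r * L_out_um, np.zeros_like(r), q)
        assert np.all(np.diff(F) > 0)

    def test_overstretching_rejected(self):
        q = QuantParams()
        L_out_um = q.alpha_dye * q.L_kb * 1e3 * 0.342e-3
        with pytest.raises(ValueError):
            external_tension_pN(1.01 * L_out_um, 0.0, q)
        with pytest.raises(ValueError):
            external_tension_pN(1.0, 42.5, q)  # no DNA outside


class TestFrap:
    def test_flat_curve_when_no_bleach(self):
        cfg = KymoSynthConfig(n_frames=30, fraction=(0.3,))
        stack, truth = gen_condensation_kymograph(cfg, seed=5)
        kym = build_kymograph(stack, truth["dna_ends"])
        curve, tau, t_half = frap_recovery(kym, bleach_frame=10)
        assert np.allclose(curve, 1.0, atol=0.05)
        assert tau == np.inf

    def test_exchange_time_recovered(self):
        cfg = KymoSynthConfig(n_frames=150, fraction=(0.3,),
                              bleach_frame=25, exchange_time_s=40.0,
                              frame_interval_s=1.0)
        stack, truth = gen_condensation_kymograph(cfg, seed=6)
        kym = build_kymograph(stack, truth["dna_ends"], frame_interval_s=1.0)
        curve, tau, t_half = frap_recovery(kym, bleach_frame=25)
        assert tau == pytest.approx(40.0, rel=0.10)
        assert t_half == pytest.approx(tau * np.log(2), rel=1e-9)

    def test_bleach_frame_validated(self):
        kym = Kymograph(np.ones((10, 20)), 0.13, 1.0, (0, 9))
        with pytest.raises(ValueError):
            frap_recovery(kym, bleach_frame=25)


class TestPipeline:
    def test_condensate_trajectory_recovery(self):
        """End-to-end: programmed condensate-size trajectory within 5%."""
        frac = tuple(np.clip(np.linspace(0.2, 0.6, 40), 0, 1))
        cfg = KymoSynthConfig(n_frames=40, fraction=frac)
        stack, truth = gen_condensation_kymograph(cfg, seed=7)
        kym = build_kymograph(stack, truth["dna_ends"])
        track = quantify_kymograph(kym)
        ok = ~np.isnan(track.L_cond_kb)
        assert ok.mean() > 0.7
        programmed = truth["fraction"][ok] * QuantParams().L_kb
        rel = np.abs(track.L_cond_kb[ok] - programmed) / QuantParams().L_kb
        assert np.mean(rel) < 0.05
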