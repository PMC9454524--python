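"""SPGR signal model, T10 estimation, LTKM forward model and fitting."""

import numpy as np
import pytest

from cedsim import dce, phantom as ph


class TestSPGR:
    def test_zero_concentration_gives_unit_ratio(self, acq):
        assert dce.spgr_signal_ratio(0.0, 1.0, acq) == pytest.approx(1.0, abs=1e-14)

    def test_oracle_value_at_one_millimolar(self, acq):
        # direct arithmetic of the signal equation at the protocol settings
        assert dce.spgr_signal_ratio(1.0, 1.0, acq) == pytest.approx(2.1985, abs=2e-3)

    def test_monotone_increasing_up_to_stationary_point(self, acq):
        cstar = dce.spgr_peak_concentration(1.0, acq)
        c = np.linspace(0, cstar, 400)
        r = dce.spgr_signal_ratio(c, 1.0, acq)
        assert np.all(np.diff(r) > 0)

    @pytest.mark.parametrize("c", [0.1, 0.5, 2.0])
    def test_round_trip_identity(self, acq, c):
        r = dce.spgr_signal_ratio(c, 1.0, acq)
        c2 = dce.concentration_from_signal(r, 1.0, acq)
        assert abs(c2 - c) / c < 1e-8

    def test_inverse_of_oracle_ratio(self, acq):
        assert dce.concentration_from_signal(2.1985, 1.0, acq) == pytest.approx(1.0, abs=2e-3)

    def test_ratio_below_one_clamps_to_zero(self, acq):
        assert dce.concentration_from_signal(0.98, 1.0, acq) == 0.0

    def test_unreachable_ratio_raises(self, acq):
        with pytest.raises(ValueError, match="exceeds"):
            dce.concentration_from_signal(5.0, 1.0, acq)

    def test_nonpositive_t10_rejected(self, acq):
        with pytest.raises(ValueError):
            dce.spgr_signal_ratio(1.0, -0.5, acq)


class TestT10:
    def test_noiseless_recovery_from_own_forward_model(self):
        f = dce.FSEParams()
        s = [dce.fse_signal(1.2, 0.09, TR, TE) for TR, TE in
             ((f.TR_t1w_s, f.TE_t1w_s), (f.TR_t2w_s, f.TE_t2w_s),
              (f.TR_pd_s, f.TE_pd_s))]
        t10, ok = dce.estimate_t10(*s)
        assert ok and abs(t10 - 1.2) / 1.2 < 1e-6

    def test_noisy_median_error_under_five_percent(self):
        rng = np.random.default_rng(7)
        f = dce.FSEParams()
        s = np.array([dce.fse_signal(1.2, 0.09, TR, TE) for TR, TE in
                      ((f.TR_t1w_s, f.TE_t1w_s), (f.TR_t2w_s, f.TE_t2w_s),
                       (f.TR_pd_s, f.TE_pd_s))])[:, None] * np.ones(1000)
        sn = s * (1 + 0.01 * rng.standard_normal(s.shape))
        t10, ok = dce.estimate_t10(sn[0], sn[1], sn[2])
        assert np.median(np.abs(t10[ok] - 1.2) / 1.2) < 0.05

    def test_degenerate_signals_flagged(self):
        t10, ok = dce.estimate_t10(0.5, 0.6, 0.6)   # S_PD == S_T2w
        assert not ok and np.isnan(t10)
        _, ok2 = dce.estimate_t10(-1.0, 0.4, 0.6)
        assert not ok2


class TestLTKMForward:
    def test_pure_plasma_term(self, aif_grid):
        c = dce.ltkm_forward(0.05, 0.0, 0.3, 0.0, aif_grid)
        assert np.allclose(c, 0.05 * aif_grid.cb_mM)

    def test_leakage_term_matches_quadrature(self, aif_grid):
        lam = 2e-4
        c = dce.ltkm_forward(0.05, 0.0, 0.3, lam, aif_grid)
        t, cb = aif_grid.times_s, aif_grid.cb_mM
        cum = np.concatenate([[0.0], np.cumsum(0.5 * (cb[1:] + cb[:-1]) * np.diff(t))])
        assert np.allclose(c, 0.05 * cb + lam * cum, rtol=1e-12)

    def test_against_oversampled_convolution(self, acq):
        aifp = ph.AIFParams(t0_s=3 * acq.dt_s)
        times = np.arange(0.0, 129.0, acq.dt_s)
        fine = np.arange(0.0, times[-1] + 1e-9, acq.dt_s / 1000)
        p = (0.05, 0.005, 0.4, 1e-4)
        coarse = dce.ltkm_forward(*p, ph.synth_aif(times, aifp), times)
        oracle = np.interp(times, fine,
                           dce.ltkm_forward(*p, ph.synth_aif(fine, aifp), fine))
        m = oracle > 0.05 * oracle.max()
        assert np.max(np.abs(coarse[m] - oracle[m]) / oracle[m]) < 5e-3

    def test_volume_forward_matches_scalar(self, aif_grid):
        maps = dce.PerfusionMaps(epsBL=np.full((2, 2, 1), 0.04),
                                 ktrans_s=np.full((2, 2, 1), 3e-3),
                                 epsECS=np.full((2, 2, 1), 0.2),
                                 lambda_tr_s=np.full((2, 2, 1), 1e-4))
        vol = ph.ltkm_forward_volume(maps, aif_grid)
        ref = dce.ltkm_forward(0.04, 3e-3, 0.2, 1e-4, aif_grid)
        assert np.allclose(vol[0, 0, 0], ref, rtol=1e-12, atol=1e-15)

    def test_times_outside_aif_support_rejected(self, aif_grid):
        with pytest.raises(ValueError, match="support"):
            dce.ltkm_forward(0.05, 0.0, 0.3, 0.0, aif_grid,
                             times_s=np.array([0.0, 1e4]))


class TestLTKMFit:
    def test_noiseless_recovery_within_one_percent(self, aif_grid):
        p = np.array([0.05, 0.005, 0.4, 1e-4])
        curve = dce.ltkm_forward(*p, aif_grid)
        fit = dce.fit_ltkm(curve, aif_grid)
        assert fit.converged
        assert np.all(np.abs(fit.params - p) / p < 0.01)

    def test_zero_curve_gives_zero_parameters(self, aif_grid):
        fit = dce.fit_ltkm(np.zeros(aif_grid.times_s.size), aif_grid)
        assert fit.rss == 0.0 and np.all(fit.params == 0.0)

    def test_gtkm_pins_leakage_to_zero(self, aif_grid):
        curve = dce.ltkm_forward(0.05, 0.005, 0.4, 0.0, aif_grid)
        fit = dce.fit_ltkm(curve, aif_grid, gtkm=True)
        assert fit.params[3] == 0.0
        assert np.abs(fit.params[1] - 0.005) / 0.005 < 0.01

    def test_volume_fit_recovers_masked_voxels(self, aif_grid):
        shp = (2, 2, 1)
        maps = dce.PerfusionMaps(epsBL=np.full(shp, 0.04),
                                 ktrans_s=np.full(shp, 4e-3),
                                 epsECS=np.full(shp, 0.25),
                                 lambda_tr_s=np.full(shp, 1e-4))
        from cedsim import phantom as ph
        series = ph.ltkm_forward_volume(maps, aif_grid)
        mask = np.zeros(shp, bool)
        mask[0, 0, 0] = mask[1, 1, 0] = True
        fitted, rss, conv = dce.fit_ltkm_volume(series, aif_grid, mask=mask)
        assert np.all(conv)
        assert fitted.ktrans_s[0, 0, 0] == pytest.approx(4e-3, rel=0.01)
        assert fitted.epsBL[0, 1, 0] == 0.0        # unmasked voxel untouched

    def test_nonfinite_curve_rejected(self, aif_grid):
        bad = np.zeros(aif_grid.times_s.size)
        bad[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            dce.fit_ltkm(bad, aif_grid)


class TestPropertyDerivation:
    def test_closure_arithmetic(self):
        shp = (1, 1, 1)
        maps = dce.PerfusionMaps(epsBL=np.full(shp, 0.02),
                                 ktrans_s=np.full(shp, 2e-3),
                                 epsECS=np.full(shp, 0.40),
                                 lambda_tr_s=np.zeros(shp))
        tis = dce.derive_property_maps(maps, tumor_mask=np.ones(shp, bool))
        assert tis.epsICS[0, 0, 0] == pytest.approx(0.50260, abs=1e-5)
        assert tis.epsCM[0, 0, 0] == pytest.approx(0.07740, abs=1e-5)

    def test_fractions_sum_to_one_everywhere(self, default_phantom):
        tis = default_phantom.tissue
        total = tis.epsBL0 + tis.epsECS0 + tis.epsCM + tis.epsICS
        mask = default_phantom.grid.tissue_mask
        assert np.max(np.abs(total[mask] - 1.0)) < 1e-12

    def test_sv_scaling_doubles_with_ktrans(self):
        shp = (2, 1, 1)
        maps = dce.PerfusionMaps(epsBL=np.full(shp, 0.02),
                                 ktrans_s=np.array([1e-3, 2e-3]).reshape(shp),
                                 epsECS=np.full(shp, 0.3),
                                 lambda_tr_s=np.zeros(shp))
        tis = dce.derive_property_maps(maps, tumor_mask=np.ones(shp, bool))
        # Kavg = 1.5e-3; a voxel at 2x the average gets 4/3 * 2.0e4...
        assert tis.sv0[1, 0, 0] / tis.sv0[0, 0, 0] == pytest.approx(2.0)
        # ...and a voxel at exactly 2x Kavg maps to 4.0e4 per the scaling law
        maps2 = dce.PerfusionMaps(epsBL=np.full(shp, 0.02),
                                  ktrans_s=np.array([2e-3, 6e-3]).reshape(shp),
                                  epsECS=np.full(shp, 0.3),
                                  lambda_tr_s=np.zeros(shp))
        tis2 = dce.derive_property_maps(maps2, tumor_mask=np.ones(shp, bool))
        assert tis2.sv0[1, 0, 0] == pytest.approx(6e-3 / 4e-3 * 2.0e4)

    def test_overfull_voxel_clipped_with_warning(self):
        shp = (1, 1, 1)
        maps = dce.PerfusionMaps(epsBL=np.full(shp, 0.7),
                                 ktrans_s=np.full(shp, 1e-3),
                                 epsECS=np.full(shp, 0.5),
                                 lambda_tr_s=np.zeros(shp))
        with pytest.warns(UserWarning, match="clipped"):
            tis = dce.derive_property_maps(maps, tumor_mask=np.ones(shp, bool))
        assert tis.clipped[0, 0, 0]
        assert tis.epsBL0[0, 0, 0] + tis.epsECS0[0, 0, 0] <= 1.0
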