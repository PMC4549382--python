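import numpy as np
import pytest
from scipy import stats as sps

import orseg as o
from orseg.exceptions import DegenerateFitError, InvalidArgumentError
from orseg.prf import (PRFGrid, VertexTimeSeries, _drive, default_lattice,
                       double_gamma_kernel, fit_hrf, grid_fit,
                       predict_timeseries, refine_fit, smooth_sheet)


class TestDoubleGammaKernel:
    def test_zero_at_origin(self, hrf):
        k = double_gamma_kernel(hrf, tr_s=0.5)
        assert k[0] == 0.0

    def test_argmax_matches_dense_evaluation(self, hrf):
        """Peak location agrees with a brute-force fine-grid argmax."""
        k = double_gamma_kernel(hrf, tr_s=0.01)
        t_fine = np.arange(0, hrf.duration_s + 1e-9, 0.001)
        dense = (sps.gamma.pdf(t_fine, hrf.peak_delay_s, scale=1.0)
                 - sps.gamma.pdf(t_fine, hrf.undershoot_delay_s, scale=1.0)
                 / hrf.peak_undershoot_ratio)
        assert abs(0.01 * np.argmax(k) - t_fine[np.argmax(dense)]) <= 0.01

    def test_large_ratio_limit_is_pure_gamma(self, hrf):
        from dataclasses import replace
        k = double_gamma_kernel(replace(hrf, peak_undershoot_ratio=1e12), 0.5)
        t = np.arange(0, hrf.duration_s + 1e-9, 0.5)
        pos = sps.gamma.pdf(t, hrf.peak_delay_s, scale=1.0)
        assert np.allclose(k, pos / pos.max(), atol=1e-9)

    def test_invalid_dispersion(self):
        with pytest.raises(InvalidArgumentError):
            o.HRFParams(peak_dispersion_s=-1.0)


class TestFitHRF:
    def _burst_series(self, h, amplitude=2.0, tr=2.376, noise=None, seed=0):
        sched = o.make_burst_schedule(10, 1, 14)
        k = double_gamma_kernel(h, tr, 15 * tr)
        sig = np.zeros(len(sched))
        for onset in sched.stim_onsets:
            L = min(len(k), len(sig) - onset)
            sig[onset:onset + L] += amplitude * k[:L]
        if noise:
            sig += np.random.default_rng(seed).normal(0, noise, sig.size)
        return VertexTimeSeries(sig, tr), sched

    def test_parameter_recovery(self):
        truth = o.HRFParams(peak_delay_s=5.2, undershoot_delay_s=14.0,
                            peak_undershoot_ratio=4.0)
        series, sched = self._burst_series(truth)
        fit = fit_hrf(series, sched)
        assert abs(fit.params.peak_delay_s - 5.2) < 0.25 * series.tr_s
        assert not fit.degenerate

    def test_pure_noise_flagged_degenerate(self):
        rng = np.random.default_rng(7)
        sched = o.make_burst_schedule(10, 1, 14)
        series = VertexTimeSeries(rng.normal(0, 1, len(sched)), 2.376)
        assert fit_hrf(series, sched).degenerate

    def test_event_averaging_idempotent(self, hrf):
        """Two identical runs give the same fit as one."""
        series, sched = self._burst_series(hrf)
        twice = VertexTimeSeries(np.tile(series.values, 2), series.tr_s)
        sched2 = o.make_burst_schedule(20, 1, 14)
        f1, f2 = fit_hrf(series, sched), fit_hrf(twice, sched2)
        assert f1.params.peak_delay_s == pytest.approx(
            f2.params.peak_delay_s, abs=1e-6)

    def test_constant_series_degenerate_error(self):
        sched = o.make_burst_schedule(10, 1, 14)
        with pytest.raises(DegenerateFitError):
            fit_hrf(VertexTimeSeries(np.ones(len(sched)), 2.376), sched)


class TestPredict:
    def test_prf_outside_field_degenerate(self, mapping_run, hrf):
        ap, _ = mapping_run
        with pytest.raises(DegenerateFitError):
            predict_timeseries(o.PRFParams(100.0, 100.0, 1.0), ap, hrf)

    def test_full_field_aperture_constant_drive(self, stim_cfg):
        masks = np.ones((10, stim_cfg.grid_n, stim_cfg.grid_n), np.uint8)
        ap = o.ApertureSequence(masks, np.arange(10) * 2.376,
                                stim_cfg.field_radius_deg)
        drive = _drive(1.0, -1.0, 1.5, ap)
        assert np.ptp(drive) <= 1e-9 * drive.max()

    def test_self_consistency(self, mapping_run, hrf):
        ap, _ = mapping_run
        p = o.PRFParams(-3.0, 2.0, 1.2)
        a = predict_timeseries(p, ap, hrf).values
        b = predict_timeseries(p, ap, hrf).values
        r = np.corrcoef(a, b)[0, 1]
        assert abs(r - 1.0) < 1e-9

    def test_sigma_validation(self):
        with pytest.raises(InvalidArgumentError):
            o.PRFParams(0.0, 0.0, -1.0)

    def test_drive_invariant_to_grid_refinement(self, hrf):
        """Doubling the raster resolution changes the prediction < 1% RMS."""
        preds = []
        for n in (81, 161):
            cfg = o.StimulusConfig(grid_n=n)
            ap, _ = o.make_mapping_run(cfg, 10, 14)
            preds.append(predict_timeseries(o.PRFParams(-3.0, 1.0, 1.0),
                                            ap, hrf).values)
        rms = np.sqrt(np.mean((preds[0] - preds[1]) ** 2))
        assert rms < 0.01 * np.sqrt(np.mean(preds[1] ** 2))


class TestGridFit:
    def test_exact_lattice_series_recovered(self, mapping_run, hrf, prf_grid):
        ap, _ = mapping_run
        j = 100
        series = VertexTimeSeries(prf_grid.zpred[:, j].copy(), 2.376)
        p = grid_fit(series, ap, hrf, prf_grid)
        assert np.allclose([p.x0_deg, p.y0_deg, p.sigma_deg],
                           prf_grid.lattice[j])
        assert p.r == pytest.approx(1.0, abs=1e-9)

    def test_affine_rescaling_invariance(self, mapping_run, hrf, prf_grid):
        ap, _ = mapping_run
        base = prf_grid.zpred[:, 42].copy()
        p1 = grid_fit(VertexTimeSeries(base, 2.376), ap, hrf, prf_grid)
        p2 = grid_fit(VertexTimeSeries(3.5 * base - 7.0, 2.376), ap, hrf,
                      prf_grid)
        assert (p1.x0_deg, p1.y0_deg, p1.sigma_deg) == (
            p2.x0_deg, p2.y0_deg, p2.sigma_deg)

    def test_zero_variance_series_error(self, mapping_run, hrf, prf_grid):
        ap, _ = mapping_run
        with pytest.raises(DegenerateFitError):
            grid_fit(VertexTimeSeries(np.zeros(len(ap)), 2.376), ap, hrf,
                     prf_grid)

    def test_monte_carlo_recovery_within_one_step(self, mapping_run, hrf,
                                                  prf_grid):
        """At noise sd 0.5, the lattice winner stays within one lattice step
        of the true (lattice) parameters for >= 90% of 200 vertices."""
        ap, _ = mapping_run
        rng = np.random.default_rng(11)
        lat = prf_grid.lattice
        n_sig, n_ang, n_ecc = 6, 12, 8
        idx = rng.integers(0, lat.shape[0], 200)
        hits = 0
        for j in idx:
            clean = prf_grid.zpred[:, j] * np.sqrt(len(ap))
            noisy = clean + 0.5 * rng.standard_normal(clean.size)
            p = grid_fit(VertexTimeSeries(noisy, 2.376), ap, hrf, prf_grid)
            k = int(np.flatnonzero(
                np.all(np.isclose(lat, [p.x0_deg, p.y0_deg, p.sigma_deg]),
                       axis=1))[0])

            def coords(m):
                s = m % n_sig
                a = (m // n_sig) % n_ang
                e = m // (n_sig * n_ang)
                return e, a, s

            (e1, a1, s1), (e2, a2, s2) = coords(j), coords(k)
            d_ang = min(abs(a1 - a2), n_ang - abs(a1 - a2))
            if abs(e1 - e2) <= 1 and d_ang <= 1 and abs(s1 - s2) <= 1:
                hits += 1
        assert hits >= 0.9 * 200


class TestRefineFit:
    def test_init_at_truth_stays(self, mapping_run, hrf):
        ap, _ = mapping_run
        p_true = o.PRFParams(-2.0, 3.0, 1.0)
        series = predict_timeseries(p_true, ap, hrf)
        p = refine_fit(series, ap, hrf, p_true)
        assert abs(p.x0_deg - p_true.x0_deg) < 1e-4
        assert abs(p.y0_deg - p_true.y0_deg) < 1e-4
        assert abs(p.sigma_deg - p_true.sigma_deg) < 1e-4

    def test_monotone_improvement_over_grid(self, mapping_run, hrf, prf_grid,
                                            retino_phantom):
        ap, _ = mapping_run
        rng = np.random.default_rng(3)
        vidx = rng.choice(retino_phantom.x0.size, 30, replace=False)
        series = o.simulate_bold(retino_phantom, ap, hrf, noise_sd=0.5,
                                 seed=4, vertices=vidx)
        for row in series:
            vs = VertexTimeSeries(row, 2.376)
            p0 = grid_fit(vs, ap, hrf, prf_grid)
            p = refine_fit(vs, ap, hrf, p0)
            assert p.r >= p0.r - 1e-12

    def test_noiseless_recovery_from_grid_init(self, mapping_run, hrf,
                                               prf_grid):
        from orseg.prf import fit_vertex
        ap, _ = mapping_run
        rng = np.random.default_rng(5)
        for _ in range(8):
            x0, y0 = rng.uniform(-6, 6, 2)
            s = rng.uniform(0.5, 2.5)
            series = predict_timeseries(o.PRFParams(x0, y0, s), ap, hrf)
            p = fit_vertex(series, ap, hrf, prf_grid)
            assert abs(p.x0_deg - x0) < 0.1
            assert abs(p.y0_deg - y0) < 0.1
            assert abs(p.sigma_deg - s) / s < 0.05


class TestSmoothSheet:
    def test_constant_map_unchanged(self):
        pos = np.random.default_rng(0).uniform(0, 10, (50, 2))
        v = np.full(50, 3.3)
        assert np.allclose(smooth_sheet(v, pos, 5.0), v)

    def test_fwhm_zero_identity(self):
        pos = np.arange(20, dtype=float).reshape(10, 2)
        v = np.arange(10, dtype=float)
        assert np.array_equal(smooth_sheet(v, pos, 0.0), v)

    def test_impulse_matches_closed_form(self):
        """Impulse response follows the 2D Gaussian within 2%."""
        sheet = o.grid_sheet(21, 21, 1.0)
        v = np.zeros(21 * 21)
        center = 10 * 21 + 10
        v[center] = 1.0
        fwhm = 4.0
        out = smooth_sheet(v, sheet.positions, fwhm)
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
        d2 = np.sum((sheet.positions - sheet.positions[center]) ** 2, axis=1)
        expected = np.exp(-d2 / (2 * sigma ** 2))
        ratio = out / out[center]
        near = d2 < (2 * sigma) ** 2
        assert np.allclose(ratio[near], expected[near], rtol=0.02)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(InvalidArgumentError):
            smooth_sheet(np.zeros(4), np.zeros((4, 2)), -1.0)
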