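"""Inversion: self-consistency, round trips, boundary flags, time series."""

import numpy as np
import pytest

from layerlut import (
    FDReflectance,
    G2Curve,
    MeasurementFrame,
    fd_from_batch,
    fit_timeseries,
    invert_dcs,
    invert_fd,
    invert_fd_diffusion,
    pool_batches,
    run_layered_mc,
)
from layerlut.invert import DataQualityError
from layerlut.mc import _fresnel


def _fd_meas(lut, mua, musp):
    """A noiseless synthetic measurement taken from the LUT itself."""
    c = lut.query(mua, musp)
    return FDReflectance(lut.wavelength, lut.mod_freq_hz, 25.0, abs(c), float(-np.angle(c)))


class TestInvertFD:
    def test_grid_node_self_inversion_is_exact(self, tissue_luts, small_axes):
        lut = tissue_luts["fd"]
        mua, musp = small_axes.mua_grid[40], small_axes.musp_coarse[3]
        fit = invert_fd(_fd_meas(lut, mua, musp), lut)
        assert fit.mua == pytest.approx(mua, abs=1e-12)
        assert fit.musp == pytest.approx(musp, abs=1e-12)
        assert not fit.boundary_hit
        assert fit.model_tag == "multi_layer"

    def test_off_node_recovery_within_one_dense_step(self, tissue_luts, small_axes):
        # sub-grid mua offsets trade against musp along the shallow
        # single-frequency valley, so continuous refinement is required to
        # resolve off-grid optima to a dense-grid step
        lut = tissue_luts["fd"]
        mua, musp = 0.0137, 0.734  # deliberately off both grids
        fit = invert_fd(_fd_meas(lut, mua, musp), lut, refine="continuous")
        assert abs(fit.mua - mua) <= small_axes.mua_step + 1e-12
        assert abs(fit.musp - musp) <= small_axes.musp_dense_step_fd + 1e-12

    def test_grid_argmin_recovers_mua_to_its_grid_step(self, tissue_luts, small_axes):
        lut = tissue_luts["fd"]
        mua, musp = 0.0137, 0.734
        fit = invert_fd(_fd_meas(lut, mua, musp), lut)
        assert abs(fit.mua - mua) <= small_axes.mua_step + 1e-12

    def test_continuous_refinement_improves_off_grid_recovery(self, tissue_luts):
        lut = tissue_luts["fd"]
        mua, musp = 0.0226, 0.581
        coarse_fit = invert_fd(_fd_meas(lut, mua, musp), lut)
        quad_fit = invert_fd(_fd_meas(lut, mua, musp), lut, refine="quadratic")
        cont_fit = invert_fd(_fd_meas(lut, mua, musp), lut, refine="continuous")
        assert abs(cont_fit.mua - mua) < abs(coarse_fit.mua - mua)
        assert abs(cont_fit.musp - musp) < 1e-3
        # quadratic refinement stays within one grid step of the argmin
        assert abs(quad_fit.mua - coarse_fit.mua) <= 1e-3

    def test_boundary_hit_flagged(self, tissue_luts, small_axes):
        lut = tissue_luts["fd"]
        # an unattainably bright measurement drives mua to the axis floor
        c = lut.query(small_axes.mua_grid[0], 0.6)
        meas = FDReflectance(lut.wavelength, lut.mod_freq_hz, 25.0, 10 * abs(c), float(-np.angle(c)))
        fit = invert_fd(meas, lut)
        assert fit.boundary_hit

    def test_calibration_factor_applied(self, tissue_luts):
        lut = tissue_luts["fd"]
        mua, musp = 0.05, 0.6
        raw = _fd_meas(lut, mua, musp)
        scaled = FDReflectance(raw.wavelength, raw.mod_freq_hz, raw.sds, raw.amplitude * 2.0, raw.phase_rad)
        fit = invert_fd(scaled, lut, calibration=0.5 + 0j)
        assert fit.mua == pytest.approx(mua, abs=1e-9)


class TestDiffusionCrossValidation:
    def test_lut_and_diffusion_inverse_agree_on_homogeneous_data(
        self, homog_medium, fast_sim, small_axes
    ):
        """Single-layer MC-LUT and analytic diffusion inversions of the same
        homogeneous measurement recover compatible optical properties."""
        from layerlut import build_fd_lut

        sim = fast_sim.with_(seed=41, n_photons=120_000)
        lut = build_fd_lut(homogeneous_like(homog_medium), small_axes, sim, 830.0, 149e6, n_repeats=2)
        batch = pool_batches(
            [run_layered_mc(homog_medium, fast_sim.with_(seed=900 + i, n_photons=120_000), 830.0) for i in range(2)]
        )
        # white MC: any bottom mua can be applied at weighting time; 0.015 sits
        # in the interior of the LUT mua axis
        meas = fd_from_batch(batch, np.array([0.015]), 149e6)
        lut_fit = invert_fd(meas, lut, refine="continuous")
        diff_fit = invert_fd_diffusion(
            meas, 1.4, specular_factor=1.0 - _fresnel(1.0, 1.4, 1.0)
        )
        # both routes recover truth within the MC noise of this problem size
        assert lut_fit.mua == pytest.approx(0.015, rel=0.15)
        assert diff_fit.mua == pytest.approx(0.015, rel=0.15)
        assert lut_fit.musp == pytest.approx(diff_fit.musp, rel=0.08)


def homogeneous_like(medium):
    """Single-layer template with the same optical constants as ``medium``."""
    from layerlut import homogeneous_medium

    lay = medium.layers[0]
    return homogeneous_medium(n=lay.n, g=lay.g)


class TestInvertDCS:
    def test_noiseless_self_inversion(self, tissue_luts):
        lut = tissue_luts["dcs"]
        truth = 5e-6
        g2 = G2Curve(lut.tau_grid, lut.g2(0.6, truth, beta=0.35), 0.35)
        fit = invert_dcs(g2, lut.mua_bottom, 0.6, lut, beta=0.35)
        assert fit.bfi == pytest.approx(truth, rel=0.05)
        assert not fit.boundary_hit

    def test_flat_g2_pins_at_lower_bound_with_flag(self, tissue_luts):
        lut = tissue_luts["dcs"]
        tau = lut.tau_grid
        g2 = G2Curve(tau, np.full(tau.size, 1.35), 0.35)
        fit = invert_dcs(g2, lut.mua_bottom, 0.6, lut, beta=0.35)
        assert fit.boundary_hit
        assert fit.bfi == pytest.approx(lut.axes.bfi_min, rel=0.05)

    def test_nonphysical_g2_rejected(self, tissue_luts):
        lut = tissue_luts["dcs"]
        tau = lut.tau_grid
        g2 = G2Curve(tau, np.full(tau.size, 0.8), 0.35)
        with pytest.raises(DataQualityError):
            invert_dcs(g2, lut.mua_bottom, 0.6, lut, beta=0.35)

    def test_fitted_beta_recovers_generating_beta(self, tissue_luts):
        lut = tissue_luts["dcs"]
        truth_bfi, truth_beta = 8e-6, 0.42
        g2 = G2Curve(lut.tau_grid, lut.g2(0.6, truth_bfi, beta=truth_beta), None)
        fit = invert_dcs(g2, lut.mua_bottom, 0.6, lut, beta_mode="fitted", beta=0.35)
        assert fit.beta == pytest.approx(truth_beta, abs=0.02)
        assert fit.bfi == pytest.approx(truth_bfi, rel=0.08)

    def test_musp_outside_axis_clipped_with_warning(self, tissue_luts):
        lut = tissue_luts["dcs"]
        g2 = G2Curve(lut.tau_grid, lut.g2(0.6, 5e-6, beta=0.35), 0.35)
        with pytest.warns(UserWarning, match="clipped"):
            invert_dcs(g2, lut.mua_bottom, 2.0, lut, beta=0.35)


class TestFitTimeseries:
    def _frames(self, lut, n=4, mua=0.05, musp=0.6):
        c = lut.query(mua, musp)
        fd = FDReflectance(lut.wavelength, lut.mod_freq_hz, 25.0, abs(c), float(-np.angle(c)))
        return [MeasurementFrame(time_s=2.0 * i, fd={830.0: fd}) for i in range(n)]

    def test_constant_input_gives_constant_output(self, tissue_luts):
        frames = self._frames(tissue_luts["fd"])
        fits = fit_timeseries(frames, {830.0: tissue_luts["fd"]})
        muas = {f.fd[830.0].mua for f in fits}
        assert len(muas) == 1
        assert not any(f.failed for f in fits)

    def test_frame_order_permutation_invariance(self, tissue_luts):
        frames = self._frames(tissue_luts["fd"], n=5)
        fits_fwd = fit_timeseries(frames, {830.0: tissue_luts["fd"]})
        fits_rev = fit_timeseries(frames[::-1], {830.0: tissue_luts["fd"]})
        assert [f.fd[830.0].mua for f in fits_fwd] == [f.fd[830.0].mua for f in fits_rev][::-1]

    def test_per_frame_failure_is_marked_not_fatal(self, tissue_luts):
        lut = tissue_luts["dcs"]
        good = self._frames(tissue_luts["fd"], n=1)[0]
        bad = MeasurementFrame(
            time_s=2.0,
            fd=dict(good.fd),
            g2=G2Curve(lut.tau_grid, np.full(lut.tau_grid.size, 0.5), 0.35),
        )
        with pytest.warns(UserWarning, match="failed"):
            fits = fit_timeseries([good, bad], {830.0: tissue_luts["fd"]}, lut, beta=0.35)
        assert not fits[0].failed
        assert fits[1].failed and "DataQualityError" in fits[1].error
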