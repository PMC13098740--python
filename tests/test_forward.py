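"""Forward observables and their closed-form diffusion oracles."""

import math

import numpy as np
import pytest

from layerlut import (
    absorption_weights,
    diffusion_fd_semi_infinite,
    diffusion_g1_semi_infinite,
    fd_from_batch,
    fd_reflectance,
    g1_from_batch,
    siegert,
    tof_histogram,
)
from layerlut.forward import default_tau_grid, diffusion_mean_tof_ns
from layerlut.mc import _fresnel

MUA, MUSP, N = 0.01, 1.0, 1.4
SPECULAR = 1.0 - _fresnel(1.0, N, 1.0)


def _oracle_annulus(batch, freq):
    """Diffusion FD reflectance averaged over the detection annulus area."""
    rr = np.linspace(batch.sds - batch.detector_half_width, batch.sds + batch.detector_half_width, 9)
    vals = np.array([diffusion_fd_semi_infinite(MUA, MUSP, N, r, freq) for r in rr])
    return np.average(vals, weights=rr) * SPECULAR


class TestAbsorptionWeights:
    def test_zero_mua_is_identity(self, homog_batch):
        np.testing.assert_array_equal(
            absorption_weights(homog_batch, np.array([0.0])), homog_batch.exit_weight
        )

    def test_analytic_multiplier(self):
        # L = [1, 2, 10] mm with the light-skin stack mua at 730 nm
        L = np.array([1.0, 2.0, 10.0])
        mua = np.array([0.019, 0.010, 0.010])
        assert math.exp(-(L @ mua)) == pytest.approx(0.8702, abs=5e-5)

    def test_length_mismatch_rejected(self, homog_batch):
        with pytest.raises(ValueError):
            absorption_weights(homog_batch, np.array([0.01, 0.01]))


class TestTOFHistogram:
    def test_total_weight_conserved(self, homog_batch):
        w = absorption_weights(homog_batch, np.array([MUA]))
        hist = tof_histogram(homog_batch, w)
        assert hist.total_weight == pytest.approx(w.sum(), rel=1e-12)

    def test_halving_bin_width_conserves_weight(self, homog_batch):
        w = absorption_weights(homog_batch, np.array([MUA]))
        h1 = tof_histogram(homog_batch, w, bin_width_ns=0.02)
        h2 = tof_histogram(homog_batch, w, bin_width_ns=0.01)
        assert h1.total_weight == pytest.approx(h2.total_weight, rel=1e-12)

    def test_mean_tof_matches_diffusion(self, homog_batch):
        w = absorption_weights(homog_batch, np.array([MUA]))
        t = homog_batch.time_of_flight_ns()
        mean_mc = float((w * t).sum() / w.sum())
        mean_oracle = diffusion_mean_tof_ns(MUA, MUSP, N, homog_batch.sds)
        assert mean_mc == pytest.approx(mean_oracle, rel=0.05)


class TestFDReflectance:
    def test_dc_limit_equals_total_weight(self, homog_batch):
        w = absorption_weights(homog_batch, np.array([MUA]))
        hist = tof_histogram(homog_batch, w)
        fd = fd_reflectance(hist, 0.0)
        assert fd.amplitude == pytest.approx(w.sum(), rel=1e-12)
        assert fd.phase_rad == 0.0

    def test_histogram_route_matches_direct_summation(self, homog_batch):
        w = absorption_weights(homog_batch, np.array([MUA]))
        hist = tof_histogram(homog_batch, w, bin_width_ns=0.01)
        scale = 1.0 / (homog_batch.n_launched * homog_batch.detector_area)
        via_hist = fd_reflectance(hist, 139e6, scale=scale)
        direct = fd_from_batch(homog_batch, np.array([MUA]), 139e6)
        assert via_hist.amplitude == pytest.approx(direct.amplitude, rel=2e-3)
        assert via_hist.phase_rad == pytest.approx(direct.phase_rad, abs=2e-3)

    def test_phase_increases_with_modulation_frequency(self, homog_batch):
        p139 = fd_from_batch(homog_batch, np.array([MUA]), 139e6).phase_rad
        p149 = fd_from_batch(homog_batch, np.array([MUA]), 149e6).phase_rad
        assert 0 < p139 < p149


class TestDiffusionOracles:
    def test_zero_frequency_reduces_to_steady_state(self):
        r0 = diffusion_fd_semi_infinite(MUA, MUSP, N, 25.0, 0.0)
        assert abs(r0.imag) < 1e-12

    def test_amplitude_strictly_decreasing_in_mua(self):
        amps = [
            abs(diffusion_fd_semi_infinite(mua, MUSP, N, 25.0, 139e6))
            for mua in (0.005, 0.01, 0.02, 0.04)
        ]
        assert all(a > b for a, b in zip(amps, amps[1:]))

    def test_g1_limits_and_monotonicity(self):
        tau = default_tau_grid(32, 1e-7, 1e-2)
        g1 = diffusion_g1_semi_infinite(MUA, MUSP, N, 25.0, 1e-6, 850.0, tau)
        assert diffusion_g1_semi_infinite(MUA, MUSP, N, 25.0, 1e-6, 850.0, np.array([0.0])).values[0] == pytest.approx(1.0)
        assert np.all(np.diff(g1.values) <= 1e-12)
        flat = diffusion_g1_semi_infinite(MUA, MUSP, N, 25.0, 0.0, 850.0, tau)
        np.testing.assert_allclose(flat.values, 1.0, atol=1e-12)

    def test_g1_decay_accelerates_with_bfi(self):
        tau = default_tau_grid(32, 1e-6, 1e-3)
        slow = diffusion_g1_semi_infinite(MUA, MUSP, N, 25.0, 1e-6, 850.0, tau).values
        fast = diffusion_g1_semi_infinite(MUA, MUSP, N, 25.0, 5e-6, 850.0, tau).values
        assert np.all(fast <= slow + 1e-12)
        assert fast[10] < slow[10]


class TestMCvsOracle:
    """Core correctness gate: homogeneous MC against the diffusion closed forms."""

    @pytest.mark.parametrize("freq", [139e6, 149e6])
    def test_fd_amplitude_and_phase(self, homog_batch, freq):
        meas = fd_from_batch(homog_batch, np.array([MUA]), freq)
        oracle = _oracle_annulus(homog_batch, freq)
        assert meas.amplitude == pytest.approx(abs(oracle), rel=0.05)
        assert abs(math.degrees(meas.phase_rad - (-np.angle(oracle)))) < 1.0

    def test_g1_against_correlation_diffusion(self, homog_batch):
        tau = default_tau_grid(64, 1e-7, 1e-2)
        bfi = 1e-6
        g1 = g1_from_batch(homog_batch, np.array([MUA]), np.array([bfi]), tau, 850.0)
        oracle = diffusion_g1_semi_infinite(MUA, MUSP, N, homog_batch.sds, bfi, 850.0, tau)
        rms = float(np.sqrt(np.mean((g1.values - oracle.values) ** 2)))
        assert rms < 0.02


class TestG1AndSiegert:
    def test_g1_is_one_at_tau_zero_and_for_zero_bfi(self, homog_batch):
        tau = np.array([0.0, 1e-5, 1e-3])
        g1 = g1_from_batch(homog_batch, np.array([MUA]), np.array([2e-6]), tau, 850.0)
        assert g1.values[0] == pytest.approx(1.0)
        flat = g1_from_batch(homog_batch, np.array([MUA]), np.array([0.0]), tau, 850.0)
        np.testing.assert_allclose(flat.values, 1.0)

    def test_g1_monotone_and_faster_with_higher_bfi(self, homog_batch):
        tau = default_tau_grid(48, 1e-7, 1e-2)
        lo = g1_from_batch(homog_batch, np.array([MUA]), np.array([1e-6]), tau, 850.0).values
        hi = g1_from_batch(homog_batch, np.array([MUA]), np.array([4e-6]), tau, 850.0).values
        assert np.all(np.diff(lo) <= 1e-12)
        assert np.all(hi <= lo + 1e-12) and hi[20] < lo[20]

    def test_negative_bfi_rejected(self, homog_batch):
        with pytest.raises(ValueError):
            g1_from_batch(homog_batch, np.array([MUA]), np.array([-1e-6]), np.array([1e-5]), 850.0)

    @pytest.mark.parametrize(
        "g1val, beta, expected",
        [(1.0, 0.45, 1.45), (0.0, 0.45, 1.0), (1.0, 0.0, 1.0), (0.5, 0.35, 1.0875)],
    )
    def test_siegert_values(self, g1val, beta, expected):
        g2 = siegert(np.array([g1val]), beta)
        assert g2.values[0] == pytest.approx(expected)
        assert g2.beta == beta

    def test_siegert_bounds(self, homog_batch):
        tau = default_tau_grid(48, 1e-7, 1e-1)
        g1 = g1_from_batch(homog_batch, np.array([MUA]), np.array([3e-6]), tau, 850.0)
        g2 = siegert(g1, 0.45)
        assert np.all(g2.values >= 1.0 - 1e-12)
        assert np.all(g2.values <= 1.45 + 1e-12)

    def test_siegert_rejects_invalid_beta(self):
        with pytest.raises(ValueError):
            siegert(np.array([1.0]), 1.5)
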