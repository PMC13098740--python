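"""Transport engine: conservation, reproducibility, bookkeeping identities."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from layerlut import (
    LayeredMedium,
    OpticalLayer,
    SimConfig,
    absorption_weights,
    fd_from_batch,
    fresnel_reflectance,
    pool_batches,
    run_layered_mc,
)

WL = 830.0


def _medium(layers):
    return LayeredMedium(tuple(layers))


def _layer(name, thickness, mua, musp, g=0.9, n=1.4, bfi=0.0):
    return OpticalLayer(name, thickness, {WL: mua}, {WL: musp}, g, n, bfi)


class TestFresnel:
    def test_matched_indices_zero(self):
        assert fresnel_reflectance(1.4, 1.4, 0.3) == 0.0

    def test_normal_incidence_closed_form(self):
        assert fresnel_reflectance(1.0, 1.4, 1.0) == pytest.approx((0.4 / 2.4) ** 2)

    def test_total_internal_reflection(self):
        # sin(theta) > 1/1.4  <=>  cos(theta) < sqrt(1 - 1/1.96)
        cos_beyond = 0.9 * math.sqrt(1 - (1 / 1.4) ** 2)
        assert fresnel_reflectance(1.4, 1.0, cos_beyond) == 1.0

    @given(
        st.floats(min_value=1.0, max_value=2.0),
        st.floats(min_value=1.0, max_value=2.0),
        st.floats(min_value=1e-3, max_value=1.0),
    )
    def test_is_a_probability(self, n1, n2, cosi):
        assert 0.0 <= fresnel_reflectance(n1, n2, cosi) <= 1.0


class TestConservationAndReproducibility:
    def test_weight_ledger_balances(self, homog_medium, fast_sim):
        b = run_layered_mc(homog_medium, fast_sim.with_(n_photons=20_000, seed=3), WL)
        a = b.accounting
        total = a["specular"] + a["escaped_top"] + a["absorbed"] + a["path_capped"] + a["roulette_net"]
        assert total == pytest.approx(a["launched_weight"], rel=1e-6)

    def test_baked_absorption_ledger_balances(self, homog_medium, fast_sim):
        b = run_layered_mc(
            homog_medium, fast_sim.with_(n_photons=20_000, seed=3), WL, bake_absorption=True
        )
        a = b.accounting
        assert a["absorbed"] > 0
        total = a["specular"] + a["escaped_top"] + a["absorbed"] + a["path_capped"] + a["roulette_net"]
        assert total == pytest.approx(a["launched_weight"], rel=1e-6)

    def test_same_seed_identical_batch(self, homog_medium, fast_sim):
        s = fast_sim.with_(n_photons=15_000, seed=11)
        b1 = run_layered_mc(homog_medium, s, WL)
        b2 = run_layered_mc(homog_medium, s, WL)
        np.testing.assert_array_equal(b1.L, b2.L)
        np.testing.assert_array_equal(b1.Y, b2.Y)
        np.testing.assert_array_equal(b1.detector_r, b2.detector_r)

    def test_different_seeds_binomially_compatible(self, homog_medium, fast_sim):
        counts = [
            run_layered_mc(homog_medium, fast_sim.with_(n_photons=40_000, seed=s), WL).n_detected
            for s in (21, 22, 23)
        ]
        mean = np.mean(counts)
        # detected counts scatter within a few binomial sigma of each other
        assert np.ptp(counts) < 8 * math.sqrt(mean)


class TestBookkeeping:
    def test_layer_split_is_identity_photon_by_photon(self, fast_sim):
        p = dict(mua=0.02, musp=0.8)
        one = _medium([_layer("a", math.inf, **p)])
        three = _medium(
            [_layer("a", 1.0, **p), _layer("b", 5.0, **p), _layer("c", math.inf, **p)]
        )
        s = fast_sim.with_(n_photons=15_000, seed=5)
        b1 = run_layered_mc(one, s, WL)
        b3 = run_layered_mc(three, s, WL)
        assert b1.n_detected == b3.n_detected
        np.testing.assert_allclose(b3.L.sum(axis=1), b1.L[:, 0], rtol=1e-12)
        np.testing.assert_allclose(b3.Y.sum(axis=1), b1.Y[:, 0], rtol=1e-9)

    def test_detector_distance_within_annulus(self, homog_batch):
        r = homog_batch.detector_r
        assert np.all(r >= homog_batch.sds - homog_batch.detector_half_width)
        assert np.all(r <= homog_batch.sds + homog_batch.detector_half_width)

    def test_pathlengths_and_momentum_nonnegative_and_consistent(self, homog_batch):
        assert np.all(homog_batch.L >= 0)
        assert np.all(homog_batch.Y >= 0)

    def test_unvisited_layer_has_zero_path_and_momentum(self, fast_sim):
        # deep third layer beyond the depth photons reach at this path cap
        med = _medium(
            [
                _layer("top", 1.0, 0.02, 1.0),
                _layer("mid", 120.0, 0.02, 1.0),
                _layer("deep", math.inf, 0.02, 1.0),
            ]
        )
        b = run_layered_mc(med, fast_sim.with_(n_photons=15_000, seed=9), WL)
        unvisited = b.L[:, 2] == 0
        assert unvisited.any()
        assert np.all(b.Y[:, 2][unvisited] == 0)

    def test_nonscattering_medium_detects_nothing_off_axis(self, fast_sim):
        med = _medium([_layer("clear", math.inf, 0.0, 0.0, g=0.0)])
        with pytest.warns(UserWarning, match="no photons detected"):
            b = run_layered_mc(med, fast_sim.with_(n_photons=2_000, seed=1), WL)
        assert b.n_detected == 0

    def test_zero_thickness_layer_is_noop(self, fast_sim):
        # a zero-thickness intermediate layer must not change transport at all
        from layerlut import tissue_medium

        m0 = tissue_medium("medium", 0.0)
        thick, *_ = m0.property_arrays(WL)
        assert len(thick) == 2


class TestWhiteMCEquivalence:
    def test_reweighted_equals_baked_absorption(self, homog_medium, fast_sim):
        """White MC + Beer reweighting must agree with absorption baked into
        propagation within Monte Carlo error (independent streams)."""
        mua = 0.01
        n_rep = 3
        amps = {True: [], False: []}
        for bake in (False, True):
            for i in range(n_rep):
                s = fast_sim.with_(n_photons=60_000, seed=500 + 97 * i + int(bake))
                b = run_layered_mc(homog_medium, s, WL, bake_absorption=bake)
                amps[bake].append(fd_from_batch(b, np.array([0.0 if bake else mua]), 0.0).amplitude)
        m_white, m_baked = np.mean(amps[False]), np.mean(amps[True])
        se = math.hypot(np.std(amps[False], ddof=1), np.std(amps[True], ddof=1)) / math.sqrt(n_rep)
        assert abs(m_white - m_baked) < 3.5 * se + 0.02 * m_white

    def test_absorption_weights_bounded_by_exit_weight(self, homog_batch):
        w = absorption_weights(homog_batch, np.array([0.05]))
        assert np.all(w > 0)
        assert np.all(w <= homog_batch.exit_weight + 1e-15)


class TestBatchPersistence:
    def test_hdf5_roundtrip(self, homog_batch, tmp_path):
        path = tmp_path / "batch.h5"
        homog_batch.to_hdf5(path)
        from layerlut import PhotonBatch

        back = PhotonBatch.from_hdf5(path)
        np.testing.assert_array_equal(back.L, homog_batch.L)
        np.testing.assert_array_equal(back.Y, homog_batch.Y)
        assert back.n_launched == homog_batch.n_launched
        assert back.accounting == pytest.approx(homog_batch.accounting)

    def test_pooling_concatenates_and_sums(self, homog_medium, fast_sim):
        b1 = run_layered_mc(homog_medium, fast_sim.with_(n_photons=5_000, seed=1), WL)
        b2 = run_layered_mc(homog_medium, fast_sim.with_(n_photons=5_000, seed=2), WL)
        pooled = pool_batches([b1, b2])
        assert pooled.n_detected == b1.n_detected + b2.n_detected
        assert pooled.n_launched == 10_000
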