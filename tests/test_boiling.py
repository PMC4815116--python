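"""Bubble-cloud detection, shielding, dilation, weights and composition."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hifusim.boiling import (
    NO_PLANE,
    BoilingModelParams,
    boiling_heat_source,
    boiling_region,
    boiling_step,
    cloud_convexity,
    compose_total_source,
    enhanced_zone,
    intercepted_power,
    shielding_coefficient,
)
from hifusim.grid import build_grid
from hifusim.heat import AxialPowerProfile

FOCUS = (0.0, 0.0, 0.038)


def grid33(n=33, dx=0.2e-3):
    return build_grid(n, n, n, dx, FOCUS, focus_index=(n // 2, n // 2, n // 2))


class TestBoilingRegion:
    def test_cold_field_empty(self):
        assert not boiling_region(np.full((4, 4, 4), 37.0), 85.0).any()

    def test_strict_inequality_at_threshold(self):
        T = np.full((3, 3, 3), 37.0)
        T[1, 1, 1] = 85.0
        assert not boiling_region(T, 85.0).any()
        T[1, 1, 1] = 85.0001
        assert boiling_region(T, 85.0).sum() == 1


class TestShielding:
    def test_empty_cloud(self):
        Q = np.ones((5, 5, 5))
        r, z = shielding_coefficient(Q, np.zeros((5, 5, 5), bool))
        assert r == 0.0 and z == NO_PLANE

    def test_full_plane_gives_unity(self):
        Q = np.ones((5, 5, 7))
        B = np.zeros((5, 5, 7), bool)
        B[:, :, 3] = True
        r, z = shielding_coefficient(Q, B)
        assert r == 1.0 and z == 3

    def test_max_over_planes_with_argmax_plane(self):
        Q = np.ones((10, 10, 6))
        B = np.zeros((10, 10, 6), bool)
        B[:4, :, 2] = True   # 40 % of plane 2
        B[:6, :, 4] = True   # 60 % of plane 4
        r, z = shielding_coefficient(Q, B)
        assert r == pytest.approx(0.6)
        assert z == 4

    def test_tie_resolves_to_most_proximal_plane(self):
        Q = np.ones((4, 4, 6))
        B = np.zeros((4, 4, 6), bool)
        B[:2, :, 1] = True
        B[:2, :, 4] = True
        _, z = shielding_coefficient(Q, B)
        assert z == 1

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_monotone_under_cloud_growth(self, seed):
        rng = np.random.default_rng(seed)
        Q = rng.uniform(0.0, 1.0, (6, 6, 6))
        B1 = rng.uniform(size=(6, 6, 6)) < 0.2
        extra = rng.uniform(size=(6, 6, 6)) < 0.2
        B2 = B1 | extra
        r1, _ = shielding_coefficient(Q, B1)
        r2, _ = shielding_coefficient(Q, B2)
        assert r2 >= r1 - 1e-12


def brute_force_dilate(B: np.ndarray, r_vox: float) -> np.ndarray:
    out = np.zeros_like(B)
    rr = int(math.floor(r_vox))
    offs = [
        (i, j, k)
        for i in range(-rr, rr + 1)
        for j in range(-rr, rr + 1)
        for k in range(-rr, rr + 1)
        if i * i + j * j + k * k <= r_vox * r_vox + 1e-9
    ]
    for idx in np.argwhere(B):
        for o in offs:
            t = idx + o
            if (t >= 0).all() and (t < B.shape).all():
                out[tuple(t)] = True
    return out


class TestEnhancedZone:
    def test_empty_cloud_empty_zone(self):
        g = grid33(9)
        assert not enhanced_zone(np.zeros(g.shape, bool), 1e-3, g).any()

    def test_single_voxel_radius_two_lattice_ball(self):
        g = grid33(9)
        B = np.zeros(g.shape, bool)
        B[4, 4, 4] = True
        H = enhanced_zone(B, 2 * g.dx, g)
        # lattice ball of radius 2: 1 + 6 + 12 + 8 + 6 = 33 offsets
        assert H.sum() == 33

    def test_single_voxel_reference_radius(self):
        g = grid33(33, dx=200e-6)
        B = np.zeros(g.shape, bool)
        B[16, 16, 16] = True
        H = enhanced_zone(B, 2.5e-3, g)
        count = sum(
            1
            for i in range(-12, 13)
            for j in range(-12, 13)
            for k in range(-12, 13)
            if i * i + j * j + k * k <= 12.5**2
        )
        assert H.sum() == count

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.floats(1.0, 3.5))
    def test_matches_brute_force_on_random_masks(self, seed, r_vox):
        g = grid33(11, dx=0.3e-3)
        rng = np.random.default_rng(seed)
        B = rng.uniform(size=g.shape) < 0.05
        H = enhanced_zone(B, r_vox * g.dx, g)
        assert (H == brute_force_dilate(B, r_vox)).all()

    def test_subvoxel_radius_rejected(self):
        g = grid33(9)
        with pytest.raises(ValueError):
            enhanced_zone(np.ones(g.shape, bool), 0.1 * g.dx, g)


class TestInterceptedPower:
    def test_arithmetic(self):
        prof = AxialPowerProfile(z_index=np.arange(5), P=np.full(5, 40.0))
        assert intercepted_power(0.5, 2, prof, 0.31) == pytest.approx(6.2)

    def test_zero_cases(self):
        prof = AxialPowerProfile(z_index=np.arange(5), P=np.full(5, 40.0))
        assert intercepted_power(0.0, NO_PLANE, prof, 0.31) == 0.0
        assert intercepted_power(0.5, 2, prof, 0.0) == 0.0


class TestConvexity:
    def test_centered_ball_convex(self):
        g = grid33(11)
        B = np.zeros(g.shape, bool)
        B[3:8, 3:8, 4:9] = True
        assert cloud_convexity(B, (5, 5))

    def test_ring_with_deeper_column_voxel_concave(self):
        B = np.zeros((9, 9, 9), bool)
        B[2:7, 2:7, 3] = True
        B[4, 4, 3] = False       # hole at the focal column
        B[4, 4, 5] = True        # column only present deeper
        assert not cloud_convexity(B, (4, 4))

    def test_single_voxel_on_column_convex(self):
        B = np.zeros((5, 5, 5), bool)
        B[2, 2, 3] = True
        assert cloud_convexity(B, (2, 2))

    def test_empty_cloud_rejected(self):
        with pytest.raises(ValueError):
            cloud_convexity(np.zeros((3, 3, 3), bool), (1, 1))


class TestBoilingHeatSource:
    def test_zero_power_zero_field(self):
        g = grid33(9)
        W = np.ones(g.shape)
        assert (boiling_heat_source(0.0, W, g) == 0).all()

    def test_single_voxel_receives_everything(self):
        g = grid33(9)
        W = np.zeros(g.shape)
        W[4, 4, 4] = 3.7
        Q = boiling_heat_source(2.0, W, g)
        assert Q[4, 4, 4] == pytest.approx(2.0 / g.dx**3)
        assert Q.sum() * g.dx**3 == pytest.approx(2.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.floats(0.01, 50.0))
    def test_power_bookkeeping_exact(self, seed, P_H):
        g = grid33(9)
        rng = np.random.default_rng(seed)
        W = rng.uniform(0.0, 1.0, g.shape)
        Q = boiling_heat_source(P_H, W, g)
        assert Q.sum() * g.dx**3 == pytest.approx(P_H, rel=1e-12)

    def test_all_zero_weights_rejected(self):
        g = grid33(9)
        with pytest.raises(ValueError):
            boiling_heat_source(1.0, np.zeros(g.shape), g)


class TestComposeTotalSource:
    def test_empty_cloud_returns_base(self):
        params = BoilingModelParams()
        Q0 = np.random.default_rng(5).uniform(size=(5, 5, 5))
        B = np.zeros((5, 5, 5), bool)
        out = compose_total_source(Q0, B, np.zeros_like(Q0), 0.0, NO_PLANE, params)
        assert np.allclose(out, Q0)

    def test_cloud_voxels_zeroed(self):
        params = BoilingModelParams()
        Q0 = np.ones((5, 5, 5))
        B = np.zeros((5, 5, 5), bool)
        B[2, 2, 2] = True
        out = compose_total_source(Q0, B, np.zeros_like(Q0), 0.5, 2, params)
        assert out[2, 2, 2] == 0.0

    def test_full_shielding_flag_blanks_distal_base(self):
        params = BoilingModelParams(postfocal_base_attenuation=True)
        Q0 = np.ones((5, 5, 6))
        B = np.zeros((5, 5, 6), bool)
        B[2, 2, 2] = True
        out = compose_total_source(Q0, B, np.zeros_like(Q0), 1.0, 2, params)
        assert (out[:, :, 3:] == 0).all()
        assert (out[:, :, :2] == 1).all()


class TestBoilingWeights:
    def _setup(self):
        from hifusim.boiling import boiling_weights, enhanced_zone

        g = grid33(15)
        B = np.zeros(g.shape, bool)
        B[7, 7, 7] = True
        H = enhanced_zone(B, 3 * g.dx, g)
        return g, B, H, boiling_weights

    def test_inverse_distance_ratio(self):
        g, B, H, boiling_weights = self._setup()
        W = boiling_weights(B, H, np.ones(g.shape), g, FOCUS, 14, 1.0, True,
                            BoilingModelParams())
        # adjacent voxel vs two voxels away along the same axis: ratio 2
        assert W[8, 7, 7] / W[9, 7, 7] == pytest.approx(2.0)
        assert W[7, 7, 7] == 0.0  # no deposition inside the cloud

    def test_w2_unity_up_to_shield_plane(self):
        g, B, H, boiling_weights = self._setup()
        W_all = boiling_weights(B, H, np.ones(g.shape), g, FOCUS, 14, 0.25,
                                True, BoilingModelParams())
        W_shield = boiling_weights(B, H, np.ones(g.shape), g, FOCUS, 7, 0.25,
                                   True, BoilingModelParams())
        # with z_shield at the top, all weights carry the W2=1 branch
        support = H & ~B
        zz = np.arange(g.nz)[None, None, :] * np.ones(g.shape, int)
        distal = support & (zz > 7)
        assert np.allclose(W_shield[distal] / W_all[distal], 0.25)
        proximal = support & (zz <= 7)
        assert np.allclose(W_shield[proximal], W_all[proximal])

    def test_convex_weights_proportional_to_source(self):
        g, B, H, boiling_weights = self._setup()
        rng = np.random.default_rng(13)
        Q0 = rng.uniform(0.5, 2.0, g.shape)
        W = boiling_weights(B, H, Q0, g, FOCUS, 14, 1.0, True,
                            BoilingModelParams())
        support = H & ~B
        from scipy import ndimage

        dist = ndimage.distance_transform_edt(~B)
        ratio = W[support] / (Q0[support] / dist[support])
        assert np.allclose(ratio, ratio.flat[0])


class TestBoilingStepIntegration:
    def test_no_cloud_passthrough(self):
        g = grid33(11)
        T = np.full(g.shape, 37.0)
        Q0 = np.ones(g.shape)
        prof = AxialPowerProfile(z_index=np.arange(11), P=np.full(11, 30.0))
        Q, state = boiling_step(T, Q0, prof, g, FOCUS, BoilingModelParams())
        assert Q is Q0
        assert state.P_H == 0.0 and not state.B.any()

    def test_cloud_redistributes_exact_power(self):
        g = grid33(21)
        T = np.full(g.shape, 37.0)
        T[10, 10, 10] = 95.0
        rng = np.random.default_rng(11)
        Q0 = rng.uniform(0.1, 1.0, g.shape) * 1e6
        prof = AxialPowerProfile(z_index=np.arange(21), P=np.full(21, 30.0))
        params = BoilingModelParams(R_SE=0.8e-3)
        Q, state = boiling_step(T, Q0, prof, g, FOCUS, params)
        assert state.B.sum() == 1
        assert (Q[state.B] == 0).all()
        # total = base outside cloud + exactly P_H
        expected = Q0[~state.B].sum() * g.dx**3 + state.P_H
        assert Q.sum() * g.dx**3 == pytest.approx(expected, rel=1e-9)
        assert state.P_H == pytest.approx(
            0.31 * state.r_shield * 30.0, rel=1e-12
        )

    def test_weight_regimes_convex_vs_concave(self):
        g = grid33(21)
        params = BoilingModelParams(R_SE=0.8e-3)
        prof = AxialPowerProfile(z_index=np.arange(21), P=np.full(21, 30.0))
        Q0 = np.ones(g.shape)
        # convex: single voxel on the focal column
        T = np.full(g.shape, 37.0)
        T[10, 10, 10] = 95.0
        _, s1 = boiling_step(T, Q0, prof, g, FOCUS, params)
        assert s1.convex
        # concave: off-column voxel shallower than the column voxel
        T = np.full(g.shape, 37.0)
        T[6, 6, 8] = 95.0
        T[10, 10, 12] = 95.0
        _, s2 = boiling_step(T, Q0, prof, g, FOCUS, params)
        assert not s2.convex
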