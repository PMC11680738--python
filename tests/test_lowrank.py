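"""Hankel lifting, singular value thresholding, and the POCS infill loop."""

import numpy as np
import pytest

import ztefill as z
from ztefill.evaluation import gap_sample_error
from ztefill.infill_lowrank import (
    LowRankConfig,
    hankel_lift,
    hankel_lift_multicoil,
    hankel_unlift,
    hankel_unlift_multicoil,
    lowrank_infill,
    svt,
)
from ztefill.nufft import cdft


def kspace_of_supported_image(n, support, rng, d=2):
    """Exact Cartesian k-space of a random image with given support box."""
    img = np.zeros((n,) * d, dtype=complex)
    sl = tuple(
        slice(n // 2 - support // 2, n // 2 - support // 2 + support)
        for _ in range(d)
    )
    img[sl] = rng.standard_normal((support,) * d) + 1j * rng.standard_normal(
        (support,) * d
    )
    return cdft(img)


class TestHankelLifting:
    def test_classic_1d_hankel_rows(self):
        rows = hankel_lift(np.array([1.0, 2.0, 3.0, 4.0]), 2)
        np.testing.assert_array_equal(
            rows, [[1.0, 2.0], [2.0, 3.0], [3.0, 4.0]]
        )

    def test_lift_is_linear(self, rng):
        a = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        b = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        lhs = hankel_lift(2 * a - 3j * b, 3)
        rhs = 2 * hankel_lift(a, 3) - 3j * hankel_lift(b, 3)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_unlift_inverts_lift(self, rng):
        v = rng.standard_normal((10, 10)) + 1j * rng.standard_normal((10, 10))
        m = hankel_lift(v, 4)
        np.testing.assert_allclose(hankel_unlift(m, (10, 10), 4), v, atol=1e-12)

    def test_unnormalized_unlift_is_adjoint(self, rng):
        v = rng.standard_normal((9, 9)) + 1j * rng.standard_normal((9, 9))
        m = rng.standard_normal((36, 16)) + 1j * rng.standard_normal((36, 16))
        lhs = np.vdot(hankel_lift(v, 4), m)
        rhs = np.vdot(v, hankel_unlift(m, (9, 9), 4, normalize=False))
        assert abs(lhs - rhs) / abs(lhs) < 1e-10

    def test_kernel_larger_than_volume_rejected(self):
        with pytest.raises(ValueError):
            hankel_lift(np.zeros((3, 3)), 4)

    def test_finite_support_gives_numerical_null_space(self, rng):
        ks = kspace_of_supported_image(16, 3, rng)
        m = hankel_lift(ks, 5)
        s = np.linalg.svd(m, compute_uv=False)
        assert s[-1] / s[0] < 1e-6

    def test_annihilation_filter_predicts_held_out_sample(self, rng):
        # 1D: 2-point support, 3-tap filter; the filter from the null space
        # of the training rows must predict a held-out row's last entry as
        # k3 = -(w1 k1 + w2 k2) / w3
        n = 16
        img = np.zeros(n, complex)
        img[n // 2 : n // 2 + 2] = rng.standard_normal(
            2
        ) + 1j * rng.standard_normal(2)
        ks = cdft(img)
        m = hankel_lift(ks, 3)
        train, held = m[:-1], m[-1]
        _, _, vh = np.linalg.svd(train)
        h = vh[-1].conj()
        assert abs(train @ h).max() < 1e-10
        w1, w2, w3 = h
        predicted = -(w1 * held[0] + w2 * held[1]) / w3
        assert abs(predicted - held[2]) / abs(held[2]) < 1e-6

    def test_relative_rank_decreases_with_support_ratio(self, rng):
        # numerical rank at the method's own 1.5% threshold
        n = 20
        ranks = []
        for support in (16, 10, 6):  # support ratios 0.8, 0.5, 0.3
            ks = kspace_of_supported_image(n, support, rng)
            m = hankel_lift(ks, 5)
            s = np.linalg.svd(m, compute_uv=False)
            num_rank = int(np.sum(s / s[0] > 0.015))
            ranks.append(num_rank / min(m.shape))
        assert ranks[0] > ranks[1] > ranks[2]

    def test_multicoil_lift_concatenates_columns(self, rng):
        v = rng.standard_normal((3, 8, 8)) + 1j * rng.standard_normal((3, 8, 8))
        m = hankel_lift_multicoil(v, 3)
        assert m.shape == (36, 27)
        back = hankel_unlift_multicoil(m, (8, 8), 3, 3)
        np.testing.assert_allclose(back, v, atol=1e-12)


class TestSvt:
    def test_low_rank_fixed_point_hard_mode(self, rng):
        u = np.linalg.qr(rng.standard_normal((20, 3)))[0]
        vt = np.linalg.qr(rng.standard_normal((15, 3)))[0].T
        m = u @ np.diag([5.0, 3.0, 1.0]) @ vt
        out = svt(m, "hard", 0.015)
        np.testing.assert_allclose(out, m, atol=1e-10)

    def test_threshold_arithmetic(self):
        m = np.diag([1.0, 0.02, 0.01])
        out = svt(m, "hard", 0.015)
        s = np.linalg.svd(out, compute_uv=False)
        np.testing.assert_allclose(np.sort(s)[::-1][:2], [1.0, 0.02], atol=1e-12)
        assert s[-1] < 1e-12

    @pytest.mark.parametrize("mode", ["hard", "soft"])
    def test_nuclear_norm_never_increases(self, mode, rng):
        m = rng.standard_normal((12, 8)) + 1j * rng.standard_normal((12, 8))
        before = np.linalg.svd(m, compute_uv=False).sum()
        after = np.linalg.svd(
            svt(m, mode, 0.1), compute_uv=False
        ).sum()
        assert after <= before + 1e-12

    def test_soft_mode_shrinks_all_values(self, rng):
        m = np.diag([2.0, 1.0, 0.5])
        out = svt(m, "soft", 0.1)  # threshold 0.2
        s = np.sort(np.linalg.svd(out, compute_uv=False))[::-1]
        np.testing.assert_allclose(s, [1.8, 0.8, 0.3], atol=1e-12)

    def test_zero_matrix_passthrough(self):
        m = np.zeros((4, 6))
        np.testing.assert_array_equal(svt(m), m)


@pytest.fixture(scope="module")
def lowrank_cfg():
    # desk-scale geometry: 40% spoke fraction keeps the covered radius at
    # ~12 dwells on the 64-voxel grid, matching the reference proportion
    return LowRankConfig(spoke_fraction=0.4, max_iter=300)


class TestLowRankInfill:
    def test_zero_gap_converges_immediately(
        self, kspace2d_small, traj2d_small, lowrank_cfg
    ):
        filled, trace = lowrank_infill(
            kspace2d_small, traj2d_small, z.DeadTimeGap(0.0), lowrank_cfg
        )
        np.testing.assert_array_equal(filled.data, kspace2d_small.data)
        assert trace.converged and trace.n_iter == 1

    def test_gap2_recovery_and_contract(
        self, kspace2d_small, traj2d_small, lowrank_cfg
    ):
        gap = z.DeadTimeGap(2.0)
        ng = z.missing_sample_count(2.0, 2.0)
        gapped = z.apply_gap(kspace2d_small, traj2d_small, gap)
        filled, trace = lowrank_infill(
            gapped, traj2d_small, gap, lowrank_cfg
        )
        assert trace.converged
        err = gap_sample_error(filled, kspace2d_small, traj2d_small, gap)
        assert err < 0.02
        # explicit-method contract: acquired samples bit-identical
        np.testing.assert_array_equal(
            filled.data[:, ng:, :], gapped.data[:, ng:, :]
        )
        assert filled.synthesized[:, :ng].all()

    def test_iterations_nondecreasing_in_gap(
        self, kspace2d_small, traj2d_small, lowrank_cfg
    ):
        iters = []
        for g in (1.0, 2.0, 2.5, 3.0):
            gap = z.DeadTimeGap(g)
            gapped = z.apply_gap(kspace2d_small, traj2d_small, gap)
            _, trace = lowrank_infill(gapped, traj2d_small, gap, lowrank_cfg)
            iters.append(trace.n_iter)
        assert np.all(np.diff(iters) >= 0)

    def test_nonconvergence_flagged_not_raised(
        self, kspace2d_small, traj2d_small
    ):
        gap = z.DeadTimeGap(2.0)
        gapped = z.apply_gap(kspace2d_small, traj2d_small, gap)
        cfg = LowRankConfig(spoke_fraction=0.4, max_iter=3)
        _, trace = lowrank_infill(gapped, traj2d_small, gap, cfg)
        assert not trace.converged
        assert trace.n_iter == 3

    def test_gap_beyond_center_region_rejected(
        self, kspace2d_small, traj2d_small
    ):
        cfg = LowRankConfig(spoke_fraction=0.05)
        with pytest.raises(ValueError):
            lowrank_infill(
                kspace2d_small, traj2d_small, z.DeadTimeGap(4.0), cfg
            )

    def test_config_validation(self):
        with pytest.raises(ValueError):
            LowRankConfig(threshold_frac=1.5)
        with pytest.raises(ValueError):
            LowRankConfig(tol=0.0)
        with pytest.raises(ValueError):
            LowRankConfig(threshold_mode="median")
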