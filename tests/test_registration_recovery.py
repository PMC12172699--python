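"""Ground-truth recovery of rigid, affine and FFD registration on phantoms.

Moving images are created by resampling the fixed phantom through a known
transform K; by the pull-back convention the registration should recover
K^-1, so the composed map (recovered ∘ K) must be close to the identity.
"""

import numpy as np
import pytest

from centiloid.registration import (AffineTransform, FFDTransform,
                                    apply_transform, nmi, register_affine,
                                    register_ffd, register_rigid)
from centiloid.phantom import make_random_ffd
from centiloid.volume_io import resample_to


def _warp(fixed, matrix, dof=12):
    moving = apply_transform(fixed, AffineTransform(matrix, dof=dof),
                             (fixed.shape, fixed.affine))
    moving.meta.pop("support_mask", None)
    return moving


class TestRigid:
    def test_identity_input_recovers_identity(self, reference_phantom):
        fixed, _ = reference_phantom
        t = register_rigid(fixed, fixed)
        assert np.abs(t.matrix[:3, 3]).max() < 0.1          # mm
        angle = np.rad2deg(np.arccos(np.clip((np.trace(t.matrix[:3, :3]) - 1) / 2, -1, 1)))
        assert angle < 0.1                                   # degrees

    def test_translation_recovery(self, reference_phantom):
        fixed, _ = reference_phantom
        K = np.eye(4)
        K[:3, 3] = (6.0, -4.0, 3.0)
        t = register_rigid(_warp(fixed, K, dof=6), fixed)
        residual = (t.matrix @ K)[:3, 3]
        assert np.abs(residual).max() < 0.5                  # mm per axis
        assert t.meta["nmi_final"] >= t.meta["nmi_init"]     # monotone improvement

    def test_rotation_recovery(self, reference_phantom):
        fixed, _ = reference_phantom
        th = np.deg2rad(5.0)
        K = np.eye(4)
        K[:2, :2] = [[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]]
        t = register_rigid(_warp(fixed, K, dof=6), fixed)
        M = t.matrix @ K
        angle = np.rad2deg(np.arccos(np.clip((np.trace(M[:3, :3]) - 1) / 2, -1, 1)))
        assert angle < 0.5

    def test_rigid_block_is_orthonormal(self, reference_phantom):
        fixed, _ = reference_phantom
        t = register_rigid(fixed, fixed)
        R = t.matrix[:3, :3]
        assert np.abs(R.T @ R - np.eye(3)).max() <= 1e-6


class TestAffine:
    def test_isotropic_scale_recovery(self, reference_phantom):
        fixed, _ = reference_phantom
        t = register_affine(_warp(fixed, np.diag([1.1, 1.1, 1.1, 1.0])), fixed)
        residual = t.matrix @ np.diag([1.1, 1.1, 1.1, 1.0])
        assert np.abs(np.diag(residual)[:3] - 1).max() < 0.02

    def test_shear_recovery(self, reference_phantom):
        fixed, _ = reference_phantom
        K = np.eye(4)
        K[0, 1] = 0.05
        t = register_affine(_warp(fixed, K), fixed)
        M = t.matrix @ K
        offdiag = M[:3, :3] - np.diag(np.diag(M[:3, :3]))
        assert np.abs(offdiag).max() < 0.02

    def test_determinism(self, reference_phantom):
        fixed, _ = reference_phantom
        K = np.eye(4)
        K[:3, 3] = (2.0, 1.0, -1.0)
        moving = _warp(fixed, K, dof=6)
        t1 = register_affine(moving, fixed)
        t2 = register_affine(moving, fixed)
        np.testing.assert_array_equal(t1.matrix, t2.matrix)


class TestFFD:
    def test_zero_lattice_is_identity_map(self, grid, sample_points):
        shape, affine = grid
        f = FFDTransform(np.zeros((6, 6, 5, 3)), origin=(-120, -120, -90),
                         spacing=(60, 60, 60))
        assert np.abs(f(sample_points) - sample_points).max() <= 1e-9

    def test_identity_input_stays_near_identity(self, reference_phantom, sample_points):
        fixed, _ = reference_phantom
        f = register_ffd(fixed, fixed)
        disp = np.linalg.norm(f.displacement(sample_points), axis=1)
        vox = np.sqrt((fixed.affine[:3, :3] ** 2).sum(axis=0)).min()
        assert disp.mean() <= 0.2 * vox

    def test_known_smooth_warp_recovery(self, reference_phantom, sample_points):
        """4 mm-amplitude 30 mm warp: mean residual displacement <= 1.5 mm."""
        fixed, _ = reference_phantom
        gt = make_random_ffd((fixed.shape, fixed.affine), 30.0, 4.0, seed=11)
        moving = apply_transform(fixed, gt, (fixed.shape, fixed.affine))
        moving.meta.pop("support_mask")
        f = register_ffd(moving, fixed)
        residual = np.linalg.norm(gt(f(sample_points)) - sample_points, axis=1)
        assert residual.mean() <= 1.5
        # must actually improve on doing nothing
        assert residual.mean() < np.linalg.norm(
            gt.displacement(sample_points), axis=1).mean()

    def test_pure_translation_after_affine_prestep(self, reference_phantom,
                                                   sample_points):
        fixed, _ = reference_phantom
        K = np.eye(4)
        K[:3, 3] = (4.0, -3.0, 2.0)
        moving = _warp(fixed, K, dof=6)
        pre_t = register_affine(moving, fixed)
        pre = apply_transform(moving, pre_t, (fixed.shape, fixed.affine))
        pre.meta.pop("support_mask")
        f = register_ffd(pre, fixed)
        total = (pre_t.matrix[:3, :3] @ (sample_points + f.displacement(sample_points)).T
                 + pre_t.matrix[:3, 3:4]).T
        residual = (K[:3, :3] @ total.T + K[:3, 3:4]).T - sample_points
        assert np.linalg.norm(residual, axis=1).mean() <= 0.5

    def test_spacing_below_two_voxels_rejected(self, reference_phantom):
        fixed, _ = reference_phantom
        with pytest.raises(ValueError, match="spacing"):
            register_ffd(fixed, fixed, grid_spacing_mm=4.0)  # voxels are 3 mm


class TestApplyTransform:
    def test_identity_matches_resample_to(self, reference_phantom):
        fixed, _ = reference_phantom
        a = apply_transform(fixed, AffineTransform(np.eye(4)), (fixed.shape, fixed.affine))
        b = resample_to(fixed, fixed)
        np.testing.assert_allclose(a.data, b.data, atol=1e-9)

    def test_translation_then_inverse_round_trip(self, reference_phantom):
        fixed, _ = reference_phantom
        K = np.eye(4)
        K[:3, 3] = (4.5, -2.5, 1.5)
        t = AffineTransform(K, dof=6)
        there = apply_transform(fixed, t, (fixed.shape, fixed.affine))
        back = apply_transform(there, t.invert(), (fixed.shape, fixed.affine))
        inside = back.meta["support_mask"] & there.meta["support_mask"]
        rms = np.sqrt(np.mean((back.data[inside] - fixed.data[inside]) ** 2))
        assert rms <= 0.02 * np.ptp(fixed.data)

    def test_nearest_keeps_mask_binary_through_ffd(self, vois, grid):
        f = make_random_ffd(grid, 40.0, 3.0, seed=2)
        out = apply_transform(vois.target, f, grid, interpolation="nearest")
        assert set(np.unique(out.data)) <= {0.0, 1.0}


def test_transform_serialization_round_trip(tmp_path, grid):
    from centiloid.registration import load_transform, save_transform

    a = AffineTransform(np.diag([1.05, 1.0, 0.98, 1.0]))
    save_transform(a, tmp_path / "aff.yaml")
    a2 = load_transform(tmp_path / "aff.yaml")
    np.testing.assert_allclose(a2.matrix, a.matrix)

    f = make_random_ffd(grid, 40.0, 3.0, seed=5)
    save_transform(f, tmp_path / "ffd.yaml")
    f2 = load_transform(tmp_path / "ffd.yaml")
    rng = np.random.default_rng(0)
    pts = rng.uniform(-60, 60, size=(100, 3))
    np.testing.assert_allclose(f2.displacement(pts), f.displacement(pts), atol=1e-4)
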