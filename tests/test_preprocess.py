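"""Registration, rigid extraction, cropping and templates."""

import numpy as np
import pytest

from fetalvol.preprocess import (
    AffineTransform,
    RigidTransform,
    apply_transform,
    build_template,
    register_affine,
    reorient_and_crop,
    rigid_part,
)
from fetalvol.synthetic import PhantomSpec, make_phantom
from fetalvol.volumes import BinaryMask, Volume, VolumeGrid, normalize_intensity


def _euler(ax_deg):
    t = AffineTransform(np.eye(3), (0, 0, 0))
    from fetalvol.preprocess import _euler_matrix

    return _euler_matrix(ax_deg)


class TestTransforms:
    def test_affine_matrix_roundtrip_text(self, tmp_path):
        t = AffineTransform(
            np.array([[1.1, 0.1, 0.0], [0.0, 0.9, 0.05], [0.0, 0.0, 1.0]]),
            (2.0, -1.0, 0.5),
            centre=(8.0, 8.0, 8.0),
        )
        path = tmp_path / "t.txt"
        t.to_text(path)
        t2 = AffineTransform.from_text(path)
        x = np.array([3.0, 4.0, 5.0])
        np.testing.assert_allclose(t2(x), t(x), atol=1e-6)

    def test_inverse_composes_to_identity(self):
        t = AffineTransform(
            _euler((5.0, -3.0, 8.0)) * 1.1, (4.0, 1.0, -2.0), centre=(10, 10, 10)
        )
        x = np.array([2.0, 7.0, 4.0])
        np.testing.assert_allclose(t.inverse()(t(x)), x, atol=1e-9)

    def test_rigid_requires_orthonormal_rotation(self):
        with pytest.raises(ValueError, match="orthonormal"):
            RigidTransform(np.eye(3) * 1.2, (0, 0, 0))


class TestRigidPart:
    def test_rotation_times_scale_recovers_rotation(self):
        rot = _euler((10.0, 20.0, -5.0))
        t = AffineTransform(rot * 1.2, (1.0, 2.0, 3.0))
        r = rigid_part(t)
        # polar-factor oracle via SVD
        u, _, vt = np.linalg.svd(rot * 1.2)
        np.testing.assert_allclose(r.linear, u @ vt, atol=1e-10)
        np.testing.assert_allclose(r.linear, rot, atol=1e-10)
        np.testing.assert_allclose(r.translation, t.translation)

    def test_identity_affine_gives_identity_rigid(self):
        r = rigid_part(AffineTransform(np.eye(3), (0, 0, 0)))
        np.testing.assert_allclose(r.linear, np.eye(3), atol=1e-12)

    def test_reflection_rejected(self):
        refl = np.diag([-1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="reflection"):
            rigid_part(AffineTransform(refl, (0, 0, 0)))

    def test_idempotent(self):
        t = AffineTransform(_euler((7.0, 0.0, 3.0)) * 0.9, (1.0, 0.0, 0.0))
        once = rigid_part(t)
        twice = rigid_part(once)
        np.testing.assert_allclose(twice.linear, once.linear, atol=1e-12)


class TestRegistration:
    def test_self_registration_is_identity(self, phantom_pair):
        vol, _, _, _ = phantom_pair
        t = register_affine(vol, vol, dof=6)
        assert np.linalg.norm(t.translation) < 0.5  # < 0.5 voxel at 1 mm
        angle = np.degrees(np.arccos(np.clip((np.trace(rigid_part(t).linear) - 1) / 2, -1, 1)))
        assert angle < 1.0
        assert t.objective > 0.99

    def test_translation_recovery_within_1mm(self, phantom_pair):
        vol, _, _, spec = phantom_pair
        moved_spec = PhantomSpec(
            **{**spec.__dict__, "translation_mm": (6.0, -4.0, 2.0)}
        )
        moving = normalize_intensity(make_phantom(moved_spec)[0])
        t = register_affine(moving, vol, dof=6)
        np.testing.assert_allclose(t.translation, (6.0, -4.0, 2.0), atol=1.0)

    def test_rotation_recovery_within_2deg(self, phantom_pair):
        vol, _, _, spec = phantom_pair
        rot_spec = PhantomSpec(**{**spec.__dict__, "rotation_deg": (10.0, 0.0, 0.0)})
        moving = normalize_intensity(make_phantom(rot_spec)[0])
        t = register_affine(moving, vol, dof=6)
        r = rigid_part(t)
        ang = np.degrees(np.arctan2(r.linear[2, 1], r.linear[1, 1]))
        assert abs(ang - 10.0) < 2.0

    def test_composition_consistency_over_random_poses(self, phantom_pair):
        """Registering a warped phantom recovers the applied transform."""
        vol, _, _, _ = phantom_pair
        rng = np.random.default_rng(99)
        centre = (np.array(vol.shape) - 1) / 2.0 * vol.spacing_mm
        from fetalvol.preprocess import _euler_matrix

        n_ok = 0
        n_poses = 8
        for _ in range(n_poses):
            angles = rng.uniform(-12, 12, 3)
            trans = rng.uniform(-4, 4, 3)
            known = RigidTransform(_euler_matrix(angles), trans, centre)
            moving = apply_transform(vol, known)  # moving(x) = vol(known(x))
            t = register_affine(moving, vol, dof=12)
            recovered = rigid_part(t)
            # expected: T = known^{-1}
            expected = np.linalg.inv(known.as_matrix())
            err_lin = np.abs(recovered.as_matrix()[:3, :3] - expected[:3, :3]).max()
            err_t = np.abs(recovered.as_matrix()[:3, 3] - expected[:3, 3]).max()
            if err_lin < 0.04 and err_t < 1.5:
                n_ok += 1
        assert n_ok >= n_poses - 1


class TestReorientAndCrop:
    def test_crop_contains_ground_truth_mask(self, phantom_pair):
        vol, mask, _, _ = phantom_pair
        identity = RigidTransform(np.eye(3), (0, 0, 0))
        out = reorient_and_crop(vol, identity, margin_mm=2.0, target_spacing_mm=1.0)
        # foreground (head) extent must fit inside the crop
        idx = np.nonzero(mask.data)
        head_extent = [int(i.max()) - int(i.min()) + 1 for i in idx]
        assert all(o >= h for o, h in zip(out.shape, head_extent))
        assert all(o <= s for o, s in zip(out.shape, vol.shape))

    def test_zero_margin_equals_tight_bounding_box(self, phantom_pair):
        vol, _, _, _ = phantom_pair
        identity = RigidTransform(np.eye(3), (0, 0, 0))
        out = reorient_and_crop(vol, identity, margin_mm=0.0, target_spacing_mm=1.0)
        fg = vol.data > 0.1
        import scipy.ndimage as ndi

        labels, n = ndi.label(fg)
        sizes = ndi.sum_labels(fg, labels, index=np.arange(1, n + 1))
        fg = labels == (int(np.argmax(sizes)) + 1)
        idx = np.nonzero(fg)
        expected = tuple(int(i.max()) - int(i.min()) + 1 for i in idx)
        assert out.shape == expected

    def test_empty_foreground_is_error(self, small_grid):
        dark = Volume(np.zeros(small_grid.shape), small_grid)
        with pytest.raises(ValueError, match="foreground"):
            reorient_and_crop(dark, RigidTransform(np.eye(3), (0, 0, 0)))

    def test_resamples_to_target_spacing(self, phantom_pair):
        vol, _, _, _ = phantom_pair
        identity = RigidTransform(np.eye(3), (0, 0, 0))
        out = reorient_and_crop(vol, identity, margin_mm=1.0, target_spacing_mm=0.5)
        assert out.spacing_mm == pytest.approx(0.5)


class TestTemplate:
    def test_single_input_is_identity(self, random_volume, random_mask):
        t = build_template([(random_volume, random_mask)], wave="20w")
        np.testing.assert_allclose(t.template_volume.data, random_volume.data)
        np.testing.assert_array_equal(t.template_mask.data, random_mask.data)

    def test_two_identical_inputs(self, random_volume, random_mask):
        t = build_template([(random_volume, random_mask)] * 2, wave="30w")
        np.testing.assert_allclose(t.template_volume.data, random_volume.data)
        np.testing.assert_array_equal(t.template_mask.data, random_mask.data)

    def test_majority_vote_patterns(self, small_grid):
        vol = Volume(np.full(small_grid.shape, 0.5), small_grid)

        def mk(on):
            d = np.zeros(small_grid.shape, dtype=np.uint8)
            d[0, 0, 0] = 1  # always ensure non-empty template
            for c in on:
                d[c] = 1
            return BinaryMask(d, small_grid)

        m1 = mk([(2, 2, 2), (3, 3, 3)])
        m2 = mk([(2, 2, 2)])
        m3 = mk([])
        t = build_template([(vol, m1), (vol, m2), (vol, m3)], wave="20w")
        assert t.template_mask.data[2, 2, 2] == 1  # 2 votes of 3
        assert t.template_mask.data[3, 3, 3] == 0  # 1 vote of 3

    def test_mismatched_grids_rejected(self, random_volume, random_mask):
        other = Volume(np.zeros((8, 8, 8)), VolumeGrid((8, 8, 8), 1.0))
        om = BinaryMask(np.zeros((8, 8, 8), dtype=np.uint8), VolumeGrid((8, 8, 8), 1.0))
        with pytest.raises(ValueError, match="common grid"):
            build_template([(random_volume, random_mask), (other, om)], wave="20w")
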