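"""Augmentation: printed matrices, exact label updates, moment oracles."""

import math

import numpy as np
import pytest

from capstrack.augment import (
    AugmentPlan,
    SampleRejectedError,
    augment_dataset,
    crop_borders,
    resize_with_labels,
    rotate_with_labels,
    rotation_matrix,
    shift_with_labels,
    translation_matrix,
    warp_affine,
)
from capstrack.geometry import ImageFrame, PoseLabel, StateLabel, angular_distance
from capstrack.synthetic import mask_moment_pose, render_frame


class TestRotationMatrix:
    def test_identity(self):
        assert np.allclose(rotation_matrix(0.0, 1.0, 10, 20),
                           [[1, 0, 0], [0, 1, 0]])

    def test_ninety_degrees_about_origin(self):
        assert np.allclose(rotation_matrix(90.0, 1.0, 0, 0),
                           [[0, 1, 0], [-1, 0, 0]], atol=1e-12)

    def test_entries_and_fixed_point(self):
        theta, c, cx, cy = 30.0, 1.0, 100.0, 50.0
        alpha = c * math.cos(math.radians(theta))
        beta = c * math.sin(math.radians(theta))
        m = rotation_matrix(theta, c, cx, cy)
        expected = [[alpha, beta, (1 - alpha) * cx - beta * cy],
                    [-beta, alpha, beta * cx + (1 - alpha) * cy]]
        assert np.allclose(m, expected)
        # the rotation center is a fixed point of the map
        assert np.allclose(m @ [cx, cy, 1.0], [cx, cy])

    def test_invalid_scale(self):
        with pytest.raises(ValueError):
            rotation_matrix(5.0, 0.0)


@pytest.fixture(scope="module")
def rendered(tiny_config_module=None):
    from capstrack.synthetic import PhantomConfig

    cfg = PhantomConfig.tiny()
    pose = PoseLabel(cfg.width / 2, cfg.height / 2, 30.0)
    frame, mask, rec = render_frame(cfg, StateLabel.CLOSED, pose, seed=21)
    return cfg, frame, mask, pose, rec.corners


class TestRotateWithLabels:
    def test_zero_rotation_is_identity(self, rendered):
        _, frame, _, pose, corners = rendered
        s = rotate_with_labels(frame, pose, 0.0, AugmentPlan(rotation_angles=(5.0,)),
                               corners)
        assert np.array_equal(s.frame.pixels, frame.pixels)
        assert (s.pose.x, s.pose.y, s.pose.theta) == pytest.approx(
            (pose.x, pose.y, pose.theta))

    def test_center_pose_gains_delta(self, rendered):
        _, frame, _, pose, corners = rendered
        s = rotate_with_labels(frame, pose, 2.0, AugmentPlan(), corners)
        # the capsule sits at the rotation center: centroid fixed, theta + 2
        assert (s.pose.x, s.pose.y) == pytest.approx((pose.x, pose.y), abs=1e-9)
        assert s.pose.theta == pytest.approx(pose.theta + 2.0)

    def test_moment_oracle_after_rotation(self, rendered):
        """Image-moment orientation of the rotated soft mask matches the
        updated label within 0.5 deg."""
        _, frame, mask, pose, corners = rendered
        delta = 4.0
        s = rotate_with_labels(frame, pose, delta, AugmentPlan(), corners)
        m = rotation_matrix(delta, 1.0, frame.w / 2, frame.h / 2)
        soft = warp_affine(mask.astype(float), m, order=1)
        mp = mask_moment_pose(soft)
        assert angular_distance(mp.theta, s.pose.theta) < 0.5
        assert math.hypot(mp.x - s.pose.x, mp.y - s.pose.y) < 1.0

    def test_out_of_frame_rejected(self):
        from capstrack.synthetic import PhantomConfig

        cfg = PhantomConfig.tiny()
        # capsule close to the left edge: a 5-deg rotation about the image
        # center sweeps it out of bounds
        pose = PoseLabel(cfg.workspace_margin_px, 5.0, 0.0)
        from capstrack.synthetic import capsule_corners

        corners = capsule_corners(pose, cfg.capsule_length_px, cfg.capsule_diameter_px)
        frame = ImageFrame(np.zeros((cfg.height, cfg.width), np.uint8), 0.5)
        with pytest.raises(SampleRejectedError):
            rotate_with_labels(frame, pose, 5.0, AugmentPlan(), corners)


class TestShiftWithLabels:
    def test_zero_shift_identity(self, rendered):
        _, frame, _, pose, corners = rendered
        s = shift_with_labels(frame, pose, 0, 0, corners)
        assert np.array_equal(s.frame.pixels, frame.pixels)
        assert s.pose == pose

    def test_labels_additive(self, rendered):
        _, frame, _, pose, corners = rendered
        s = shift_with_labels(frame, pose, 10, 12, corners)
        assert (s.pose.x, s.pose.y) == (pose.x + 10, pose.y + 12)
        assert s.pose.theta == pose.theta

    def test_shift_composition_recovers_labels(self, rendered):
        _, frame, _, pose, corners = rendered
        s = shift_with_labels(frame, pose, 5, 0, corners)
        back = shift_with_labels(s.frame, s.pose, -5, 0, s.corners)
        assert back.pose == pose
        assert np.allclose(back.corners.as_array(), corners.as_array())


class TestCropBorders:
    def test_zero_margin_identity(self, rendered):
        _, frame, _, pose, corners = rendered
        s = crop_borders(frame, pose, 0, corners)
        assert s.frame is frame and s.pose is pose

    def test_arithmetic(self):
        frame = ImageFrame(np.zeros((224, 224), np.uint8), 1.0)
        s = crop_borders(frame, PoseLabel(112, 112, 0), 16)
        assert s.frame.pixels.shape == (192, 192)
        assert (s.pose.x, s.pose.y) == (96.0, 96.0)

    def test_no_border_fill_pixels_survive_crop(self):
        """An indicator channel tracked through any single rotation <= 5 deg
        or shift <= (10, 12) contains no zero-injected pixels after the
        16-px crop on a 224x224 frame (variants apply one transform each)."""
        ind = np.ones((224, 224), dtype=float)
        transforms = [rotation_matrix(d, 1.0, 112, 112) for d in (0.5, 2.5, 5.0)]
        transforms += [translation_matrix(tx, ty)
                       for tx, ty in ((10, 12), (-10, -10), (0, 12))]
        for m in transforms:
            out = warp_affine(ind, m, order=1)
            assert (out[16:-16, 16:-16] > 0.999).all()

    def test_capsule_in_band_rejected(self, rendered):
        cfg, frame, _, pose, corners = rendered
        with pytest.raises(SampleRejectedError):
            crop_borders(frame, pose, int(cfg.width // 2 - 4), corners)

    def test_margin_too_large(self, rendered):
        _, frame, _, pose, _ = rendered
        with pytest.raises(ValueError):
            crop_borders(frame, pose, frame.w // 2, None)


class TestResizeWithLabels:
    def test_square_resize_scales_pose(self, rendered):
        _, frame, mask, pose, _ = rendered
        s = resize_with_labels(frame, pose, target=128)
        scale = 128 / frame.w
        assert (s.pose.x, s.pose.y) == pytest.approx(
            (pose.x * scale, pose.y * scale))
        assert s.pose.theta == pytest.approx(pose.theta, abs=1e-9)
        assert s.frame.pixels.shape == (128, 128)


class TestAugmentDataset:
    def test_default_plan_has_ten_rotation_angles(self):
        assert AugmentPlan().rotation_angles == tuple(
            pytest.approx(0.5 * k) for k in range(1, 11))

    def test_rotations_only_counts(self, mixed_manifest):
        plan = AugmentPlan(rotation_angles=(1.0, 2.0), crop_margin=0,
                           shifts_per_image=0)
        out = augment_dataset(mixed_manifest, plan, out_dir="",
                              images=mixed_manifest.images)
        # every record yields 1 base + 2 rotations when nothing is rejected
        assert len(out) == len(mixed_manifest) * 3

    def test_base_of_five_images_yields_55_records(self, tiny_config, tmp_path):
        from capstrack.synthetic import render_dataset_arrays

        images, manifest = render_dataset_arrays(
            tiny_config, {StateLabel.LOST: 5}, seed=13)
        manifest.images = {r.path: im for r, im in zip(manifest, images)}
        plan = AugmentPlan(crop_margin=0, shifts_per_image=0)  # 10 default angles
        out = augment_dataset(manifest, plan, out_dir="", images=manifest.images)
        assert len(out) == 55

    def test_lost_records_keep_null_pose(self, mixed_manifest):
        plan = AugmentPlan(rotation_angles=(2.0,), crop_margin=0, shifts_per_image=1)
        out = augment_dataset(mixed_manifest, plan, out_dir="",
                              images=mixed_manifest.images)
        for rec in out:
            assert (rec.pose is None) == (rec.state is StateLabel.LOST)

    def test_determinism(self, mixed_manifest):
        plan = AugmentPlan(rotation_angles=(1.5,), crop_margin=2, shifts_per_image=2)
        a = augment_dataset(mixed_manifest, plan, "", seed=3, images=mixed_manifest.images)
        b = augment_dataset(mixed_manifest, plan, "", seed=3, images=mixed_manifest.images)
        assert [r.path for r in a] == [r.path for r in b]
        assert all(np.array_equal(a.images[p], b.images[p]) for p in a.images)

    def test_variant_labels_match_transformed_masks(self):
        """Every augmented closed record's label agrees with the moment pose
        of the identically transformed soft mask within 1 px / 0.5 deg."""
        from capstrack.synthetic import PhantomConfig, render_dataset_arrays

        cfg = PhantomConfig(width=224, height=224, scale_mm_per_px=0.25, seed=0)
        images, masks, manifest = render_dataset_arrays(
            cfg, {StateLabel.CLOSED: 8}, seed=31, with_masks=True)
        manifest.images = {r.path: im for r, im in zip(manifest, images)}
        mask_by_path = {r.path: m for r, m in zip(manifest, masks)}
        plan = AugmentPlan(rotation_angles=(2.0, 4.0), shift_range_x=(-10, 10),
                           shift_range_y=(-10, 12), crop_margin=16,
                           shifts_per_image=1, seed=5)
        out = augment_dataset(manifest, plan, "", seed=5, images=manifest.images)
        h = w = 224
        checked = 0
        for rec in out:
            if not rec.aug_kind:
                continue
            soft = mask_by_path[rec.base_path].astype(float)
            if rec.aug_kind == "rotate":
                m = rotation_matrix(float(rec.aug_param), 1.0, w / 2, h / 2)
            else:
                tx, ty = (int(v) for v in rec.aug_param.split(","))
                m = translation_matrix(tx, ty)
            soft = warp_affine(soft, m, order=1)[plan.crop_margin:-plan.crop_margin,
                                                 plan.crop_margin:-plan.crop_margin]
            mp = mask_moment_pose(soft)
            assert math.hypot(mp.x - rec.pose.x, mp.y - rec.pose.y) < 1.0
            assert angular_distance(mp.theta, rec.pose.theta) < 0.5
            checked += 1
        assert checked > 10

    def test_angle_histogram_at_least_as_uniform(self, tiny_config):
        """Rotation expansion must not make the theta histogram less
        uniform (chi-square statistic does not increase)."""
        from scipy import stats

        from capstrack.synthetic import render_dataset_arrays

        images, manifest = render_dataset_arrays(
            tiny_config, {StateLabel.CLOSED: 60}, seed=17)
        manifest.images = {r.path: im for r, im in zip(manifest, images)}
        plan = AugmentPlan(crop_margin=0, shifts_per_image=0)
        out = augment_dataset(manifest, plan, "", images=manifest.images)

        def chi2_per_sample(man):
            thetas = [r.pose.theta for r in man if r.pose is not None]
            hist, _ = np.histogram(thetas, bins=18, range=(0, 180))
            # per-sample statistic so datasets of different size compare
            return stats.chisquare(hist).statistic / len(thetas)

        assert chi2_per_sample(out) <= chi2_per_sample(manifest) + 1e-9
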