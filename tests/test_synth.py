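"""Synthetic scene generator: spectra, cameras, rendering, augmentation."""

import itertools

import numpy as np
import pytest

from endospectra import BoundingBox, spectrum_rmse
from endospectra.errors import ConfigurationError
from endospectra.grid import DEFAULT_GRID
from endospectra.stages import LESION_STAGES, STAGE_ORDER, StageLabel
from endospectra.synth import (
    Lesion,
    SceneSpec,
    TissueSpectrumModel,
    _mass_window_width,
    apply_augmentation,
    augment,
    capture_color_target,
    make_color_target,
    make_stage_spectra,
    make_test_set,
    nbi_camera,
    render_rgb,
    wli_camera,
)


class TestStageSpectra:
    def test_four_distinct_stage_means(self, tissue_model):
        means = make_stage_spectra(tissue_model)
        assert set(means) == set(STAGE_ORDER)
        floor = 3 * tissue_model.noise_sd
        for a, b in itertools.combinations(STAGE_ORDER, 2):
            assert spectrum_rmse(means[a], means[b]) > floor

    def test_deterministic_per_seed(self):
        m1 = make_stage_spectra(TissueSpectrumModel(seed=7))
        m2 = make_stage_spectra(TissueSpectrumModel(seed=7))
        for stage in STAGE_ORDER:
            assert np.array_equal(m1[stage], m2[stage])

    def test_unsatisfiable_separation_rejected(self):
        with pytest.raises(ConfigurationError):
            make_stage_spectra(TissueSpectrumModel(noise_sd=0.5, seed=1))

    def test_zero_noise_scene_pixels_equal_stage_mean(self, wli_cam):
        tissue = TissueSpectrumModel(smooth_amplitude=0.0, noise_sd=0.0, seed=3)
        means = make_stage_spectra(tissue)
        scene = SceneSpec(width=16, height=16, seed=3)
        rendered = render_rgb(scene, tissue, wli_cam)
        assert np.allclose(rendered.true_spectra,
                           means[StageLabel.NORMAL][None, None, :], atol=1e-6)


class TestColorTarget:
    def test_24_mutually_distinct_patches(self, seed1_target):
        assert len(seed1_target.patch_ids) == 24
        for i, j in itertools.combinations(range(24), 2):
            assert spectrum_rmse(seed1_target.spectra[i],
                                 seed1_target.spectra[j]) > 0.03

    def test_spectra_within_unit_range(self, seed1_target):
        assert seed1_target.spectra.min() >= 0.0
        assert seed1_target.spectra.max() <= 1.0

    def test_deterministic_per_seed(self):
        t1 = make_color_target(seed=5)
        t2 = make_color_target(seed=5)
        assert np.array_equal(t1.spectra, t2.spectra)


class TestCameras:
    def test_nbi_curves_are_narrow(self):
        cam = nbi_camera()
        for curve in cam.sensitivities:
            assert _mass_window_width(curve, DEFAULT_GRID) <= 60.0

    def test_wli_curves_are_broad(self):
        cam = wli_camera()
        assert all(_mass_window_width(c, DEFAULT_GRID) > 60.0
                   for c in cam.sensitivities)

    def test_capture_of_zero_reflectance_is_black(self, wli_cam):
        spectra = np.zeros((1, 401))
        rgb, _ = wli_cam.render(spectra)
        assert np.all(rgb == 0.0)

    def test_exposure_linearity_before_transfer(self, seed1_target):
        lo = wli_camera(exposure=0.3)
        hi = wli_camera(exposure=0.6)
        lin_lo, _ = lo.render_linear(seed1_target.spectra)
        lin_hi, _ = hi.render_linear(seed1_target.spectra)
        unclipped = (lin_hi < 1.0) & (lin_lo < 1.0)
        assert np.allclose(lin_hi[unclipped], 2 * lin_lo[unclipped], rtol=1e-12)

    def test_captured_patches_distinct_at_8bit(self, seed1_target, wli_cam):
        rgb = capture_color_target(seed1_target, wli_cam)
        quantized = {tuple(np.round(row * 255).astype(int)) for row in rgb}
        assert len(quantized) == 24


class TestRendering:
    def test_single_lesion_box_is_tight_ellipse_bbox(self, tissue_model, wli_cam):
        lesion = Lesion(center=(50.0, 40.0), axes=(12.0, 8.0), angle=0.0,
                        stage=StageLabel.INVASIVE_CANCER)
        scene = SceneSpec(width=100, height=80, lesions=(lesion,), seed=2)
        rendered = render_rgb(scene, tissue_model, wli_cam)
        assert len(rendered.boxes) == 1
        box, stage = rendered.boxes[0]
        assert stage is StageLabel.INVASIVE_CANCER
        assert box.as_tuple() == pytest.approx((38, 32, 62, 48))

    def test_rotated_ellipse_bbox_closed_form(self):
        import math
        lesion = Lesion(center=(50.0, 50.0), axes=(10.0, 5.0), angle=math.pi / 2,
                        stage=StageLabel.LOW_GRADE_DYSPLASIA)
        # rotated 90 degrees: width/height swap
        assert lesion.bounding_box().as_tuple() == pytest.approx((45, 40, 55, 60))

    def test_zero_exposure_renders_black(self, tissue_model):
        cam = wli_camera(exposure=0.0)
        scene = SceneSpec(width=8, height=8, seed=1)
        rendered = render_rgb(scene, tissue_model, cam)
        assert np.all(rendered.rgb == 0.0)

    def test_wli_and_nbi_render_differently(self, tissue_model, seed1_scene):
        scene = SceneSpec(width=32, height=32, seed=1)
        a = render_rgb(scene, tissue_model, wli_camera())
        b = render_rgb(scene, tissue_model, nbi_camera())
        assert np.mean(np.abs(a.rgb - b.rgb)) > 0.01

    def test_lesion_outside_image_rejected(self):
        lesion = Lesion(center=(5.0, 5.0), axes=(10.0, 10.0), angle=0.0,
                        stage=StageLabel.INVASIVE_CANCER)
        with pytest.raises(ConfigurationError):
            SceneSpec(width=64, height=64, lesions=(lesion,))

    def test_channels_in_unit_range(self, seed1_scene):
        assert seed1_scene.rgb.min() >= 0.0 and seed1_scene.rgb.max() <= 1.0
        assert seed1_scene.true_spectra.min() >= 0.0


class TestAugmentation:
    @pytest.fixture()
    def sample(self, rng):
        image = rng.uniform(0, 1, (100, 100, 3))
        boxes = [(BoundingBox(10, 20, 30, 60), StageLabel.INVASIVE_CANCER)]
        return image, boxes

    @pytest.mark.parametrize("op", ["hflip", "vflip", "rot180"])
    def test_involution(self, sample, op):
        image, boxes = sample
        img1, b1 = apply_augmentation(image, boxes, op)
        img2, b2 = apply_augmentation(img1, b1, op)
        assert np.array_equal(img2, image)
        assert b2[0][0].as_tuple() == boxes[0][0].as_tuple()

    def test_rot90_swaps_box_dimensions(self, rng):
        image = rng.uniform(0, 1, (100, 100, 3))
        boxes = [(BoundingBox(0, 0, 10, 20), StageLabel.INVASIVE_CANCER)]
        img, newb = apply_augmentation(image, boxes, "rot90")
        box = newb[0][0]
        assert (box.width, box.height) == (20, 10)
        assert box.area == 200
        assert box.as_tuple() == (80, 0, 100, 10)

    def test_rot90_pixels_track_boxes(self, rng):
        """The pixel content inside the box moves with the box."""
        image = np.zeros((50, 50))
        image[5:15, 20:30] = 1.0  # rows 5-15 (y), cols 20-30 (x)
        boxes = [(BoundingBox(20, 5, 30, 15), StageLabel.INVASIVE_CANCER)]
        img, newb = apply_augmentation(image, boxes, "rot90")
        b = newb[0][0]
        assert img[int(b.ymin):int(b.ymax), int(b.xmin):int(b.xmax)].min() == 1.0
        assert img.sum() == image.sum()

    def test_empty_ops_returns_singleton(self, sample):
        image, boxes = sample
        out = augment(image, boxes, [])
        assert len(out) == 1 and out[0][0] is image

    def test_unknown_op_rejected(self, sample):
        image, boxes = sample
        with pytest.raises(ConfigurationError):
            apply_augmentation(image, boxes, "shear")


class TestTestSet:
    def test_counts_for_two_per_stage(self, wli_cam):
        scenes = make_test_set(2, seed=1, camera=wli_cam, size=48)
        assert len(scenes) == 8
        n_boxes = sum(len(ts.rendered.boxes) for ts in scenes)
        assert n_boxes == 6  # normals carry no boxes
        normals = [ts for ts in scenes if ts.true_stage is StageLabel.NORMAL]
        assert all(not ts.rendered.boxes for ts in normals)

    def test_balanced_across_stages(self, wli_cam):
        scenes = make_test_set(2, seed=1, camera=wli_cam, size=48)
        for stage in STAGE_ORDER:
            assert sum(ts.true_stage is stage for ts in scenes) == 2

    def test_lesion_stage_matches_scene_stage(self, wli_cam):
        scenes = make_test_set(1, seed=9, camera=wli_cam, size=48)
        for ts in scenes:
            if ts.true_stage in LESION_STAGES:
                assert ts.rendered.boxes[0][1] is ts.true_stage
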