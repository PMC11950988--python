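"""Atlas registration and region-mask transfer."""

import numpy as np
import pytest
import SimpleITK as sitk

from aspectscore.exceptions import (
    RegistrationError,
    SegmentationError,
    ValidationError,
)
from aspectscore.phantom import PhantomConfig, atlas_reference_images, build_atlas
from aspectscore.preprocess import HUImage
from aspectscore.segment import (
    RegionMaskSet,
    SimilarityTransform2D,
    dilate_internal,
    refine_nonrigid,
    register_rigid,
    transfer_masks,
)


def _warp(img: HUImage, angle, scale, translation, fill=-1000.0) -> HUImage:
    s = img.shape[0]
    t = sitk.Similarity2DTransform()
    t.SetCenter(((s - 1) / 2.0, (s - 1) / 2.0))
    t.SetAngle(angle)
    t.SetScale(scale)
    t.SetTranslation(translation)
    f = sitk.GetImageFromArray(img.pixels.astype(np.float32))
    out = sitk.Resample(f, f, t, sitk.sitkLinear, fill)
    return HUImage(sitk.GetArrayFromImage(out).astype(float), level=img.level), t


class TestRegisterRigid:
    def test_self_registration_recovers_identity(self, ref_images):
        img = ref_images["basal_ganglia"]
        t = register_rigid(img, img)
        assert abs(t.rotation) < 0.01
        assert abs(t.scale - 1.0) < 0.01
        assert np.hypot(*t.translation) < 0.5

    @pytest.mark.parametrize("size", [128, 256])
    def test_identity_recovery_across_sizes(self, size):
        cfg = PhantomConfig(image_size=size, noise_sd=0.0)
        atlas = build_atlas(cfg)
        img = atlas_reference_images(atlas, cfg)["cortical"]
        t = register_rigid(img, img)
        assert abs(t.rotation) < 0.01
        assert abs(t.scale - 1.0) < 0.01
        assert np.hypot(*t.translation) < 0.5

    def test_known_similarity_transform_recovered(self, ref_images):
        img = ref_images["basal_ganglia"]
        patient, _ = _warp(img, 0.1, 1.05, (3.0, -2.0))
        t = register_rigid(img, patient)
        assert abs(t.rotation - 0.1) < 0.02
        assert abs(t.scale - 1.05) < 0.02
        assert np.hypot(t.translation[0] - 3.0, t.translation[1] + 2.0) < 1.0

    def test_structureless_input_raises_with_metric(self, ref_images, rng):
        img = ref_images["basal_ganglia"]
        noise = HUImage(rng.normal(30.0, 10.0, img.shape))
        with pytest.raises(RegistrationError) as err:
            register_rigid(img, noise)
        assert err.value.metric is not None

    def test_deterministic(self, ref_images):
        img = ref_images["cortical"]
        patient, _ = _warp(img, 0.05, 1.02, (1.0, 2.0))
        t1 = register_rigid(img, patient)
        t2 = register_rigid(img, patient)
        assert t1.rotation == t2.rotation
        assert t1.scale == t2.scale
        assert t1.translation == t2.translation


class TestRefineNonrigid:
    def test_identical_images_give_zero_field(self, ref_images):
        img = ref_images["basal_ganglia"]
        ident = SimilarityTransform2D.identity(img.shape)
        field = refine_nonrigid(img, img, ident)
        assert np.abs(field).max() < 0.5

    def test_small_deformation_not_worse_than_rigid(self):
        cfg = PhantomConfig(image_size=128, noise_sd=0.0)
        atlas = build_atlas(cfg)
        img = atlas_reference_images(atlas, cfg)["basal_ganglia"]
        # smooth sinusoidal bulge of ~2 px
        s = cfg.image_size
        rr, cc = np.mgrid[0:s, 0:s].astype(float)
        dx = 2.0 * np.sin(rr / s * np.pi)
        dy = 2.0 * np.cos(cc / s * np.pi)
        from scipy.ndimage import map_coordinates

        warped = map_coordinates(
            img.pixels, [rr + dy, cc + dx], order=1, cval=-1000.0
        )
        patient = HUImage(warped, level="basal_ganglia")
        rigid = register_rigid(img, patient)
        field = refine_nonrigid(img, patient, rigid)
        assert field.shape == (s, s, 2)

        # ground truth: the atlas mask deformed by the same displacement
        gt = (
            map_coordinates(
                atlas.mask("M2", "left").astype(float),
                [rr + dy, cc + dx], order=0, cval=0.0,
            )
            > 0.5
        )
        for f in (None, field):
            ms = transfer_masks(atlas, rigid, f, level="basal_ganglia")
            m = ms.mask("M2", "left")
            dice = 2 * np.sum(m & gt) / (m.sum() + gt.sum())
            if f is None:
                dice_rigid = dice
            else:
                dice_refined = dice
        assert dice_refined >= dice_rigid - 0.02


class TestTransferMasks:
    def test_identity_transfer_equals_atlas(self, atlas):
        ident = SimilarityTransform2D.identity(atlas.labels["basal_ganglia"].shape)
        ms = transfer_masks(atlas, ident, level="basal_ganglia")
        for (region, side), m in ms.masks.items():
            assert np.array_equal(m, atlas.mask(region, side))

    def test_pure_translation_shifts_masks_exactly(self, atlas):
        shape = atlas.labels["basal_ganglia"].shape
        t = SimilarityTransform2D(
            0.0, 1.0, (5.0, 0.0), center=((shape[1] - 1) / 2, (shape[0] - 1) / 2)
        )
        ms = transfer_masks(atlas, t, level="basal_ganglia")
        # transform maps patient (x) to atlas (x + 5): mask shifts left by 5 cols
        src = atlas.mask("L", "left")
        expect = np.zeros_like(src)
        expect[:, :-5] = src[:, 5:]
        assert np.array_equal(ms.mask("L", "left"), expect)

    def test_region_lost_off_image_raises_named_error(self, atlas):
        shape = atlas.labels["basal_ganglia"].shape
        t = SimilarityTransform2D(0.0, 1.0, (10000.0, 10000.0))
        with pytest.raises(SegmentationError) as err:
            transfer_masks(atlas, t, level="basal_ganglia")
        assert err.value.region in {"C", "I", "IC", "L", "M1", "M2", "M3"}


class TestDilateInternal:
    def _square_maskset(self):
        m = np.zeros((64, 64), dtype=bool)
        m[20:30, 20:30] = True
        other = np.zeros((64, 64), dtype=bool)
        other[50:60, 50:60] = True
        return RegionMaskSet(
            level="basal_ganglia",
            masks={("C", "left"): m, ("M1", "left"): other},
        )

    def test_radius_zero_is_identity(self):
        ms = self._square_maskset()
        out = dilate_internal(ms, 0)
        assert out is ms

    def test_square_grows_to_diamond_footprint(self):
        # 10x10 square dilated by a radius-1 diamond: + 4 edges of 10, no corners
        ms = self._square_maskset()
        out = dilate_internal(ms, 1)
        assert out.mask("C", "left").sum() == 140

    def test_cortical_masks_untouched(self):
        ms = self._square_maskset()
        out = dilate_internal(ms, 2)
        assert np.array_equal(out.mask("M1", "left"), ms.mask("M1", "left"))

    def test_dilated_internal_regions_stay_disjoint(self, atlas):
        ident = SimilarityTransform2D.identity(atlas.labels["basal_ganglia"].shape)
        ms = transfer_masks(atlas, ident, level="basal_ganglia")
        out = dilate_internal(ms, 2, brain_mask=atlas.brain["basal_ganglia"])
        stack = np.sum([out.masks[k].astype(int) for k in out.masks], axis=0)
        assert stack.max() <= 1
        assert not (out.mask("L", "left") & out.mask("IC", "left")).any()

    def test_negative_radius_rejected(self):
        with pytest.raises(ValidationError):
            dilate_internal(self._square_maskset(), -1)


class TestMaskTransferDice:
    def test_known_warp_dice_above_095(self, atlas, ref_images):
        img = ref_images["basal_ganglia"]
        patient, known = _warp(img, 0.08, 1.04, (2.0, -3.0))
        lab = sitk.GetImageFromArray(atlas.labels["basal_ganglia"].astype(np.int16))
        gt = sitk.GetArrayFromImage(
            sitk.Resample(lab, lab, known, sitk.sitkNearestNeighbor, 0)
        )
        t = register_rigid(img, patient)
        ms = transfer_masks(atlas, t, level="basal_ganglia")
        for (region, side), m in ms.masks.items():
            g = gt == atlas.label_of(region, side)
            dice = 2 * np.sum(m & g) / (m.sum() + g.sum())
            assert dice >= 0.95, (region, side, dice)
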