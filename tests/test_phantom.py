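"""Phantom generator: geometry, lesions, noise, cohorts, exclusions."""

import numpy as np
import pytest

from aspectscore.exceptions import SizingError, ValidationError
from aspectscore.phantom import (
    LEVEL_OF_REGION,
    REGIONS,
    CohortRecord,
    LesionSpec,
    PhantomConfig,
    apply_exclusions,
    build_atlas,
    synth_cohort,
    synth_patient,
)


class TestAtlasGeometry:
    def test_all_ten_regions_present_on_both_sides(self, atlas):
        assert len(atlas.region_ids) == 10
        for region in REGIONS:
            for side in ("left", "right"):
                assert atlas.mask(region, side).any(), (region, side)

    def test_left_masks_are_exact_mirrors_of_right(self, atlas):
        for region in REGIONS:
            left = atlas.mask(region, "left")
            right = atlas.mask(region, "right")
            assert np.array_equal(np.fliplr(left), right)
            assert left.sum() == right.sum()

    def test_left_right_masks_disjoint_and_levels_partition(self, atlas):
        for level, lab in atlas.labels.items():
            # disjointness is inherent in a single label map; check sides
            for region in REGIONS:
                if LEVEL_OF_REGION[region] != level:
                    continue
                both = atlas.mask(region, "left") & atlas.mask(region, "right")
                assert not both.any()
        basal = set(np.unique(atlas.labels["basal_ganglia"])) - {0}
        cortical = set(np.unique(atlas.labels["cortical"])) - {0}
        assert not basal & cortical

    def test_masks_inside_brain(self, atlas):
        for region in REGIONS:
            level = LEVEL_OF_REGION[region]
            m = atlas.mask(region, "left") | atlas.mask(region, "right")
            assert not (m & ~atlas.brain[level]).any()

    def test_minimum_size_enforced(self):
        with pytest.raises(SizingError):
            PhantomConfig(image_size=32)

    def test_smallest_supported_size_places_all_regions(self):
        atlas = build_atlas(PhantomConfig(image_size=64, noise_sd=0.0))
        for region in REGIONS:
            assert atlas.mask(region, "left").any()

    def test_deterministic_for_fixed_size(self, config):
        a1 = build_atlas(config)
        a2 = build_atlas(config)
        for level in a1.labels:
            assert np.array_equal(a1.labels[level], a2.labels[level])


class TestSynthPatient:
    def test_noiseless_lesionless_phantom_is_left_right_symmetric(
        self, atlas, config
    ):
        rec = synth_patient(atlas, config, [], seed=3)
        for level, img in rec.slices.items():
            assert np.array_equal(img.pixels, np.fliplr(img.pixels))
        for region in REGIONS:
            img = rec.slices[LEVEL_OF_REGION[region]]
            lm = img.pixels[atlas.mask(region, "left")]
            rm = img.pixels[atlas.mask(region, "right")]
            assert lm.mean() == rm.mean()
            assert lm.std() == rm.std()

    def test_lesion_decrement_is_exact_contralateral_difference(
        self, atlas, config
    ):
        rec = synth_patient(
            atlas, config, [LesionSpec("L", "left", 5.0)], seed=0
        )
        img = rec.slices["basal_ganglia"]
        diff = (
            img.pixels[atlas.mask("L", "left")].mean()
            - img.pixels[atlas.mask("L", "right")].mean()
        )
        assert diff == pytest.approx(-5.0, abs=1e-12)
        assert rec.truth["L"] and not any(
            rec.truth[r] for r in REGIONS if r != "L"
        )

    def test_seed_determinism(self):
        les = [LesionSpec("M2", "right", 4.0)]
        cfg = PhantomConfig(image_size=128, noise_sd=2.0)
        r1 = synth_patient(build_atlas(cfg), cfg, les, seed=11)
        r2 = synth_patient(build_atlas(cfg), cfg, les, seed=11)
        for level in r1.slices:
            assert np.array_equal(r1.slices[level].pixels, r2.slices[level].pixels)

    def test_unknown_region_rejected(self, atlas, config):
        with pytest.raises(ValidationError):
            synth_patient(atlas, config, [LesionSpec("M7", "left", 5.0)], seed=0)

    def test_noisy_region_mean_concentrates_at_nominal(self):
        """Monte Carlo: the sample mean of a region under noise SD 2 stays
        within 4 * 2/sqrt(n) of the nominal HU in at least 99% of seeds."""
        cfg = PhantomConfig(image_size=128, noise_sd=2.0)
        atlas = build_atlas(cfg)
        mask = atlas.mask("L", "left")
        n = int(mask.sum())
        nominal = cfg.region_baseline("L")
        bound = 4.0 * 2.0 / np.sqrt(n)
        hits = 0
        for seed in range(1000):
            rec = synth_patient(atlas, cfg, [], seed=seed)
            m = rec.slices["basal_ganglia"].pixels[mask].mean()
            hits += abs(m - nominal) <= bound
        assert hits >= 990


class TestSynthCohort:
    def test_zero_prevalence_gives_no_positives(self, atlas128, config128):
        cohort = synth_cohort(
            5, 0.0, (3.0, 5.0), config128, seed=1, atlas=atlas128
        )
        assert all(not any(rec.truth.values()) for rec in cohort)

    def test_same_seed_reproduces_cohort(self, atlas128, config128):
        a = synth_cohort(6, 0.4, (3.0, 5.0), config128, seed=9, atlas=atlas128)
        b = synth_cohort(6, 0.4, (3.0, 5.0), config128, seed=9, atlas=atlas128)
        for ra, rb in zip(a, b):
            assert ra.truth == rb.truth and ra.laterality == rb.laterality
            for level in ra.slices:
                assert np.array_equal(
                    ra.slices[level].pixels, rb.slices[level].pixels
                )

    def test_prevalence_matches_binomial_expectation(self, atlas128):
        cfg = PhantomConfig(image_size=128, noise_sd=0.0)
        cohort = synth_cohort(
            1000, {"I": 0.3}, (3.0, 5.0), cfg, seed=2, atlas=atlas128
        )
        frac = np.mean([rec.truth["I"] for rec in cohort])
        half_width = 2.576 * np.sqrt(0.3 * 0.7 / 1000)  # binomial 99% CI
        assert abs(frac - 0.3) < half_width

    def test_truth_only_on_laterality_side(self, atlas128, config128):
        cohort = synth_cohort(
            20, 0.5, (3.0, 5.0), config128, seed=5, atlas=atlas128
        )
        for rec in cohort:
            for lesion in rec.lesions:
                assert lesion.side == rec.laterality

    def test_empty_decrement_range_rejected(self, atlas128, config128):
        with pytest.raises(ValidationError):
            synth_cohort(3, 0.3, (5.0, 4.0), config128, seed=0, atlas=atlas128)


def _record(pid, category):
    return CohortRecord(
        patient_id=pid, category=category, laterality="left",
        slices={}, truth={r: False for r in REGIONS},
    )


class TestExclusions:
    def test_category_filter_preserves_order(self):
        manifest = [
            _record("a", "acute"),
            _record("b", "hemorrhagic"),
            _record("c", "acute"),
            _record("d", "chronic"),
        ]
        kept = apply_exclusions(manifest)
        assert [r.patient_id for r in kept] == ["a", "c"]

    def test_all_acute_unchanged(self):
        manifest = [_record(f"p{i}", "acute") for i in range(5)]
        assert apply_exclusions(manifest) == manifest

    def test_empty_manifest(self):
        assert apply_exclusions([]) == []

    def test_missing_category_rejected(self):
        bad = _record("x", "acute")
        bad.category = ""
        with pytest.raises(ValidationError):
            apply_exclusions([bad])
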