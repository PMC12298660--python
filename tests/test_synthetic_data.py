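import numpy as np
import pytest
from scipy import ndimage

from marblesense.color_features import color_stats
from marblesense.geometry import enumerate_valid_blocks
from marblesense.svm_classifier import BeefClass
from marblesense.synthetic_data import (
    BRIGHTNESS_MU_DEFAULT,
    DEFAULT_SPECS,
    GenerationError,
    PerturbationKind,
    PerturbationSpec,
    TiltDirection,
    brightness_level_value,
    default_spec,
    generate_dataset,
    generate_image,
    perturb,
)

LUMA = np.array([0.299, 0.587, 0.114])


@pytest.fixture(scope="module")
def roi(medium_mask):
    return medium_mask.boolean_mask()


class TestGenerateImage:
    def test_seeded_determinism(self):
        spec = DEFAULT_SPECS[BeefClass.REGULAR]
        a, ma = generate_image(spec, seed=5)
        b, mb = generate_image(spec, seed=5)
        assert np.array_equal(a, b) and np.array_equal(ma, mb)

    @pytest.mark.parametrize("cls", list(BeefClass))
    def test_fat_fraction_within_spec_range(self, cls, roi):
        spec = DEFAULT_SPECS[cls]
        lo, hi = spec.fat_fraction_range
        for seed in range(4):
            _, fat = generate_image(spec, seed=seed)
            frac = (fat & roi).sum() / roi.sum()
            assert lo - 0.02 <= frac <= hi + 0.02

    def test_wagyu_more_fat_components_than_injected(self):
        medians = {}
        for cls in (BeefClass.WAGYU, BeefClass.FAT_INJECTED):
            counts = []
            for seed in range(10):
                _, fat = generate_image(DEFAULT_SPECS[cls], seed=seed)
                counts.append(ndimage.label(fat)[1])
            medians[cls] = np.median(counts)
        assert medians[BeefClass.WAGYU] > medians[BeefClass.FAT_INJECTED]

    def test_fat_pixels_brighter_than_lean(self, class_images, roi):
        for cls, (image, fat) in class_images.items():
            luma = image @ LUMA
            lean = roi & ~fat
            assert np.median(luma[fat]) > np.percentile(luma[lean], 90)

    def test_image_black_outside_roi(self, class_images, roi):
        for image, _ in class_images.values():
            assert not image[~roi].any()

    def test_infeasible_spec_raises(self):
        bad = default_spec(BeefClass.REGULAR,
                           fat_fraction_range=(0.5, 0.6),
                           fleck_count_range=(1, 1),
                           elongation_range=(400.0, 400.0))
        with pytest.raises(GenerationError):
            generate_image(bad, seed=0)

    def test_color_contrasts_drive_the_documented_orderings(self, class_images):
        """Red dominates in every class; regular lean is the least variable."""
        grid_stats = {}
        for cls, (image, _) in class_images.items():
            from marblesense.geometry import make_ellipse_mask

            grid = enumerate_valid_blocks(make_ellipse_mask(960, 720, 0.75), 80)
            stats = [color_stats(grid.extract(image, i), "RGB") for i in range(len(grid))]
            grid_stats[cls] = stats
        for cls, stats in grid_stats.items():
            mu = np.mean([s.means for s in stats], axis=0)
            assert mu[0] > mu[1] and mu[0] > mu[2]
        mean_sigma = {
            cls: np.mean([s.stds for s in stats]) for cls, stats in grid_stats.items()
        }
        assert mean_sigma[BeefClass.REGULAR] < mean_sigma[BeefClass.WAGYU]
        assert mean_sigma[BeefClass.REGULAR] < mean_sigma[BeefClass.FAT_INJECTED]


class TestBrightnessLadder:
    def test_ladder_arithmetic(self):
        # level values mu + 1.5 k sigma reproduce the printed ladder
        assert brightness_level_value(0) == pytest.approx(98.91)
        assert brightness_level_value(-1) == pytest.approx(72.94)
        assert brightness_level_value(3) == pytest.approx(176.82)
        assert brightness_level_value(-3) == pytest.approx(2 * 98.91 - 176.82)

    @pytest.mark.parametrize("level", [-1, 0, 1])
    def test_adjusted_mean_hits_target(self, class_images, roi, level):
        image, _ = class_images[BeefClass.REGULAR]
        spec = PerturbationSpec(kind=PerturbationKind.BRIGHTNESS, brightness_level=level)
        out = perturb(image, spec, seed=3)
        mean = (out @ LUMA)[roi].mean()
        assert mean == pytest.approx(brightness_level_value(level), abs=1.0)

    def test_extreme_levels_move_monotonically(self, class_images, roi):
        image, _ = class_images[BeefClass.WAGYU]
        means = []
        for k in (-3, 0, 3):
            out = perturb(
                image,
                PerturbationSpec(kind=PerturbationKind.BRIGHTNESS, brightness_level=k),
                seed=1,
            )
            means.append((out @ LUMA)[roi].mean())
        assert means[0] < means[1] < means[2]


class TestOtherPerturbations:
    def test_none_and_zero_tilt_are_identity(self, class_images):
        image, _ = class_images[BeefClass.WAGYU]
        assert np.array_equal(perturb(image, PerturbationSpec(), seed=0), image)
        tilt0 = PerturbationSpec(kind=PerturbationKind.TILT, tilt_angle=0.0)
        assert np.array_equal(perturb(image, tilt0, seed=0), image)

    def test_label_occlusion_fraction(self, class_images, roi):
        image, _ = class_images[BeefClass.REGULAR]
        spec = PerturbationSpec(kind=PerturbationKind.LABEL, occlusion_area_fraction=0.05)
        out = perturb(image, spec, seed=9)
        occluded = ((out != image).any(axis=2) & roi).sum() / roi.sum()
        assert occluded == pytest.approx(0.05, abs=0.005)

    def test_reflection_raises_brightness(self, class_images, roi):
        image, _ = class_images[BeefClass.REGULAR]
        out = perturb(image, PerturbationSpec(kind=PerturbationKind.REFLECTION), seed=2)
        assert (out @ LUMA)[roi].mean() > (image @ LUMA)[roi].mean()

    @pytest.mark.parametrize("direction", list(TiltDirection))
    def test_tilt_changes_image_but_keeps_frame(self, class_images, direction):
        image, _ = class_images[BeefClass.WAGYU]
        spec = PerturbationSpec(kind=PerturbationKind.TILT, tilt_angle=8.0,
                                tilt_direction=direction)
        out = perturb(image, spec, seed=0)
        assert out.shape == image.shape
        assert not np.array_equal(out, image)

    def test_invalid_spec_fields_rejected(self):
        with pytest.raises(ValueError):
            PerturbationSpec(brightness_level=4)
        with pytest.raises(ValueError):
            PerturbationSpec(occlusion_area_fraction=0.5)
        with pytest.raises(ValueError):
            PerturbationSpec(kind=PerturbationKind.TILT, tilt_angle=-1)


class TestGenerateDataset:
    def test_large_sample_split_counts(self):
        ds = generate_dataset(200, split=(0.6, 0.2, 0.2), seed=1)
        for cls in BeefClass:
            rows = ds.manifest[ds.manifest["label"] == int(cls)]
            assert (rows["split"] == "train").sum() == 120
            assert (rows["split"] == "validation").sum() == 40
            assert (rows["split"] == "test").sum() == 40

    def test_small_sample_split_counts(self):
        ds = generate_dataset(80, split=(0.5, 0.25, 0.25), seed=1)
        for cls in BeefClass:
            rows = ds.manifest[ds.manifest["label"] == int(cls)]
            assert tuple(rows["split"].value_counts()[["train", "validation", "test"]]) == (40, 20, 20)

    def test_seed_changes_images_not_sizes(self):
        a = generate_dataset(6, split=(0.5, 0.25, 0.25), seed=1)
        b = generate_dataset(6, split=(0.5, 0.25, 0.25), seed=2)
        assert len(a) == len(b)
        assert (a.manifest["split"] == b.manifest["split"]).all()
        img_a, _ = a.render(0)
        img_b, _ = b.render(0)
        assert not np.array_equal(img_a, img_b)

    def test_identical_seed_identical_dataset(self):
        a = generate_dataset(4, split=(0.5, 0.25, 0.25), seed=3)
        b = generate_dataset(4, split=(0.5, 0.25, 0.25), seed=3)
        assert a.manifest.equals(b.manifest)
        assert np.array_equal(a.render(2)[0], b.render(2)[0])

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError):
            generate_dataset(10, split=(0.5, 0.2, 0.2), seed=0)

    def test_save_layout(self, tmp_path):
        ds = generate_dataset(4, split=(0.5, 0.25, 0.25), seed=4)
        ds.save(tmp_path)
        assert (tmp_path / "manifest.csv").exists()
        assert len(list((tmp_path / "masks").glob("*.png"))) == 12
        assert len(list((tmp_path / "images").rglob("*.png"))) == 12
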