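"""Tests for the seeded phantom generator, degradation and apportionment."""

import numpy as np
import pytest

from acam.contrast import apply_contrast
from acam.phantoms import (
    CLASS_NAMES,
    DEFAULT_CLASS_WEIGHTS,
    PhantomSpec,
    apply_speckle,
    degrade_contrast,
    generate_arrays,
    generate_dataset,
    largest_remainder,
    render_phantom,
)


def enumeration_apportion(total, proportions):
    """Oracle: floor quotas, then assign leftovers by sorting remainders."""
    props = np.asarray(proportions, float) / np.sum(proportions)
    quotas = total * props
    counts = np.floor(quotas).astype(int)
    remainders = quotas - counts
    for i in sorted(range(len(props)), key=lambda i: (-remainders[i], i))[: total - counts.sum()]:
        counts[i] += 1
    return counts


class TestLargestRemainder:
    def test_reference_roster_600(self):
        np.testing.assert_array_equal(
            largest_remainder(600, DEFAULT_CLASS_WEIGHTS), [34, 50, 79, 83, 150, 204]
        )

    @pytest.mark.parametrize("total", [1, 6, 37, 100, 600, 997])
    def test_matches_enumeration_oracle(self, total):
        got = largest_remainder(total, DEFAULT_CLASS_WEIGHTS)
        np.testing.assert_array_equal(got, enumeration_apportion(total, DEFAULT_CLASS_WEIGHTS))
        assert got.sum() == total

    def test_random_proportions_sum_exactly(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            props = rng.random(rng.integers(2, 8))
            total = int(rng.integers(0, 300))
            got = largest_remainder(total, props)
            np.testing.assert_array_equal(got, enumeration_apportion(total, props))


class TestRenderPhantom:
    def test_deterministic_under_seed(self):
        spec = PhantomSpec(seed=0)
        a = render_phantom(2, np.random.default_rng(5), spec)
        b = render_phantom(2, np.random.default_rng(5), spec)
        np.testing.assert_array_equal(a, b)

    def test_out_of_range_class_rejected(self):
        with pytest.raises(ValueError):
            render_phantom(6, np.random.default_rng(0), PhantomSpec())

    def test_femur_is_elongated(self):
        """The femur scene's bright component has aspect ratio > 3."""
        from scipy import ndimage

        img = render_phantom(1, np.random.default_rng(1), PhantomSpec())
        labeled, n = ndimage.label(img > 0.5)
        assert n >= 1
        sizes = ndimage.sum(img > 0.5, labeled, range(1, n + 1))
        ys, xs = np.nonzero(labeled == 1 + int(np.argmax(sizes)))
        # principal-axis lengths are rotation-invariant, unlike the bbox
        cov = np.cov(np.stack([ys, xs]))
        evals = np.sort(np.linalg.eigvalsh(cov))
        aspect = np.sqrt(evals[1] / evals[0])
        assert aspect > 3

    def test_all_classes_pairwise_distinct(self):
        spec = PhantomSpec(seed=0)
        scenes = [render_phantom(c, np.random.default_rng(3), spec) for c in range(len(CLASS_NAMES))]
        for i in range(len(scenes)):
            for j in range(i + 1, len(scenes)):
                assert np.abs(scenes[i] - scenes[j]).max() > 0.05

    def test_values_in_unit_interval(self):
        for c in range(6):
            img = render_phantom(c, np.random.default_rng(c), PhantomSpec())
            assert img.min() >= 0.0 and img.max() <= 1.0


class TestApplySpeckle:
    def test_zero_strength_is_identity(self, random_image):
        out = apply_speckle(random_image, np.random.default_rng(0), 0.0)
        np.testing.assert_array_equal(out, random_image)

    def test_unit_mean_on_flat_region(self):
        """Fully developed speckle keeps the mean of a large flat region."""
        img = np.full((64, 64), 0.6)
        out = apply_speckle(img, np.random.default_rng(1), 1.0)
        assert out.mean() == pytest.approx(0.6, rel=0.05)

    def test_deterministic_under_seed(self, random_image):
        a = apply_speckle(random_image, np.random.default_rng(9), 0.7)
        b = apply_speckle(random_image, np.random.default_rng(9), 0.7)
        np.testing.assert_array_equal(a, b)

    def test_invalid_strength_rejected(self, random_image):
        with pytest.raises(ValueError):
            apply_speckle(random_image, np.random.default_rng(0), 1.5)


class TestDegradeContrast:
    def test_unit_gain_no_jitter_is_identity(self, random_image):
        out, alpha = degrade_contrast(random_image, 1.0, 0.0, np.random.default_rng(0))
        np.testing.assert_allclose(out, random_image, rtol=1e-12)
        assert alpha == 1.0

    def test_half_gain_records_double_restore(self, random_image):
        _, alpha = degrade_contrast(random_image, 0.5, 0.0, np.random.default_rng(0))
        assert alpha == 2.0

    def test_restoring_with_alpha_star_inverts(self, random_image):
        for g in [1 / 3, 0.5, 0.9]:
            degraded, alpha = degrade_contrast(random_image, g, 0.0, np.random.default_rng(0))
            np.testing.assert_allclose(
                apply_contrast(degraded, alpha), random_image, atol=1e-6
            )

    def test_invalid_gain_rejected(self, random_image):
        with pytest.raises(ValueError):
            degrade_contrast(random_image, 0.0, 0.0, np.random.default_rng(0))

    def test_alpha_star_clamped_to_clinical_range(self, random_image):
        _, alpha = degrade_contrast(random_image, 0.2, 0.0, np.random.default_rng(0))
        assert alpha == 3.0


class TestGenerateDataset:
    def test_all_six_classes_present(self, tiny_dataset):
        _, _, _, manifest = tiny_dataset
        assert set(manifest.records["class"]) == set(range(6))

    def test_split_integrity(self, tiny_dataset):
        _, _, _, manifest = tiny_dataset
        df = manifest.records
        assert set(df["split"]) == {"train", "test"}
        for cls, group in df.groupby("class"):
            frac = (group["split"] == "train").mean()
            assert abs(frac - 0.70) <= 1.0 / len(group)

    def test_round_trip_restoration_without_jitter(self):
        spec = PhantomSpec(n_samples=24, seed=5, brightness_jitter=0.0)
        clean, degraded, manifest = generate_arrays(spec)
        alphas = manifest.records["alpha_star"].to_numpy()
        for i in range(len(alphas)):
            np.testing.assert_allclose(apply_contrast(degraded[i], alphas[i]), clean[i], atol=1e-6)

    def test_seed_reproducibility(self):
        spec = PhantomSpec(n_samples=36, seed=11)
        c1, d1, m1 = generate_arrays(spec)
        c2, d2, m2 = generate_arrays(spec)
        np.testing.assert_array_equal(d1, d2)
        assert m1.records.equals(m2.records)

    def test_alpha_star_consistent_with_gain(self, tiny_dataset):
        _, _, _, manifest = tiny_dataset
        df = manifest.records
        np.testing.assert_allclose(
            df["alpha_star"], np.clip(1.0 / df["g"], 1.0, 3.0), rtol=1e-12
        )

    def test_disk_round_trip(self, tmp_path):
        from acam.phantoms import DatasetManifest, load_images

        spec = PhantomSpec(n_samples=12, image_size=32, seed=2)
        manifest = generate_dataset(spec, tmp_path)
        assert (tmp_path / "manifest.csv").exists()
        reloaded = DatasetManifest.from_csv(tmp_path / "manifest.csv")
        assert reloaded.records["path"].tolist() == manifest.records["path"].tolist()
        images = load_images(tmp_path, reloaded)
        assert images.shape == (12, 32, 32)
        assert images.min() >= 0.0 and images.max() <= 1.0

    def test_bad_spec_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(class_proportions=(0.5, 0.5, 0.5, 0, 0, 0))
        with pytest.raises(ValueError):
            PhantomSpec(gain_range=(0.0, 1.0))
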