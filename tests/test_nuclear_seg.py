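import math

import numpy as np
import pytest
from skimage import filters

from conftest import disk_mask
from ifishquant import nuclear_seg as ns
from ifishquant import synth


def gaussian_blob(shape, center, sigma, amplitude=1.0):
    rows, cols = np.mgrid[: shape[0], : shape[1]]
    return amplitude * np.exp(
        -((rows - center[0]) ** 2 + (cols - center[1]) ** 2) / (2 * sigma**2)
    )


class TestForegroundMask:
    def test_bright_disks_on_noise_free_background(self):
        img = np.zeros((120, 120))
        disks = disk_mask((120, 120), (40, 40), 15) | disk_mask(
            (120, 120), (80, 80), 18
        )
        img[disks] = 0.8
        mask = ns.foreground_mask(img)
        assert (mask & disks).sum() / disks.sum() > 0.99
        from skimage import morphology

        far = ~morphology.dilation(disks, morphology.disk(8))
        # background away from the disk edges stays out of the mask
        assert mask[far].mean() < 0.05

    def test_otsu_equals_brute_force_on_bimodal(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate(
            [rng.normal(0.2, 0.03, 600), rng.normal(0.8, 0.03, 424)]
        )
        img = vals.reshape(32, 32)
        # brute force: maximise between-class variance over candidate cuts
        hist, edges = np.histogram(img, bins=256)
        centers = (edges[:-1] + edges[1:]) / 2
        best, best_t = -1.0, None
        for i in range(1, 256):
            w0, w1 = hist[:i].sum(), hist[i:].sum()
            if w0 == 0 or w1 == 0:
                continue
            m0 = (hist[:i] * centers[:i]).sum() / w0
            m1 = (hist[i:] * centers[i:]).sum() / w1
            v = w0 * w1 * (m0 - m1) ** 2
            if v > best:
                best, best_t = v, centers[i - 1 : i + 1].mean()
        assert filters.threshold_otsu(img) == pytest.approx(best_t, abs=0.02)

    def test_all_zero_image_empty_mask(self):
        with pytest.warns(UserWarning):
            mask = ns.foreground_mask(np.zeros((30, 30)))
        assert not mask.any()


class TestHminimaWatershed:
    def test_two_blobs_small_depth_two_labels(self):
        img = gaussian_blob((80, 80), (25, 40), 8) + gaussian_blob(
            (80, 80), (55, 40), 8
        )
        mask = img > 0.1
        labels = ns.hminima_watershed(img, mask, depth=0.05)
        assert labels.max() == 2

    def test_depth_above_saddle_merges(self):
        # saddle height between the two blobs is computable on the midline
        img = gaussian_blob((80, 80), (25, 40), 8) + gaussian_blob(
            (80, 80), (55, 40), 8
        )
        mask = img > 0.1
        peak = img.max()
        saddle = img[40, :][mask[40, :]].max()
        labels = ns.hminima_watershed(img, mask, depth=(peak - saddle) * 1.5)
        assert labels.max() == 1

    def test_empty_mask(self):
        labels = ns.hminima_watershed(
            np.ones((20, 20)), np.zeros((20, 20), bool), depth=0.1
        )
        assert labels.max() == 0


@pytest.fixture(scope="module")
def model():
    return ns.default_fragment_model(2000.0)


@pytest.fixture(scope="module")
def params():
    return ns.SegParams.for_magnification(40)


class TestClassifyFragment:
    def make_features(self, mask, area=2000.0):
        from skimage.measure import regionprops

        region = regionprops(mask.astype(np.uint8))[0]
        return ns.fragment_features(region, area, 2 * math.sqrt(math.pi * area))

    def test_theoretical_sized_disk_is_optimal(self, model):
        r = math.sqrt(2000 / math.pi)
        mask = disk_mask((80, 80), (40, 40), r)
        assert ns.classify_fragment(self.make_features(mask), model) == "optimal"

    def test_double_area_clump_is_undersegmented(self, model):
        r = math.sqrt(2000 / math.pi)
        mask = disk_mask((120, 120), (60, 45), r) | disk_mask(
            (120, 120), (60, 45 + int(1.7 * r)), r
        )
        assert (
            ns.classify_fragment(self.make_features(mask), model)
            == "undersegmented"
        )

    def test_small_sliver_is_oversegmented(self, model):
        r = math.sqrt(2000 / math.pi)
        half = disk_mask((80, 80), (40, 40), r)
        half[:, 40:] = False
        half[:, : 40 - int(0.6 * r)] = False  # thin crescent slice
        assert (
            ns.classify_fragment(self.make_features(half), model)
            == "oversegmented"
        )

    def test_non_finite_features_rejected(self, model):
        feats = np.ones(10)
        feats[3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            ns.classify_fragment(feats, model)


class TestIterativeSegment:
    def test_isolated_nuclei_recovered(self, params):
        from ifishquant import evaluation

        spec = synth.SceneSpec(n_cells=20, height=450, width=450, seed=21)
        stack, nuclei, *_ = synth.generate_scene(spec)
        labels = ns.iterative_segment(stack.dapi, params)
        _, _, f = evaluation.precision_recall_f(
            evaluation.match_segments(labels, nuclei)
        )
        assert f >= 0.95

    def test_touching_pairs_split(self, params):
        spec = synth.SceneSpec(
            n_cells=20, height=450, width=450, seed=22, touching_fraction=0.4
        )
        stack, nuclei, *_ = synth.generate_scene(spec)
        labels = ns.iterative_segment(stack.dapi, params)
        # at least as many objects as planted: pairs must not fuse
        assert labels.max() >= nuclei.max() - 1

    def test_blank_image_no_labels(self, params):
        with pytest.warns(UserWarning):
            labels = ns.iterative_segment(np.zeros((100, 100)), params)
        assert labels.max() == 0

    def test_invariant_to_affine_rescaling(self, params):
        spec = synth.SceneSpec(n_cells=10, height=300, width=300, seed=23)
        stack, *_ = synth.generate_scene(spec)
        a = ns.iterative_segment(stack.dapi, params)
        b = ns.iterative_segment(stack.dapi * 37.0 + 11.0, params)
        np.testing.assert_array_equal(a, b)

    def test_labels_consecutive(self, params):
        spec = synth.SceneSpec(n_cells=8, height=300, width=300, seed=24)
        stack, *_ = synth.generate_scene(spec)
        labels = ns.iterative_segment(stack.dapi, params)
        present = np.unique(labels)
        np.testing.assert_array_equal(present, np.arange(labels.max() + 1))


class TestMergeOversegmented:
    def params(self, area):
        return ns.SegParams.for_magnification(
            60, theoretical_area=area, min_fragment_area=10
        )

    def test_split_disk_remerged(self):
        r = 20
        disk = disk_mask((80, 80), (40, 40), r)
        labels = np.zeros((80, 80), np.int32)
        labels[disk & (np.arange(80)[None, :] < 40)] = 1
        labels[disk & (np.arange(80)[None, :] >= 40)] = 2
        quality = {1: "oversegmented", 2: "oversegmented"}
        merged = ns.merge_oversegmented(
            labels, quality, r=5.0, params=self.params(math.pi * r**2)
        )
        assert merged.max() == 1
        np.testing.assert_array_equal(merged > 0, disk)

    def test_isolated_fragment_unchanged(self):
        labels = disk_mask((60, 60), (30, 30), 15).astype(np.int32)
        merged = ns.merge_oversegmented(
            labels,
            {1: "oversegmented"},
            r=5.0,
            params=self.params(math.pi * 15**2),
        )
        np.testing.assert_array_equal(merged, labels)

    def test_merge_never_without_positive_score(self):
        # two far-separated optimal-sized disks: union has terrible solidity
        a = disk_mask((60, 120), (30, 25), 15)
        b = disk_mask((60, 120), (30, 80), 15)
        labels = a.astype(np.int32) + 2 * b.astype(np.int32)
        merged = ns.merge_oversegmented(
            labels,
            {1: "oversegmented", 2: "optimal"},
            r=50.0,
            params=self.params(math.pi * 15**2),
        )
        assert merged.max() == 2


class TestSeededWatershed:
    def test_two_seeds_two_labels(self):
        img = gaussian_blob((80, 80), (25, 40), 8) + gaussian_blob(
            (80, 80), (55, 40), 8
        )
        labels = ns.seeded_watershed(img, [(25, 40), (55, 40)])
        assert labels.max() == 2
        assert labels[25, 40] != labels[55, 40]

    def test_single_seed_uniform_image(self):
        labels = ns.seeded_watershed(np.ones((40, 40)), [(20, 20)])
        assert labels.max() == 1
        assert (labels == 1).all()

    def test_n_seeds_n_distinct_labels(self):
        rng = np.random.default_rng(5)
        img = rng.uniform(0, 1, (100, 100))
        img = ns._suppress_minima(img, 0.0 + 1e-9)  # smooth-free determinism
        seeds = [(int(r), int(c)) for r, c in rng.integers(5, 95, (8, 2))]
        seeds = list(dict.fromkeys(seeds))
        labels = ns.seeded_watershed(img, seeds, depth_fraction=1e-6)
        seed_labels = [labels[r, c] for r, c in seeds]
        assert len(set(seed_labels)) == len(seeds)
        assert labels.max() == len(seeds)

    def test_duplicate_seed_warns(self):
        with pytest.warns(UserWarning, match="duplicate"):
            ns.seeded_watershed(np.ones((20, 20)), [(5, 5), (5, 5)])
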