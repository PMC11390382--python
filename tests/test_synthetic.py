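"""Synthetic slide and feature-bag generators."""

import numpy as np
import pytest
from scipy import ndimage

from natmil.bags import load_bags, save_bags
from natmil.synthetic import (SyntheticBagSpec, SyntheticSlideSpec,
                              generate_feature_bags, generate_slide)


class TestSlides:
    def test_zero_tumor(self):
        s = generate_slide(SyntheticSlideSpec(8, 8, tile_px=8, tumor_fraction=0.0,
                                              blob_count=0))
        assert s.tile_labels.sum() == 0
        assert s.slide_label == 0

    def test_saturated(self):
        s = generate_slide(SyntheticSlideSpec(6, 6, tile_px=8, tumor_fraction=1.0,
                                              blob_count=1))
        assert s.tile_labels.min() == 1
        assert s.slide_label == 1

    def test_fraction_control_32x32(self):
        # construction paints blobs until floor(f*n) tiles are tumor
        s = generate_slide(SyntheticSlideSpec(32, 32, tile_px=8,
                                              tumor_fraction=0.05,
                                              blob_count=2, seed=7))
        assert 45 <= s.tile_labels.sum() <= 57

    @pytest.mark.parametrize("frac", [0.05, 0.2, 0.8])
    def test_fraction_exact_by_construction(self, frac):
        s = generate_slide(SyntheticSlideSpec(32, 32, tile_px=8,
                                              tumor_fraction=frac,
                                              blob_count=1, seed=3))
        assert s.tile_labels.sum() == int(np.floor(frac * 32 * 32))

    def test_label_is_or_of_tiles(self):
        for frac in (0.0, 0.1):
            s = generate_slide(SyntheticSlideSpec(8, 8, tile_px=8,
                                                  tumor_fraction=frac,
                                                  blob_count=1, seed=1))
            assert s.slide_label == int(s.tile_labels.max())

    def test_blob_components(self):
        s = generate_slide(SyntheticSlideSpec(32, 32, tile_px=8,
                                              tumor_fraction=0.05,
                                              blob_count=2, seed=7))
        _, ncomp = ndimage.label(s.tile_labels)
        assert ncomp == 2

    def test_deterministic(self):
        spec = SyntheticSlideSpec(16, 16, tile_px=8, tumor_fraction=0.1,
                                  blob_count=1, seed=42)
        a, b = generate_slide(spec), generate_slide(spec)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.tile_labels, b.tile_labels)

    def test_background_near_white(self):
        s = generate_slide(SyntheticSlideSpec(16, 16, tile_px=8,
                                              tumor_fraction=0.05, blob_count=1,
                                              seed=2, tissue_fraction=0.5))
        bg = ~np.repeat(np.repeat(s.tissue_tiles, 8, 0), 8, 1)
        assert s.image[bg].mean() > 230

    def test_tumor_darker_than_tissue(self):
        s = generate_slide(SyntheticSlideSpec(16, 16, tile_px=8,
                                              tumor_fraction=0.2, blob_count=1,
                                              seed=2))
        up = lambda m: np.repeat(np.repeat(m, 8, 0), 8, 1)
        tumor_px = up(s.tile_labels == 1)
        tissue_px = up(s.tissue_tiles & (s.tile_labels == 0))
        assert s.image[tumor_px].mean() < s.image[tissue_px].mean()

    def test_periodic_motif_present(self):
        # tumor everywhere -> per-tile-column mean luminance carries the
        # configured period as its dominant nonzero frequency
        s = generate_slide(SyntheticSlideSpec(32, 32, tile_px=8,
                                              tumor_fraction=1.0, blob_count=1,
                                              motif_period=8, noise_sd=1.0, seed=0))
        lum = s.image.mean(axis=2)
        col_means = lum.reshape(32, 8, 32, 8).mean(axis=(1, 3)).mean(axis=0)
        spec = np.abs(np.fft.rfft(col_means - col_means.mean()))
        assert np.argmax(spec[1:]) + 1 == 4  # 32 cols / period 8

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            generate_slide(SyntheticSlideSpec(2, 8, tumor_fraction=0.1))
        with pytest.raises(ValueError):
            generate_slide(SyntheticSlideSpec(8, 8, tile_px=4))
        with pytest.raises(ValueError):
            generate_slide(SyntheticSlideSpec(8, 8, tumor_fraction=0.1,
                                              blob_count=0))


class TestBags:
    def test_exact_positive_count(self):
        bags = generate_feature_bags(SyntheticBagSpec(n_bags=10,
                                                      positive_fraction=0.5))
        assert sum(b.label for b in bags) == 5

    def test_labels_consistent_with_tiles(self):
        bags = generate_feature_bags(SyntheticBagSpec(n_bags=12, seed=3))
        for b in bags:
            assert b.label == int(b.tile_labels.max())
            if b.label:
                assert b.tile_labels.sum() >= 1
            else:
                assert b.tile_labels.sum() == 0

    def test_null_separation_indistinguishable(self):
        bags = generate_feature_bags(SyntheticBagSpec(
            n_bags=40, class_separation=0.0, cluster=False, seed=0))
        from sklearn.linear_model import LogisticRegression
        from sklearn.metrics import roc_auc_score

        X = np.stack([b.H.mean(0) for b in bags])
        y = np.array([b.label for b in bags])
        clf = LogisticRegression(max_iter=500).fit(X[:20], y[:20])
        auc = roc_auc_score(y[20:], clf.predict_proba(X[20:])[:, 1])
        assert 0.2 < auc < 0.8  # chance-level up to small-sample noise

    def test_strong_separation_probe(self):
        # linear probe on mean-pooled bags separates classes
        bags = generate_feature_bags(SyntheticBagSpec(
            n_bags=200, d=16, class_separation=6.0, cluster=False, seed=1))
        from sklearn.linear_model import LogisticRegression
        from sklearn.metrics import roc_auc_score

        X = np.stack([b.H.mean(0) for b in bags])
        y = np.array([b.label for b in bags])
        clf = LogisticRegression(max_iter=500).fit(X[:100], y[:100])
        assert roc_auc_score(y[100:], clf.predict_proba(X[100:])[:, 1]) > 0.95

    def test_clustered_positives_contiguous(self):
        bags = generate_feature_bags(SyntheticBagSpec(
            n_bags=10, grid_height=12, grid_width=12, cluster=True,
            tumor_fraction=0.1, seed=2))
        for b in bags:
            if b.label:
                grid = np.zeros((12, 12), dtype=int)
                grid[b.rows[b.tile_labels == 1], b.cols[b.tile_labels == 1]] = 1
                _, ncomp = ndimage.label(grid)
                assert ncomp == 1

    def test_hard_negatives_match_marginals(self):
        spec = SyntheticBagSpec(n_bags=40, grid_height=10, grid_width=10,
                                cluster=True, class_separation=5.0,
                                tumor_fraction=0.1, seed=4)
        bags = generate_feature_bags(spec)
        proj = []
        for b in bags:
            proj.append((b.label, b.H.mean()))
        pos = [v for l, v in proj if l]
        neg = [v for l, v in proj if not l]
        # shifted mass present in both classes -> means comparable
        assert abs(np.mean(pos) - np.mean(neg)) < 0.02

    def test_deterministic(self):
        spec = SyntheticBagSpec(n_bags=6, seed=9)
        a = generate_feature_bags(spec)
        b = generate_feature_bags(spec)
        for x, y in zip(a, b):
            assert np.array_equal(x.H, y.H)
            assert x.label == y.label

    def test_errors(self):
        with pytest.raises(ValueError):
            generate_feature_bags(SyntheticBagSpec(n_bags=1))
        with pytest.raises(ValueError):
            generate_feature_bags(SyntheticBagSpec(n_bags=4, d=1))
        with pytest.raises(ValueError):
            generate_feature_bags(SyntheticBagSpec(n_bags=4, positive_fraction=1.0))


def test_bag_h5_roundtrip(tmp_path):
    bags = generate_feature_bags(SyntheticBagSpec(n_bags=4, seed=1))
    path = tmp_path / "bags.h5"
    save_bags(path, bags, seed=1)
    loaded = load_bags(path)
    assert len(loaded) == 4
    by_id = {b.slide_id: b for b in bags}
    for lb in loaded:
        orig = by_id[lb.slide_id]
        assert np.array_equal(lb.H, orig.H)
        assert np.array_equal(lb.rows, orig.rows)
        assert lb.label == orig.label
        assert np.array_equal(lb.tile_labels, orig.tile_labels)
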