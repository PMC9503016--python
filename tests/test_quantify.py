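"""Heatmaps, blob labeling, and region-stratified deposit counting."""

import numpy as np
import pytest

from histoseg import quantify, synthetic
from histoseg.inference import LabelMask
from histoseg.quantify import (PlaqueOracle, generate_confidence_heatmaps,
                               quantify_plaques, render_overlay,
                               threshold_and_label)
from histoseg.synthetic import GM, PLAQUE_TYPES, WM


@pytest.fixture(scope="module")
def separated_sample():
    """Slide whose deposits are farther apart than 2x the heatmap stride."""
    spec = synthetic.SyntheticSpec(
        image_width=640, image_height=640, region_layout_seed=21,
        rng_seed=21,
        plaque_rates={("cored", "GM"): 5.0, ("cored", "WM"): 2.0,
                      ("diffuse", "GM"): 4.0, ("CAA", "WM"): 1.0})
    for attempt in range(50):
        sample = synthetic.generate_tissue_sample(
            synthetic.SyntheticSpec(
                **{**spec.__dict__, "rng_seed": 21 + attempt}))
        pts = np.array([(x, y) for x, y, _ in sample.plaques], dtype=float)
        if len(pts) < 2:
            continue
        d = np.sqrt(((pts[None] - pts[:, None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        if d.min() > 32 and len(pts) >= 6:
            return sample
    raise RuntimeError("no well-separated sample found")


def truth_counts(sample):
    counts = {(t, r): 0 for t in PLAQUE_TYPES for r in ("GM", "WM")}
    for x, y, t in sample.plaques:
        region = "GM" if sample.mask[y, x] == GM else "WM"
        counts[(t, region)] += 1
    return counts


class TestHeatmaps:
    def test_constant_zero_stub(self, small_sample):
        hm = generate_confidence_heatmaps(small_sample.image,
                                          lambda patch: np.zeros(3))
        assert hm.cored.max() == 0 and hm.diffuse.max() == 0

    def test_shape_is_image_over_stride(self):
        img = np.zeros((512, 512, 3), dtype=np.uint8)
        hm = generate_confidence_heatmaps(img, lambda p: np.zeros(3),
                                          stride=16)
        assert hm.cored.shape == (32, 32)

    def test_oracle_support_equals_plaque_blocks(self, separated_sample):
        oracle = PlaqueOracle(separated_sample, stride=16)
        hm = generate_confidence_heatmaps(separated_sample.image, oracle,
                                          stride=16)
        layers = hm.layers()
        for t in PLAQUE_TYPES:
            expected = {(x // 16, y // 16)
                        for x, y, k in separated_sample.plaques if k == t}
            got = {(int(x), int(y)) for y, x in zip(*np.nonzero(layers[t]))}
            assert got == expected


class TestThresholdAndLabel:
    def test_all_below_threshold(self):
        _, n, _ = threshold_and_label(np.full((8, 8), 0.2), 0.5)
        assert n == 0

    def test_two_squares_two_blobs_centroids(self):
        layer = np.zeros((20, 20))
        layer[2:5, 2:5] = 0.9
        layer[12:15, 12:15] = 0.9
        _, n, centroids = threshold_and_label(layer, 0.5)
        assert n == 2
        got = sorted(map(tuple, np.round(centroids, 6)))
        assert got == [(3.0, 3.0), (13.0, 13.0)]

    def test_tie_counts_as_detection(self):
        layer = np.zeros((4, 4))
        layer[1, 1] = 0.5
        _, n, _ = threshold_and_label(layer, 0.5)
        assert n == 1

    def test_monotone_in_threshold(self, rng):
        layer = rng.random((30, 30))
        counts = [threshold_and_label(layer, t)[1]
                  for t in (0.2, 0.5, 0.8, 0.95)]
        # blob count can merge/split, but detections cannot appear from
        # nothing: the *supra-threshold area* is monotone
        areas = [int((layer >= t).sum()) for t in (0.2, 0.5, 0.8, 0.95)]
        assert areas == sorted(areas, reverse=True)
        assert counts[-1] <= counts[0] or areas[-1] < areas[0]

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            threshold_and_label(np.zeros((4, 4)), 1.5)


class TestQuantify:
    def test_no_plaques_zero_vector(self, plaque_free_sample):
        oracle = PlaqueOracle(plaque_free_sample)
        g = LabelMask(labels=plaque_free_sample.mask)
        out = quantify_plaques(plaque_free_sample.image, oracle, g)
        assert out.as_vector().tolist() == [0] * 6

    def test_blob_mode_recovers_ground_truth(self, separated_sample):
        oracle = PlaqueOracle(separated_sample, stride=16)
        g = LabelMask(labels=separated_sample.mask)
        out = quantify_plaques(separated_sample.image, oracle, g,
                               mode="blob", stride=16)
        assert out.counts == truth_counts(separated_sample)

    def test_counts_partition_total(self, separated_sample):
        oracle = PlaqueOracle(separated_sample, stride=16)
        g = LabelMask(labels=separated_sample.mask)
        out = quantify_plaques(separated_sample.image, oracle, g,
                               mode="blob", stride=16)
        assert out.total() + len(out.dropped) == len(
            separated_sample.plaques)

    def test_patch_mode_counts_windows(self, separated_sample):
        oracle = PlaqueOracle(separated_sample, stride=16)
        g = LabelMask(labels=separated_sample.mask)
        out = quantify_plaques(separated_sample.image, oracle, g,
                               mode="patch", stride=16)
        # oracle fires exactly one window per deposit, so the literal
        # per-window accumulator agrees with blob counting here
        assert out.counts == truth_counts(separated_sample)

    def test_mismatched_mask_rejected(self, separated_sample):
        oracle = PlaqueOracle(separated_sample)
        bad = LabelMask(labels=separated_sample.mask[::2, ::2])
        with pytest.raises(ValueError):
            quantify_plaques(separated_sample.image, oracle, bad)


class TestOverlay:
    def test_empty_heatmaps_tint_only(self, plaque_free_sample):
        oracle = PlaqueOracle(plaque_free_sample)
        hm = generate_confidence_heatmaps(plaque_free_sample.image, oracle)
        mask = LabelMask(labels=plaque_free_sample.mask)
        out = render_overlay(plaque_free_sample.image, hm, mask)
        assert out.shape == plaque_free_sample.image.shape
        assert not np.any(np.all(out == (255, 140, 0), axis=-1))

    def test_detections_render_orange(self, separated_sample):
        oracle = PlaqueOracle(separated_sample, stride=16)
        hm = generate_confidence_heatmaps(separated_sample.image, oracle,
                                          stride=16)
        mask = LabelMask(labels=separated_sample.mask)
        out = render_overlay(separated_sample.image, hm, mask)
        orange = np.all(out == (255, 140, 0), axis=-1)
        assert np.any(orange)


def test_heatmap_tiff_roundtrip(plaque_free_sample, tmp_path):
    hm = generate_confidence_heatmaps(plaque_free_sample.image,
                                      lambda p: np.full(3, 0.25), stride=16)
    path = tmp_path / "hm.tif"
    quantify.save_heatmaps(hm, path)
    back = quantify.load_heatmaps(path, stride=16)
    assert np.allclose(back.cored, hm.cored, atol=1e-6)
    assert np.allclose(back.caa, hm.caa, atol=1e-6)
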