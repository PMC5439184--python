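"""Image preprocessing, spike encoding, scrambling, synthetic image sets."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from famnet import (ImagePattern, encode_image, generate_synthetic_faces,
                    normalize_image_set, preprocess_image, scramble_image,
                    upscale_pattern)


class TestPreprocess:
    def test_downsample_with_edges(self):
        rng = np.random.default_rng(0)
        img = np.zeros((200, 200))
        img[60:140, 60:140] = 200.0  # a bright square: edges at the border
        img += rng.uniform(0, 5, img.shape)
        pat = preprocess_image(img, (20, 20), mode="edge")
        assert pat.shape == (20, 20)
        assert pat.pixels.min() >= 0 and pat.pixels.max() <= 255
        # edge energy concentrates at the square border, not its interior
        assert pat.pixels[8:12, 8:12].mean() < pat.pixels[6, 6:14].mean()

    def test_constant_image_has_no_edges(self):
        pat = preprocess_image(np.full((50, 50), 99.0), (10, 10), mode="edge")
        assert np.allclose(pat.pixels, 0.0)

    def test_output_range_clipped(self):
        pat = preprocess_image(np.full((30, 30), 255.0), (10, 10))
        assert pat.pixels.max() <= 255.0

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            preprocess_image(np.empty((0, 0)), (10, 10))


class TestUpscale:
    def test_shape_and_block_replication(self):
        px = np.zeros((20, 20))
        px[0, 0] = 255.0
        up = upscale_pattern(ImagePattern(px))
        assert up.shape == (50, 50)
        assert np.all(up.pixels[:2, :2] == 255.0)
        assert up.pixels[2:, :].sum() == 0 and up.pixels[:, 2:].sum() == 0

    def test_padding_region_void(self):
        up = upscale_pattern(np.full((20, 20), 100.0))
        assert np.all(up.pixels[40:, :] == 0.0)
        assert np.all(up.pixels[:, 40:] == 0.0)
        assert np.all(up.pixels[:40, :40] == 100.0)

    def test_wrong_size_rejected(self):
        with pytest.raises(ValueError):
            upscale_pattern(np.zeros((10, 10)))


class TestEncode:
    def test_max_pixel_rate(self):
        pat = ImagePattern(np.array([[255.0]]))
        counts = [encode_image(pat, seed=s).total_spikes() for s in range(40)]
        # expectation 50 Hz * 0.5 s = 25 spikes
        mean = np.mean(counts)
        assert abs(mean - 25.0) < 4 * np.sqrt(25.0 / len(counts))

    def test_zero_pixel_silent(self):
        st_ = encode_image(ImagePattern(np.zeros((3, 3))), seed=1)
        assert st_.total_spikes() == 0

    def test_spikes_confined_to_active_window(self):
        st_ = encode_image(ImagePattern(np.full((5, 5), 255.0)), seed=2)
        allt = np.concatenate([t for t in st_.spike_times if len(t)])
        assert allt.max() < 0.5
        assert st_.duration == pytest.approx(1.0)

    def test_regular_mode_fixed_frequency(self):
        st_ = encode_image(ImagePattern(np.array([[255.0]])), regular=True)
        t = st_.spike_times[0]
        assert np.allclose(np.diff(t), 0.02)

    def test_rate_fidelity(self):
        pat = ImagePattern(np.array([[128.0]]))
        total = sum(encode_image(pat, seed=s).total_spikes() for s in range(60))
        rate = total / 60 / 0.5
        assert rate == pytest.approx(128 / 255 * 50, rel=0.1)


class TestScramble:
    @given(seed=st.integers(0, 10))
    @settings(max_examples=10, deadline=None)
    def test_permutation_invariants(self, seed):
        rng = np.random.default_rng(seed)
        pat = ImagePattern(rng.uniform(0, 255, (8, 8)))
        sc = scramble_image(pat, seed=seed)
        assert np.allclose(np.sort(sc.pixels.ravel()),
                           np.sort(pat.pixels.ravel()))
        assert sc.pixels.mean() == pytest.approx(pat.pixels.mean())

    def test_seed_determinism(self):
        pat = ImagePattern(np.arange(64.0).reshape(8, 8))
        a = scramble_image(pat, seed=3)
        b = scramble_image(pat, seed=3)
        assert np.array_equal(a.pixels, b.pixels)


class TestSyntheticFaces:
    def test_class_structure(self):
        imgs = generate_synthetic_faces(3, 8, (12, 12), seed=4)
        assert len(imgs) == 24
        px = np.array([im.pixels.ravel() for im in imgs])
        cc = np.corrcoef(px)
        labels = np.repeat(np.arange(3), 8)
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(24, dtype=bool)
        assert cc[same & off].mean() > cc[~same].mean()

    def test_feature_block_only_in_marked_class(self):
        spec = {"classes": [0], "region": (slice(9, 12), slice(3, 9)),
                "value": 255.0}
        imgs = generate_synthetic_faces(2, 5, (12, 12), feature_spec=spec,
                                        seed=5)
        for im in imgs[:5]:
            assert np.all(im.pixels[9:12, 3:9] == 255.0)
        for im in imgs[5:]:
            assert not np.all(im.pixels[9:12, 3:9] == 255.0)

    def test_seed_determinism(self):
        a = generate_synthetic_faces(2, 3, (10, 10), seed=6)
        b = generate_synthetic_faces(2, 3, (10, 10), seed=6)
        for x, y in zip(a, b):
            assert np.array_equal(x.pixels, y.pixels)

    def test_degenerate_size_rejected(self):
        with pytest.raises(ValueError):
            generate_synthetic_faces(1, 1, (1, 1))
        with pytest.raises(ValueError):
            generate_synthetic_faces(0, 1, (10, 10))


class TestNormalize:
    def test_single_image_unchanged(self):
        img = ImagePattern(np.full((5, 5), 100.0))
        out, log = normalize_image_set([img], probe=lambda ims: [10.0])
        assert np.array_equal(out[0].pixels, img.pixels)
        assert log["converged"]

    def test_converges_under_linear_probe(self):
        # response proportional to mean pixel value: 0.2 Hz per unit
        imgs = [ImagePattern(np.full((4, 4), v)) for v in (40.0, 120.0, 200.0)]
        probe = lambda ims: [0.2 * im.pixels.mean() + 5.0 for im in ims]
        out, log = normalize_image_set(imgs, probe, tolerance=0.02,
                                       max_iters=30)
        resp = np.asarray(probe(out))
        assert log["converged"]
        assert np.abs(resp - resp.mean()).max() <= 0.02 * resp.mean() + 1e-9

    def test_saturated_image_flagged(self):
        imgs = [ImagePattern(np.full((4, 4), 255.0)),
                ImagePattern(np.full((4, 4), 250.0))]
        probe = lambda ims: [1.0, 100.0]  # first image can never catch up
        out, log = normalize_image_set(imgs, probe, max_iters=5)
        assert not log["converged"]
        assert 0 in log["clipped"]
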