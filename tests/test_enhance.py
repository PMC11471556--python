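"""Dark-channel dehazing and bi-histogram equalization."""

import numpy as np
import pytest

from foliar import enhance as E
from foliar import synthetic

from conftest import luminance

RNG = np.random.default_rng(123)


def brute_force_dark_channel(image, patch):
    """Double-loop sliding-window minimum oracle."""
    h, w = image.shape[:2]
    r = patch // 2
    cmin = image.min(axis=2)
    out = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            out[i, j] = cmin[max(0, i - r) : i + r + 1, max(0, j - r) : j + r + 1].min()
    return out


class TestDarkChannel:
    @pytest.mark.parametrize(
        "color,expected",
        [((1.0, 1.0, 1.0), 1.0), ((0.8, 0.5, 0.2), 0.2)],
    )
    def test_uniform_image_gives_channel_minimum(self, color, expected):
        img = np.broadcast_to(np.array(color), (6, 6, 3)).copy()
        assert np.allclose(E.dark_channel(img, 3), expected)

    def test_single_dark_pixel_spreads_over_patch(self):
        img = np.full((5, 5, 3), 0.9)
        img[2, 2] = 0.0
        dark = E.dark_channel(img, 3)
        expected = np.full((5, 5), 0.9)
        expected[1:4, 1:4] = 0.0
        assert np.allclose(dark, expected)

    @pytest.mark.parametrize("patch", [1, 3, 5])
    def test_matches_brute_force_on_random_images(self, patch):
        for _ in range(5):
            img = RNG.random((RNG.integers(6, 17), RNG.integers(6, 17), 3))
            assert np.allclose(E.dark_channel(img, patch), brute_force_dark_channel(img, patch))

    @pytest.mark.parametrize("patch", [2, 99])
    def test_invalid_patch_rejected(self, patch):
        with pytest.raises(ValueError):
            E.dark_channel(RNG.random((8, 8, 3)), patch)


class TestAtmosphericLight:
    def test_uniform_gray_image(self):
        img = np.full((10, 10, 3), 0.5)
        light = E.estimate_atmospheric_light(img, E.dark_channel(img, 3))
        assert np.allclose(light, 0.5)

    def test_half_black_half_white(self):
        img = np.zeros((10, 10, 3))
        img[5:] = 1.0
        light = E.estimate_atmospheric_light(img, E.dark_channel(img, 1))
        assert np.allclose(light, 1.0)

    def test_single_forced_white_pixel_dominates(self):
        img = 0.5 * RNG.random((20, 20, 3))
        img[3, 4] = 1.0
        light = E.estimate_atmospheric_light(img, E.dark_channel(img, 1))
        assert np.allclose(light, 1.0)


class TestTransmission:
    def test_black_object_on_white_light_gives_full_transmission(self):
        img = np.full((9, 9, 3), 0.0)
        cfg = E.HazeConfig(patch=3)
        t = E.estimate_transmission(img, np.ones(3), cfg)
        assert np.allclose(t, 1.0)

    def test_white_image_gives_one_minus_omega(self):
        img = np.ones((9, 9, 3))
        cfg = E.HazeConfig(patch=3, omega=0.95)
        assert np.allclose(E.estimate_transmission(img, np.ones(3), cfg), 0.05)

    def test_recovers_known_constant_transmission(self, dehaze_scene):
        hazy = synthetic.add_haze(dehaze_scene, 0.6)
        cfg = E.HazeConfig(omega=1.0)
        t = E.estimate_transmission(hazy, np.ones(3), cfg)
        # the scene dark channel is zero away from the highlight, so the
        # estimate equals the true constant there
        assert np.median(np.abs(t - 0.6)) < 0.05

    def test_zero_light_component_rejected(self):
        with pytest.raises(ValueError):
            E.estimate_transmission(RNG.random((9, 9, 3)), np.array([1.0, 0.0, 1.0]))


class TestRecovery:
    def test_image_equal_to_offset_is_fixed_point(self):
        img = np.full((4, 4, 3), 0.2)
        for t in (0.05, 0.4, 1.0):
            out = E.recover_radiance(img, np.full((4, 4), t), offset=0.2)
            assert np.allclose(out, 0.2)

    def test_direct_evaluation(self):
        # (0.6 - 0.2) / 0.5 + 0.2 = 1.0
        img = np.full((1, 1, 3), 0.6)
        out = E.recover_radiance(img, np.full((1, 1), 0.5), offset=0.2, t0=0.1)
        assert np.allclose(out, 1.0)

    def test_transmission_floor_active(self):
        # max(T, t0) = 0.1: (0.25 - 0.2) / 0.1 + 0.2 = 0.7
        img = np.full((1, 1, 3), 0.25)
        out = E.recover_radiance(img, np.full((1, 1), 0.01), offset=0.2, t0=0.1)
        assert np.allclose(out, 0.7)

    def test_constant_image_is_dehaze_fixed_point(self):
        img = np.full((20, 20, 3), 0.2)
        assert np.allclose(E.dehaze(img, E.HazeConfig(patch=3)), 0.2)

    @pytest.mark.parametrize("t", [0.3, 0.5, 0.7, 0.9])
    def test_inverts_forward_haze_synthesis(self, dehaze_scene, t):
        hazy = synthetic.add_haze(dehaze_scene, t)
        restored = E.dehaze(hazy)
        mae_hazy = np.abs(hazy - dehaze_scene).mean()
        mae_restored = np.abs(restored - dehaze_scene).mean()
        assert mae_restored < mae_hazy


class TestBihe:
    def test_constant_image_unchanged(self):
        img = np.full((16, 16, 3), 0.5)
        assert np.array_equal(E.bihe(img), img)

    def test_uniform_histogram_is_near_identity(self):
        # luminance uniform over [0, 1]: equalization is identity up to a bin
        vals = (np.arange(4096) + 0.5) / 4096
        img = np.repeat(vals, 3).reshape(64, 64, 3)
        out = E.bihe(img, E.BiheConfig(brightness_target=False))
        assert np.abs(luminance(out) - luminance(img)).max() < 1.5 / 256

    def test_bimodal_image_two_subhistograms_and_mean_preserved(self):
        img = np.full((16, 16, 3), 0.3)
        img[8:] = 0.7
        segments = E.bihe_partition(luminance(img))
        assert len(segments) == 2
        out = E.bihe(img)
        assert abs(luminance(out).mean() - luminance(img).mean()) < 0.02

    def test_mean_luminance_preserved_on_fixture(self, leaf_set):
        for img in leaf_set[0][:5]:
            out = E.bihe(img)
            assert abs(luminance(out).mean() - luminance(img).mean()) < 0.02


class TestEnhance:
    def test_constant_image_stays_constant(self):
        img = np.full((20, 20, 3), 0.2)
        out = E.enhance(img, E.HazeConfig(patch=3))
        assert np.ptp(out) < 1e-9

    def test_contrast_increases_on_low_contrast_fixture(self, low_contrast_leaf):
        img, _mask = low_contrast_leaf
        out = E.enhance(img)
        assert luminance(out).std() >= luminance(img).std()

    def test_outputs_bounded_and_shape_preserved(self, leaf_set):
        img = leaf_set[0][0]
        out = E.enhance(img)
        assert out.shape == img.shape
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestImageIO:
    def test_round_half_up_quantization_round_trip(self, tmp_path):
        img = np.array([[[0.0, 0.5, 1.0]]] * 2, dtype=float).reshape(1, 2, 3)
        path = tmp_path / "x.png"
        E.save_image(path, img)
        back = E.load_image(path)
        assert np.allclose(back * 255, np.floor(img * 255 + 0.5))

    def test_enhance_directory_mirrors_tree(self, tmp_path, leaf_set):
        src = tmp_path / "in" / "class_0"
        src.mkdir(parents=True)
        for i, img in enumerate(leaf_set[0][:2]):
            E.save_image(src / f"img_{i}.png", img)
        n = E.enhance_directory(tmp_path / "in", tmp_path / "out")
        assert n == 2
        assert sorted(p.name for p in (tmp_path / "out" / "class_0").iterdir()) == [
            "img_0.png",
            "img_1.png",
        ]
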