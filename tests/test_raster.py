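"""Raster primitives: LUT contrast, isodata thresholding, binarization, I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import neuridi as nd


class TestApplyLut:
    @pytest.mark.parametrize(
        "value,expected",
        [(90, 0), (205, 255), (0, 0), (255, 255), (148, 129)],
    )
    def test_linear_window_mapping(self, value, expected):
        """The 90-205 window maps its endpoints to 0/255, values outside clamp,
        interior values follow round-half-up on the linear ramp."""
        img = np.full((3, 3), value, dtype=np.uint8)
        out = nd.apply_lut(img, nd.ContrastLUT(90, 205))
        assert int(out[0, 0]) == expected

    def test_invalid_window_rejected(self):
        with pytest.raises(nd.ConfigurationError):
            nd.ContrastLUT(205, 90)
        with pytest.raises(nd.ConfigurationError):
            nd.ContrastLUT(100, 100)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        img=hnp.arrays(np.uint8, (8, 8)),
        lo=st.integers(0, 254),
        span=st.integers(1, 255),
    )
    def test_monotone_nondecreasing(self, img, lo, span):
        """v1 <= v2 implies lut(v1) <= lut(v2) for every window."""
        hi = min(lo + span, 255)
        if hi <= lo:
            return
        out = nd.apply_lut(img, nd.ContrastLUT(lo, hi))
        flat_in = img.ravel().astype(int)
        flat_out = out.ravel().astype(int)
        order = np.argsort(flat_in, kind="stable")
        assert np.all(np.diff(flat_out[order]) >= 0)


class TestIsodata:
    def test_two_mass_histogram(self):
        """60 px at 50 and 40 px at 200 converge to the intermeans value 125."""
        img = np.concatenate(
            [np.full(60, 50, np.uint8), np.full(40, 200, np.uint8)]
        ).reshape(10, 10)
        assert nd.isodata_threshold(img) == 125

    def test_binary_extremes(self):
        img = np.concatenate(
            [np.zeros(50, np.uint8), np.full(50, 255, np.uint8)]
        ).reshape(10, 10)
        assert nd.isodata_threshold(img) == 127

    def test_constant_image_raises(self):
        with pytest.raises(nd.DegenerateHistogramError):
            nd.isodata_threshold(np.full((5, 5), 42, np.uint8))

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(data=st.data())
    def test_intermeans_fixed_point(self, data):
        """The returned threshold satisfies the intermeans fixed-point
        condition found by brute-force scan of all candidate thresholds."""
        n_levels = data.draw(st.integers(2, 6))
        levels = data.draw(
            st.lists(st.integers(0, 255), min_size=n_levels, max_size=n_levels, unique=True)
        )
        counts = data.draw(
            st.lists(st.integers(1, 50), min_size=n_levels, max_size=n_levels)
        )
        pixels = np.repeat(np.array(levels, np.uint8), counts)
        img = pixels.reshape(1, -1)
        t = nd.isodata_threshold(img)

        hist = np.bincount(pixels, minlength=256).astype(float)
        lv = np.arange(256.0)
        fixed_points = []
        for cand in range(255):
            n_lo = hist[: cand + 1].sum()
            n_hi = hist[cand + 1:].sum()
            if n_lo == 0 or n_hi == 0:
                continue
            m_lo = (hist[: cand + 1] * lv[: cand + 1]).sum() / n_lo
            m_hi = (hist[cand + 1:] * lv[cand + 1:]).sum() / n_hi
            if int(np.floor((m_lo + m_hi) / 2.0)) == cand:
                fixed_points.append(cand)
        assert t in fixed_points

    def test_matches_skimage_isodata_closely(self):
        """Cross-check against an independent isodata implementation; the
        two variants may differ by at most one gray level of rounding."""
        from skimage.filters import threshold_isodata

        rng = np.random.default_rng(11)
        for _ in range(20):
            img = np.concatenate(
                [
                    rng.normal(60, 10, 400),
                    rng.normal(180, 12, rng.integers(50, 400)),
                ]
            )
            img = np.clip(np.round(img), 0, 255).astype(np.uint8).reshape(1, -1)
            ours = nd.isodata_threshold(img)
            ref = int(threshold_isodata(img.ravel()))
            assert abs(ours - ref) <= 1


class TestBinarize:
    def test_polarity_selects_signal(self):
        img = np.full((10, 10), 200, np.uint8)
        img[2:5, 2:5] = 40  # dark cells on bright background (phase)
        dark = nd.binarize(img, nd.DARK_FOREGROUND)
        assert dark[3, 3] and not dark[0, 0]
        bright = nd.binarize(255 - img, nd.BRIGHT_FOREGROUND)
        assert bright[3, 3] and not bright[0, 0]

    def test_degenerate_image_warns_and_returns_empty(self, caplog):
        with caplog.at_level("WARNING", logger="neuridi"):
            mask = nd.binarize(np.zeros((6, 6), np.uint8), nd.BRIGHT_FOREGROUND)
        assert not mask.any()
        assert any("constant" in r.message for r in caplog.records)

    def test_unknown_mode_rejected(self):
        with pytest.raises(nd.ConfigurationError):
            nd.binarize(np.zeros((4, 4), np.uint8), "sideways")

    def test_polarity_symmetry_up_to_threshold_ties(self):
        """binarize(img, dark) and binarize(255-img, bright) agree except at
        pixels within one gray level of the threshold."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            img = np.clip(
                np.round(
                    np.concatenate(
                        [rng.normal(70, 15, 300), rng.normal(190, 15, 100)]
                    )
                ),
                0,
                255,
            ).astype(np.uint8).reshape(20, 20)
            t = nd.isodata_threshold(img)
            a = nd.binarize(img, nd.DARK_FOREGROUND)
            b = nd.binarize((255 - img).astype(np.uint8), nd.BRIGHT_FOREGROUND)
            disagree = img[a != b]
            assert np.all(np.abs(disagree.astype(int) - t) <= 1)


class TestIO:
    def test_png_roundtrip(self, tmp_path):
        img = np.arange(64, dtype=np.uint8).reshape(8, 8)
        nd.save_image(tmp_path / "a.png", img)
        assert np.array_equal(nd.load_image(tmp_path / "a.png"), img)

    def test_tiff_roundtrip(self, tmp_path):
        img = np.arange(64, dtype=np.uint8).reshape(8, 8)
        nd.save_image(tmp_path / "a.tif", img)
        assert np.array_equal(nd.load_image(tmp_path / "a.tif"), img)

    def test_uint16_rescaled_to_8bit(self, tmp_path):
        import tifffile

        img16 = np.array([[0, 1000], [2000, 4000]], dtype=np.uint16)
        tifffile.imwrite(tmp_path / "deep.tif", img16)
        out = nd.load_image(tmp_path / "deep.tif")
        assert out.dtype == np.uint8
        assert out[0, 0] == 0 and out[1, 1] == 255

    def test_color_image_rejected(self, tmp_path):
        import imageio.v3 as iio

        rgb = np.zeros((4, 4, 3), np.uint8)
        rgb[..., 0] = 200  # genuinely colored
        iio.imwrite(tmp_path / "c.png", rgb)
        with pytest.raises(nd.ConfigurationError):
            nd.load_image(tmp_path / "c.png")

    def test_gray_saved_as_rgb_accepted(self, tmp_path):
        import imageio.v3 as iio

        g = np.random.default_rng(0).integers(0, 255, (4, 4), np.uint8)
        iio.imwrite(tmp_path / "g.png", np.stack([g, g, g], axis=-1))
        assert np.array_equal(nd.load_image(tmp_path / "g.png"), g)


class TestAutoscale:
    def test_stretches_to_full_range(self):
        rng = np.random.default_rng(5)
        img = np.clip(rng.normal(120, 10, (50, 50)), 0, 255).astype(np.uint8)
        out = nd.autoscale(img)
        assert out.min() == 0 and out.max() == 255

    def test_degenerate_window_returns_input(self, caplog):
        img = np.full((10, 10), 77, np.uint8)
        with caplog.at_level("WARNING", logger="neuridi"):
            out = nd.autoscale(img)
        assert np.array_equal(out, img)
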