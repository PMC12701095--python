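"""Canonicalisation chain: cropping, orientation, CLAHE, padding, resizing."""

import numpy as np
import pytest

from mammoseg.preprocess import (
    TransformRecord,
    clahe,
    crop_borders,
    invert_mask,
    normalize_range,
    orient_right,
    pad_to_square,
    preprocess_pair,
    resize_to,
)


class TestCropBorders:
    @pytest.mark.parametrize(
        "shape,fracs,expected",
        [
            ((1000, 800), (0.025, 0.01), (950, 784)),
            ((640, 640), (0.025, 0.01), (608, 628)),
            ((100, 100), (0.0, 0.0), (100, 100)),
        ],
    )
    def test_floor_arithmetic(self, shape, fracs, expected, rng):
        img = rng.integers(0, 255, size=shape).astype(np.uint8)
        out, rec = crop_borders(img, *fracs)
        assert out.shape == expected
        if fracs == (0.0, 0.0):
            np.testing.assert_array_equal(out, img)

    def test_record_fields(self, rng):
        img = rng.integers(0, 255, size=(1000, 800)).astype(np.uint8)
        out, rec = crop_borders(img, 0.025, 0.01)
        assert (rec.crop_top, rec.crop_bottom, rec.crop_left, rec.crop_right) == (25, 25, 8, 8)
        np.testing.assert_array_equal(out, img[25:-25, 8:-8])

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            crop_borders(np.zeros((10, 10), dtype=np.uint8), 0.5, 0.0)
        with pytest.raises(ValueError):
            crop_borders(np.zeros((10, 10), dtype=np.uint8), 0.0, -0.1)


class TestOrientRight:
    def test_all_zero_tie_no_flip(self):
        out, _, flipped = orient_right(np.zeros((8, 8), dtype=np.uint8))
        assert not flipped

    def test_left_bright_unchanged(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        img[:, :5] = 200
        out, _, flipped = orient_right(img)
        assert not flipped
        np.testing.assert_array_equal(out, img)

    def test_right_bright_mirrors_image_and_companions(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        img[:, 5:] = 200
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[3, 7] = 1
        out, comps, flipped = orient_right(img, [mask])
        assert flipped
        np.testing.assert_array_equal(out, img[:, ::-1])
        # foreground column j maps to width-1-j
        assert comps[0][3, 10 - 1 - 7] == 1
        assert comps[0].sum() == 1

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="companion"):
            orient_right(np.zeros((4, 4), dtype=np.uint8), [np.zeros((5, 4), dtype=np.uint8)])


def _reference_clahe(img, clip_limit, tiles):
    """Independent naive CLAHE: explicit per-pixel loops over tile LUTs."""
    ty, tx = tiles
    h, w = img.shape
    th, tw = h // ty, w // tx
    n_pix = th * tw
    clip = max(1, int(clip_limit * n_pix / 256))
    luts = {}
    for i in range(ty):
        for j in range(tx):
            tile = img[i * th:(i + 1) * th, j * tw:(j + 1) * tw]
            hist = [0] * 256
            for v in tile.ravel():
                hist[int(v)] += 1
            excess = sum(max(c - clip, 0) for c in hist)
            hist = [min(c, clip) for c in hist]
            for k in range(256):
                hist[k] += excess // 256
            for k in range(excess % 256):
                hist[k] += 1
            cdf = 0
            lut = []
            for c in hist:
                cdf += c
                lut.append(int(round(cdf * 255.0 / n_pix)))
            luts[i, j] = lut
    out = np.zeros_like(img)
    for y in range(h):
        for x in range(w):
            fy = (y - (th - 1) / 2.0) / th
            fx = (x - (tw - 1) / 2.0) / tw
            y0 = min(max(int(np.floor(fy)), 0), ty - 1)
            x0 = min(max(int(np.floor(fx)), 0), tx - 1)
            y1 = min(y0 + 1, ty - 1)
            x1 = min(x0 + 1, tx - 1)
            wy = 0.0 if fy < 0 else (1.0 if fy > ty - 1 else fy - np.floor(fy))
            wx = 0.0 if fx < 0 else (1.0 if fx > tx - 1 else fx - np.floor(fx))
            v = int(img[y, x])
            val = ((1 - wy) * ((1 - wx) * luts[y0, x0][v] + wx * luts[y0, x1][v])
                   + wy * ((1 - wx) * luts[y1, x0][v] + wx * luts[y1, x1][v]))
            out[y, x] = int(round(val))
    return out


class TestClahe:
    def test_deterministic_and_in_range(self, rng):
        img = rng.integers(0, 255, size=(64, 48)).astype(np.uint8)
        a = clahe(img)
        b = clahe(img)
        np.testing.assert_array_equal(a, b)
        assert a.min() >= 0 and a.max() <= 255 and a.dtype == np.uint8

    def test_matches_independent_reference(self):
        # 16x16 two-tile step image, evenly divisible grid
        img = np.zeros((16, 16), dtype=np.uint8)
        img[:, 8:] = 180
        img[4:12, 2:6] = 90
        ours = clahe(img, clip_limit=2.0, tiles=(2, 2))
        ref = _reference_clahe(img, 2.0, (2, 2))
        np.testing.assert_array_equal(ours, ref)

    def test_matches_reference_random(self, rng):
        img = rng.integers(0, 256, size=(32, 32)).astype(np.uint8)
        np.testing.assert_array_equal(
            clahe(img, 3.0, (4, 4)), _reference_clahe(img, 3.0, (4, 4))
        )

    def test_rejects_bad_params(self):
        img = np.zeros((16, 16), dtype=np.uint8)
        with pytest.raises(ValueError):
            clahe(img, clip_limit=0.0)
        with pytest.raises(ValueError):
            clahe(img, tiles=(0, 8))

    def test_rejects_16bit(self):
        with pytest.raises(ValueError, match="8-bit"):
            clahe(np.full((16, 16), 3000, dtype=np.uint16))


class TestPadToSquare:
    def test_centered_padding(self, rng):
        img = rng.integers(1, 255, size=(100, 60)).astype(np.uint8)
        out, rec = pad_to_square(img)
        assert out.shape == (100, 100)
        assert rec.pad_left == 20 and rec.pad_top == 0
        assert (out[:, :20] == 0).all() and (out[:, 80:] == 0).all()
        np.testing.assert_array_equal(out[:, 20:80], img)

    def test_square_identity(self, rng):
        img = rng.integers(0, 255, size=(33, 33)).astype(np.uint8)
        out, rec = pad_to_square(img)
        np.testing.assert_array_equal(out, img)
        assert rec.pad_left == 0 and rec.pad_top == 0

    def test_odd_surplus_goes_right(self, rng):
        img = rng.integers(1, 255, size=(101, 100)).astype(np.uint8)
        out, rec = pad_to_square(img)
        assert out.shape == (101, 101)
        assert rec.pad_left == 0
        assert (out[:, -1] == 0).all()


class TestResize:
    def test_identity(self, rng):
        img = rng.integers(0, 255, size=(50, 50)).astype(np.uint8)
        out, rec = resize_to(img, 50)
        np.testing.assert_array_equal(out, img)
        assert rec.scale == 1.0

    def test_constant_stays_constant(self):
        img = np.full((64, 64), 77, dtype=np.uint8)
        out, _ = resize_to(img, 32)
        assert (out == 77).all()

    def test_mask_rebinarized(self, rng):
        mask = (rng.random((80, 80)) > 0.5).astype(np.uint8)
        out, rec = resize_to(mask, 32, is_mask=True)
        assert set(np.unique(out)) <= {0, 1}
        assert rec.scale == 32 / 80

    def test_non_square_raises(self):
        with pytest.raises(ValueError, match="square"):
            resize_to(np.zeros((10, 12), dtype=np.uint8), 8)


class TestNormalizeRange:
    def test_16bit_endpoints(self):
        img = np.array([[0, 65535], [1000, 30000]], dtype=np.uint16)
        out = normalize_range(img)
        assert out.dtype == np.uint8 and out[0, 0] == 0 and out[0, 1] == 255

    def test_constant_maps_to_zero(self):
        assert (normalize_range(np.full((5, 5), 42, dtype=np.uint16)) == 0).all()

    def test_two_value_linear_map(self):
        out = normalize_range(np.array([[100, 300]], dtype=np.uint16))
        np.testing.assert_array_equal(out, [[0, 255]])


class TestFullChain:
    def test_deterministic(self, small_case):
        a = preprocess_pair(small_case.image, small_case.per_mass_masks, out_side=320)
        b = preprocess_pair(small_case.image, small_case.per_mass_masks, out_side=320)
        np.testing.assert_array_equal(a[0], b[0])
        for ma, mb in zip(a[1], b[1]):
            np.testing.assert_array_equal(ma, mb)

    def test_single_pixel_mask_alignment(self, rng):
        """A one-pixel mask lands where the record maps its coordinate."""
        img = rng.integers(0, 255, size=(300, 220)).astype(np.uint8)
        img[:, :110] += 1  # keep left half brighter: no flip ambiguity
        mask = np.zeros_like(img, dtype=np.uint8)
        y0, x0 = 150, 120
        mask[y0, x0] = 1
        out_img, out_masks, rec = preprocess_pair(img, [mask], out_side=256)
        fg = np.argwhere(out_masks[0])
        assert len(fg) >= 1
        xm, ym = rec.apply_xy(x0, y0)
        # nearest-neighbour resize keeps the pixel within one output pixel
        dists = np.hypot(fg[:, 0] - ym, fg[:, 1] - xm)
        assert dists.min() <= max(1.0, 1.0 / rec.scale * rec.scale + 1)

    def test_record_roundtrip_within_one_pixel(self, small_case):
        _, _, rec = preprocess_pair(small_case.image, [], out_side=320)
        rng = np.random.default_rng(0)
        for _ in range(200):
            x = rng.uniform(rec.crop_left + 1, rec.raw_width - rec.crop_right - 2)
            y = rng.uniform(rec.crop_top + 1, rec.raw_height - rec.crop_bottom - 2)
            xf, yf = rec.apply_xy(x, y)
            xb, yb = rec.invert_xy(xf, yf)
            assert abs(xb - x) <= 1.0 and abs(yb - y) <= 1.0

    def test_invert_mask_restores_location(self, small_case):
        img, masks, rec = preprocess_pair(
            small_case.image, small_case.per_mass_masks, out_side=320
        )
        raw = invert_mask(masks[0], rec)
        assert raw.shape == small_case.image.shape
        truth = small_case.per_mass_masks[0]
        inter = np.logical_and(raw, truth).sum()
        union = np.logical_or(raw, truth).sum()
        assert inter / union > 0.7  # two resamplings blur the boundary a little
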