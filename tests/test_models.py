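"""Architecture family: accounting identities, forward contracts, Otsu."""

import numpy as np
import pytest

from mammoseg import nn
from mammoseg.models import (
    PRESETS,
    ArchitectureConfig,
    build_model,
    conv_schedule,
    count_macs,
    count_parameters,
    load_model,
    otsu_segment,
    otsu_threshold,
    save_model,
)


class TestConfig:
    @pytest.mark.parametrize(
        "name,depth,dsc,w",
        [
            ("segnet3", 3, False, 1.0),
            ("segnet4", 4, False, 1.0),
            ("segdsc3", 3, True, 1.0),
            ("segdsc4", 4, True, 1.0),
            ("segdsc4_85", 4, True, 0.15),
            ("segdsc4_90", 4, True, 0.10),
            ("segdsc4_95", 4, True, 0.05),
        ],
    )
    def test_presets(self, name, depth, dsc, w):
        cfg = PRESETS[name]
        assert (cfg.depth, cfg.use_dsc, cfg.width_multiplier) == (depth, dsc, w)

    def test_width_rounding_half_up_min_one(self):
        cfg = ArchitectureConfig(depth=4, use_dsc=True, width_multiplier=0.10)
        assert cfg.filters == (6, 13, 26, 51)
        tiny = ArchitectureConfig(depth=3, use_dsc=True, width_multiplier=0.01)
        assert tiny.filters[0] == 1

    def test_invalid(self):
        with pytest.raises(ValueError):
            ArchitectureConfig(depth=5)
        with pytest.raises(ValueError):
            ArchitectureConfig(width_multiplier=0.0)


class TestParameterAccounting:
    def test_analytic_equals_enumeration_for_presets(self):
        for name, cfg in PRESETS.items():
            count_parameters(cfg, enumerate_network=True)  # raises on mismatch

    def test_analytic_equals_enumeration_random_configs(self, rng):
        for _ in range(50):
            cfg = ArchitectureConfig(
                depth=int(rng.choice([3, 4])),
                use_dsc=bool(rng.random() < 0.5),
                width_multiplier=float(rng.uniform(0.05, 1.0)),
            )
            count_parameters(cfg, enumerate_network=True)

    def test_single_conv_unit_hand_count(self):
        """A standard 3x3 conv 1->4 plus affine norm holds 9*1*4 + 2*4 = 44."""
        g = np.random.default_rng(0)
        layers = [nn.Conv3x3(1, 4, g), nn.BatchNorm2d(4)]
        total = sum(p.value.size for layer in layers for p in layer.parameters())
        assert total == 44

    def test_width_doubling_scaling_law(self):
        """Doubling w scales the pointwise term ~4x and the depthwise ~2x."""
        def terms(w):
            cfg = ArchitectureConfig(depth=4, use_dsc=True, width_multiplier=w)
            dw = sum(9 * cin for cin, _, _ in conv_schedule(cfg))
            pw = sum(cin * cout for cin, cout, _ in conv_schedule(cfg))
            return dw, pw

        dw1, pw1 = terms(0.05)
        dw2, pw2 = terms(0.10)
        assert 3.5 <= pw2 / pw1 <= 4.5
        assert 1.8 <= dw2 / dw1 <= 2.2

    def test_dsc_to_standard_ratio_near_12_percent(self):
        for d in (3, 4):
            std = count_parameters(
                ArchitectureConfig(depth=d, use_dsc=False), enumerate_network=False
            ).trainable_params
            dsc = count_parameters(
                ArchitectureConfig(depth=d, use_dsc=True), enumerate_network=False
            ).trainable_params
            assert 0.11 <= dsc / std <= 0.125

    def test_serialized_size_tracks_parameter_count(self, tmp_path):
        net = build_model("segnet3", seed=0)
        path = tmp_path / "m.npz"
        save_model(net, path)
        params = count_parameters(PRESETS["segnet3"], enumerate_network=False).trainable_params
        assert abs(path.stat().st_size - 4 * params) / (4 * params) < 0.01


class TestMacAccounting:
    def test_hand_formula_single_conv(self):
        # one 3x3 conv 1->1 on a 4x4 input with padding 1: 9 * 16 = 144 MACs
        assert 4 * 4 * 9 * 1 * 1 == 144

    def test_matches_independent_schedule_sum(self):
        for name, cfg in PRESETS.items():
            total = 0
            for cin, cout, level in conv_schedule(cfg):
                hw = (128 // 2**level) ** 2
                total += hw * (9 * cin + cin * cout) if cfg.use_dsc else hw * 9 * cin * cout
            assert count_macs(cfg, 128).macs == total

    def test_halving_side_quarters_macs(self):
        for name in ("segnet3", "segdsc4_90"):
            cfg = PRESETS[name]
            assert count_macs(cfg, 128).macs == 4 * count_macs(cfg, 64).macs

    def test_indivisible_side_raises(self):
        with pytest.raises(ValueError, match="divisible"):
            count_macs(PRESETS["segnet4"], 120)


class TestNetworkForward:
    def test_output_shape_and_range(self):
        net = build_model("segdsc4_90", seed=0)
        x = np.random.default_rng(0).random((1, 1, 128, 128)).astype(np.float32)
        p = net.forward(x)
        assert p.shape == (1, 1, 128, 128)
        assert 0.0 < p.min() and p.max() < 1.0

    @pytest.mark.parametrize("side", [32, 64, 96])
    def test_output_matches_input_side(self, side):
        cfg = ArchitectureConfig(depth=3, use_dsc=True, width_multiplier=0.05)
        net = build_model(cfg, seed=0)
        x = np.zeros((1, 1, side, side), dtype=np.float32)
        assert net.forward(x).shape == (1, 1, side, side)

    def test_indivisible_input_raises(self):
        net = build_model("segdsc4_95", seed=0)
        with pytest.raises(ValueError, match="divisible"):
            net.forward(np.zeros((1, 1, 127, 127), dtype=np.float32))

    def test_unpool_restores_argmax_positions(self, rng):
        x = rng.random((2, 3, 8, 8)).astype(np.float32)
        pool = nn.MaxPool2x2()
        unpool = nn.MaxUnpool2x2()
        y, idx = pool.forward(x, training=False)
        up = unpool.forward(y, idx, training=False)
        # nonzero entries sit exactly at the per-window argmax, holding the max
        for n in range(2):
            for c in range(3):
                for i in range(4):
                    for j in range(4):
                        win = x[n, c, 2 * i : 2 * i + 2, 2 * j : 2 * j + 2]
                        uwin = up[n, c, 2 * i : 2 * i + 2, 2 * j : 2 * j + 2]
                        k = win.argmax()
                        expected = np.zeros(4, dtype=np.float32)
                        expected[k] = win.ravel()[k]
                        np.testing.assert_array_equal(uwin.ravel(), expected)

    def test_save_load_roundtrip(self, tmp_path):
        net = build_model("segdsc4_95", seed=3)
        x = np.random.default_rng(1).random((1, 1, 32, 32)).astype(np.float32)
        p1 = net.forward(x)
        save_model(net, tmp_path / "net.npz")
        net2 = load_model(tmp_path / "net.npz")
        np.testing.assert_allclose(net2.forward(x), p1, rtol=1e-6)


def _brute_force_otsu(img):
    """Scan all 256 thresholds for max between-class variance (smallest wins)."""
    pix = img.ravel().astype(float)
    best_t, best_v = 0, -1.0
    for t in range(256):
        lo = pix[pix <= t]
        hi = pix[pix > t]
        if len(lo) == 0 or len(hi) == 0:
            v = 0.0
        else:
            w0, w1 = len(lo) / len(pix), len(hi) / len(pix)
            v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


class TestOtsu:
    def test_two_valued_image(self):
        img = np.concatenate([np.full(60, 50), np.full(40, 200)]).reshape(10, 10).astype(np.uint8)
        mask = otsu_segment(img)
        assert mask.sum() == 40
        assert (img[mask.astype(bool)] == 200).all()
        assert otsu_threshold(img) == 50  # smallest maximising threshold

    def test_constant_image_empty_mask(self):
        assert otsu_segment(np.full((8, 8), 123, dtype=np.uint8)).sum() == 0

    def test_matches_brute_force_scan(self, rng):
        for _ in range(1000):
            img = rng.integers(0, 256, size=(8, 8)).astype(np.uint8)
            assert otsu_threshold(img) == _brute_force_otsu(img)

    def test_agrees_with_skimage_on_bimodal(self, rng):
        from skimage.filters import threshold_otsu

        img = np.concatenate(
            [rng.normal(60, 8, 600), rng.normal(190, 8, 400)]
        ).clip(0, 255).astype(np.uint8).reshape(25, 40)
        ours = otsu_threshold(img)
        ref = threshold_otsu(img, nbins=256)
        assert abs(int(ours) - int(ref)) <= 1
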