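"""Overlap metrics against pixel-enumeration oracles; AP against brute force."""

import numpy as np
import pytest

from mammoseg.annotations import BBox
from mammoseg.metrics import (
    Detection,
    average_precision,
    box_iou,
    dice,
    dice_loss,
    giou,
    mask_iou,
    mean_average_precision,
)


def _pixels(box: BBox) -> set:
    return {(x, y) for x in range(box.xmin, box.xmax + 1) for y in range(box.ymin, box.ymax + 1)}


def _random_box(rng, lo=0, hi=12) -> BBox:
    x1, x2 = sorted(rng.integers(lo, hi, size=2).tolist())
    y1, y2 = sorted(rng.integers(lo, hi, size=2).tolist())
    return BBox(int(x1), int(y1), int(x2), int(y2))


class TestBoxIoU:
    def test_identical(self):
        b = BBox(2, 3, 10, 12)
        assert box_iou(b, b) == 1.0

    def test_disjoint(self):
        assert box_iou(BBox(0, 0, 1, 1), BBox(5, 5, 6, 6)) == 0.0

    def test_corner_touch_pixel_counts(self):
        # 2x2 boxes sharing the single pixel (1,1): inter 1, union 7
        assert box_iou(BBox(0, 0, 1, 1), BBox(1, 1, 2, 2)) == pytest.approx(1 / 7)

    def test_matches_pixel_enumeration(self, rng):
        for _ in range(1000):
            a, b = _random_box(rng), _random_box(rng)
            pa, pb = _pixels(a), _pixels(b)
            expected = len(pa & pb) / len(pa | pb)
            assert box_iou(a, b) == pytest.approx(expected)

    def test_symmetric(self, rng):
        for _ in range(100):
            a, b = _random_box(rng), _random_box(rng)
            assert box_iou(a, b) == box_iou(b, a)


class TestGIoU:
    def test_identical(self):
        b = BBox(0, 0, 4, 4)
        assert giou(b, b) == 1.0

    def test_nested(self):
        assert giou(BBox(0, 0, 1, 1), BBox(0, 0, 2, 2)) == pytest.approx(4 / 9)

    def test_far_apart_unit_pixels(self):
        assert giou(BBox(0, 0, 0, 0), BBox(9, 9, 9, 9)) == pytest.approx(-0.98)

    def test_matches_pixel_enumeration(self, rng):
        for _ in range(1000):
            a, b = _random_box(rng), _random_box(rng)
            pa, pb = _pixels(a), _pixels(b)
            hull = BBox(
                min(a.xmin, b.xmin), min(a.ymin, b.ymin),
                max(a.xmax, b.xmax), max(a.ymax, b.ymax),
            )
            ph = _pixels(hull)
            expected = len(pa & pb) / len(pa | pb) - len(ph - (pa | pb)) / len(ph)
            assert giou(a, b) == pytest.approx(expected)

    def test_never_exceeds_iou(self, rng):
        for _ in range(300):
            a, b = _random_box(rng), _random_box(rng)
            assert giou(a, b) <= box_iou(a, b) + 1e-12


class TestDice:
    def test_perfect_overlap(self, rng):
        m = (rng.random((20, 20)) > 0.5).astype(np.uint8)
        m[0, 0] = 1
        assert dice(m, m) == 1.0
        assert dice_loss(m.astype(float), m) < 0.01

    def test_disjoint(self):
        a = np.zeros((10, 10), dtype=np.uint8)
        b = np.zeros_like(a)
        a[:2, :2] = 1
        b[5:7, 5:7] = 1
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((5, 5), dtype=np.uint8)
        b = np.zeros_like(a)
        a[0, 0:2] = 1
        b[0, 1:3] = 1
        assert dice(a, b) == 0.5

    def test_empty_conventions(self):
        e = np.zeros((4, 4), dtype=np.uint8)
        f = e.copy()
        f[0, 0] = 1
        assert dice(e, e) == 1.0 and mask_iou(e, e) == 1.0
        assert dice(e, f) == 0.0 and mask_iou(e, f) == 0.0

    def test_identity_with_iou(self, rng):
        """Dice = 2 IoU / (1 + IoU) exactly, for any binary mask pair."""
        for _ in range(300):
            a = (rng.random((12, 12)) > 0.6).astype(np.uint8)
            b = (rng.random((12, 12)) > 0.6).astype(np.uint8)
            i = mask_iou(a, b)
            assert dice(a, b) == pytest.approx(2 * i / (1 + i))

    def test_loss_monotone_toward_target(self, rng):
        y = (rng.random((16, 16)) > 0.5).astype(float)
        p0 = rng.random((16, 16))
        losses = [dice_loss(p0 + t * (y - p0), y) for t in np.linspace(0, 1, 11)]
        assert all(l1 >= l2 - 1e-12 for l1, l2 in zip(losses, losses[1:]))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice(np.zeros((3, 3), dtype=np.uint8), np.zeros((4, 3), dtype=np.uint8))


# ---------------------------------------------------------------------------
# average precision


def _brute_force_ap(detections, truths, thr):
    """Reference AP: explicit greedy matching + exact envelope integration."""
    flat = []
    for i, dets in enumerate(detections):
        for d in dets:
            flat.append((d.confidence, i, d.box))
    # stable sort by descending confidence
    flat = sorted(enumerate(flat), key=lambda kv: (-kv[1][0], kv[0]))
    n_truth = sum(len(t) for t in truths)
    used = [[False] * len(t) for t in truths]
    points = []
    tp = fp = 0
    for _, (conf, i, box) in flat:
        best, bj = 0.0, -1
        for j, gt in enumerate(truths[i]):
            if used[i][j]:
                continue
            v = box_iou(box, gt)
            if v > best:
                best, bj = v, j
        if bj >= 0 and best >= thr:
            used[i][bj] = True
            tp += 1
        else:
            fp += 1
        points.append((tp / n_truth, tp / (tp + fp)))
    # precision envelope, integrated over recall jumps
    ap = 0.0
    prev_r = 0.0
    for k, (r, _) in enumerate(points):
        if r > prev_r:
            env = max(p for rr, p in points[k:] if rr >= r)
            ap += (r - prev_r) * env
            prev_r = r
    return ap


class TestAveragePrecision:
    def test_perfect_detector(self):
        truths = [[BBox(0, 0, 9, 9)], [BBox(5, 5, 14, 14), BBox(30, 30, 39, 39)]]
        dets = [[Detection(t, 0.9) for t in ts] for ts in truths]
        assert average_precision(dets, truths, 0.5) == 1.0

    def test_high_conf_miss_then_exact_hit(self):
        truths = [[BBox(10, 10, 19, 19)]]
        dets = [[Detection(BBox(50, 50, 59, 59), 0.9), Detection(BBox(10, 10, 19, 19), 0.6)]]
        assert average_precision(dets, truths, 0.5) == pytest.approx(0.5)

    def test_no_ground_truth_raises(self):
        with pytest.raises(ValueError, match="recall"):
            average_precision([[Detection(BBox(0, 0, 1, 1), 0.5)]], [[]], 0.5)

    def test_matches_brute_force_on_small_cases(self, rng):
        for _ in range(300):
            n_img = int(rng.integers(1, 3))
            truths, dets = [], []
            total_t = 0
            for _i in range(n_img):
                nt = int(rng.integers(0, 3))
                nd = int(rng.integers(0, 3))
                truths.append([_random_box(rng) for _ in range(nt)])
                total_t += nt
                dets.append(
                    [Detection(_random_box(rng), float(np.round(rng.random(), 3)))
                     for _ in range(nd)]
                )
            if total_t == 0:
                continue
            for thr in (0.3, 0.5, 0.75):
                assert average_precision(dets, truths, thr) == pytest.approx(
                    _brute_force_ap(dets, truths, thr)
                )

    def test_map_is_mean_over_thresholds(self):
        truths = [[BBox(0, 0, 9, 9)]]
        dets = [[Detection(BBox(0, 0, 8, 9), 0.8)]]  # IoU = 90/100 = 0.9
        res = mean_average_precision(dets, truths)
        assert res.map50 == 1.0
        assert res.ap_per_threshold[0.95] == 0.0
        assert res.map50_95 == pytest.approx(np.mean(list(res.ap_per_threshold.values())))
        assert len(res.ap_per_threshold) == 10
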