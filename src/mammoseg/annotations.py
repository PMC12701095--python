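"""Mass annotations: tight boxes, YOLO labels and 128x128 ROI extraction.

Datasets store one binary mask per mass, several per mammogram.  Bounding
boxes are derived per-mass *before* the masks are merged, so two overlapping
masses still yield two boxes.  Boxes use an inclusive pixel convention:
``(xmin, ymin, xmax, ymax)`` are the extreme foreground indices and the pixel
width is ``xmax - xmin + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .preprocess import TransformRecord, _check_mask, pad_to_square, resize_to

__all__ = [
    "BBox",
    "YoloLabel",
    "mask_to_bbox",
    "combine_masks",
    "bbox_to_yolo",
    "yolo_to_bbox",
    "extract_roi",
    "write_yolo_labels",
    "read_yolo_labels",
]


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box, 0-based, inclusive of the extreme foreground pixels."""

    xmin: int
    ymin: int
    xmax: int
    ymax: int

    def __post_init__(self) -> None:
        if self.xmin > self.xmax or self.ymin > self.ymax:
            raise ValueError(f"degenerate box {self}")

    @property
    def width(self) -> int:
        return self.xmax - self.xmin + 1

    @property
    def height(self) -> int:
        return self.ymax - self.ymin + 1

    @property
    def area(self) -> int:
        return self.width * self.height

    def within(self, width: int, height: int) -> bool:
        return 0 <= self.xmin and 0 <= self.ymin and self.xmax < width and self.ymax < height


@dataclass(frozen=True)
class YoloLabel:
    """One YOLO-format label line: class id plus normalised centre/size."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (0 < self.w <= 1 and 0 < self.h <= 1):
            raise ValueError("normalised box size must lie in (0, 1]")
        if not (0 <= self.cx <= 1 and 0 <= self.cy <= 1):
            raise ValueError("normalised box centre must lie in [0, 1]")


def mask_to_bbox(mask: np.ndarray) -> BBox:
    """Tight inclusive box over the foreground of a binary mask."""
    mask = _check_mask(mask)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("mask has no foreground pixels (corrupt annotation?)")
    return BBox(int(cols[0]), int(rows[0]), int(cols[-1]), int(rows[-1]))


def combine_masks(masks: Sequence[np.ndarray]) -> np.ndarray:
    """Pixelwise OR of the per-mass masks of one mammogram."""
    if len(masks) == 0:
        raise ValueError("need at least one mask")
    out = _check_mask(masks[0]).copy()
    for k, m in enumerate(masks[1:], start=1):
        m = _check_mask(m, f"mask {k}")
        if m.shape != out.shape:
            raise ValueError(f"mask {k} shape {m.shape} differs from {out.shape}")
        out |= m
    return out


def bbox_to_yolo(box: BBox, width: int, height: int, class_id: int = 0) -> YoloLabel:
    """Convert an inclusive pixel box to a normalised YOLO label."""
    if not box.within(width, height):
        raise ValueError(f"box {box} exceeds image bounds {width}x{height}")
    return YoloLabel(
        class_id=class_id,
        cx=(box.xmin + box.width / 2.0) / width,
        cy=(box.ymin + box.height / 2.0) / height,
        w=box.width / width,
        h=box.height / height,
    )


def yolo_to_bbox(label: YoloLabel, width: int, height: int) -> BBox:
    """Inverse of :func:`bbox_to_yolo`; exact round-trip for integer boxes."""
    bw = int(round(label.w * width))
    bh = int(round(label.h * height))
    xmin = int(round(label.cx * width - label.w * width / 2.0))
    ymin = int(round(label.cy * height - label.h * height / 2.0))
    bw, bh = max(bw, 1), max(bh, 1)
    xmin = min(max(xmin, 0), width - bw)
    ymin = min(max(ymin, 0), height - bh)
    return BBox(xmin, ymin, xmin + bw - 1, ymin + bh - 1)


def extract_roi(
    image: np.ndarray,
    mask: np.ndarray,
    box: BBox,
    out_side: int = 128,
    margin: int = 0,
) -> tuple[np.ndarray, np.ndarray, TransformRecord]:
    """Cut the box out of image and mask, pad to square, resize to ``out_side``.

    With the default zero margin the crop is exactly the box, so an ROI built
    from a tight mask box has foreground touching the non-padded borders.  The
    returned record maps frame coordinates to ROI coordinates (and back).
    """
    image = np.asarray(image)
    mask = _check_mask(mask)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    h, w = image.shape
    if margin < 0:
        raise ValueError("margin must be >= 0")
    xmin = max(box.xmin - margin, 0)
    ymin = max(box.ymin - margin, 0)
    xmax = min(box.xmax + margin, w - 1)
    ymax = min(box.ymax + margin, h - 1)
    if not box.within(w, h):
        raise ValueError(f"box {box} exceeds image bounds {w}x{h}")
    crop_img = image[ymin : ymax + 1, xmin : xmax + 1]
    crop_mask = mask[ymin : ymax + 1, xmin : xmax + 1]
    sq_img, rec_pad = pad_to_square(crop_img, fill=0)
    sq_mask, _ = pad_to_square(crop_mask, fill=0)
    roi_img, rec_resize = resize_to(sq_img, out_side, is_mask=False)
    roi_mask, _ = resize_to(sq_mask, out_side, is_mask=True)
    record = TransformRecord(
        crop_top=ymin,
        crop_bottom=h - 1 - ymax,
        crop_left=xmin,
        crop_right=w - 1 - xmax,
        pad_left=rec_pad.pad_left,
        pad_top=rec_pad.pad_top,
        scale=rec_resize.scale,
        raw_height=h,
        raw_width=w,
    )
    return roi_img, roi_mask, record


# ---------------------------------------------------------------------------
# YOLO label files: one "class cx cy w h" line per box, 6-decimal fixed point


def write_yolo_labels(path: str | Path, labels: Sequence[YoloLabel]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [
        f"{lab.class_id} {lab.cx:.6f} {lab.cy:.6f} {lab.w:.6f} {lab.h:.6f}\n" for lab in labels
    ]
    path.write_text("".join(lines))


def read_yolo_labels(path: str | Path) -> list[YoloLabel]:
    labels = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) not in (5, 6):
            raise ValueError(f"{path}:{ln}: expected 5 or 6 fields, got {len(parts)}")
        labels.append(
            YoloLabel(int(parts[0]), float(parts[1]), float(parts[2]), float(parts[3]), float(parts[4]))
        )
    return labels


def build_annotations(
    data_dir: str | Path,
    out_dir: str | Path | None = None,
    roi_side: int = 128,
    margin: int = 0,
) -> dict[str, int]:
    """Derive labels, combined masks and ROI pairs for a preprocessed dataset.

    Reads ``images/<id>.png`` and per-mass ``masks/<id>_<k>.png`` from
    ``data_dir``; writes ``labels/<id>.txt``, ``masks_combined/<id>.png`` and
    ROI pairs ``rois/images/<id>_<k>.png`` / ``rois/masks/<id>_<k>.png``.
    Returns per-case mass counts.
    """
    from .preprocess import read_gray_png, write_gray_png

    data_dir = Path(data_dir)
    out_dir = Path(out_dir) if out_dir is not None else data_dir
    counts: dict[str, int] = {}
    for ipath in sorted((data_dir / "images").glob("*.png")):
        cid = ipath.stem
        image = read_gray_png(ipath)
        h, w = image.shape
        mask_paths = sorted((data_dir / "masks").glob(f"{cid}_*.png"))
        masks = [(read_gray_png(p) > 0).astype(np.uint8) for p in mask_paths]
        masks = [m for m in masks if m.any()]
        labels = []
        for k, m in enumerate(masks):
            box = mask_to_bbox(m)
            labels.append(bbox_to_yolo(box, w, h))
            roi_img, roi_mask, _ = extract_roi(image, m, box, out_side=roi_side, margin=margin)
            write_gray_png(out_dir / "rois" / "images" / f"{cid}_{k}.png", roi_img)
            write_gray_png(out_dir / "rois" / "masks" / f"{cid}_{k}.png", roi_mask * 255)
        write_yolo_labels(out_dir / "labels" / f"{cid}.txt", labels)
        if masks:
            write_gray_png(out_dir / "masks_combined" / f"{cid}.png", combine_masks(masks) * 255)
        counts[cid] = len(masks)
    return counts
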