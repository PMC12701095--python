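"""Two-stage detect-then-segment inference and dataset evaluation.

The detection stage is a pluggable interface, never a bundled network: any
provider that returns confidence-scored boxes in the canonical 640x640 frame
plugs in.  Three implementations ship:

* :class:`LabelFileDetector` — reads YOLO-format prediction files (with an
  optional sixth confidence column) from a directory;
* :class:`CommandDetector` — runs an external command that writes YOLO-format
  text for a given image;
* :class:`MaskOracleDetector` — derives boxes from ground-truth masks, for
  testing the segmentation stage in isolation.

For each accepted detection the ROI is cut from the canonical image, run
through the segmentation model, thresholded at 0.5, mapped back through the
ROI and preprocessing transforms, and OR-ed into one full-resolution mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Protocol, Sequence

import numpy as np

from .annotations import (
    BBox,
    combine_masks,
    extract_roi,
    mask_to_bbox,
    read_yolo_labels,
    yolo_to_bbox,
)
from .metrics import Detection, dice, mask_iou, mean_average_precision
from .preprocess import TransformRecord, invert_mask, read_gray_png, resize_to

__all__ = [
    "DetectorInterface",
    "LabelFileDetector",
    "CommandDetector",
    "MaskOracleDetector",
    "segment_mammogram",
    "run_evaluation",
]


class DetectorInterface(Protocol):
    """Provider contract for the detection stage."""

    def detect(self, case_id: str, image: np.ndarray) -> list[Detection]:
        """Return confidence-scored boxes within the image frame."""
        ...


class LabelFileDetector:
    """Reads YOLO-format predictions ``<labels_dir>/<id>.txt``.

    Lines are ``class cx cy w h [confidence]``; a missing confidence column
    defaults to 1.0.  A missing file means no detections.
    """

    def __init__(self, labels_dir: str | Path, default_confidence: float = 1.0) -> None:
        self.labels_dir = Path(labels_dir)
        self.default_confidence = default_confidence

    def detect(self, case_id: str, image: np.ndarray) -> list[Detection]:
        path = self.labels_dir / f"{case_id}.txt"
        if not path.exists():
            return []
        h, w = image.shape
        dets = []
        for ln, line in enumerate(path.read_text().splitlines(), start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) not in (5, 6):
                raise ValueError(f"{path}:{ln}: expected 5 or 6 fields")
            cx, cy, bw, bh = (float(v) for v in parts[1:5])
            conf = float(parts[5]) if len(parts) == 6 else self.default_confidence
            from .annotations import YoloLabel

            box = yolo_to_bbox(YoloLabel(int(parts[0]), cx, cy, bw, bh), w, h)
            dets.append(Detection(box=box, confidence=conf))
        return dets


class CommandDetector:
    """Adapter for an external detector command.

    The command template receives ``{image}`` and ``{output}`` placeholders;
    it must write YOLO-format text (``class cx cy w h [conf]``) to the output
    path for the given image file.
    """

    def __init__(self, command_template: str, workdir: str | Path | None = None) -> None:
        self.command_template = command_template
        self.workdir = Path(workdir) if workdir else None

    def detect(self, case_id: str, image: np.ndarray) -> list[Detection]:
        import subprocess
        import tempfile

        from .preprocess import write_gray_png

        with tempfile.TemporaryDirectory() as tmp:
            img_path = Path(tmp) / f"{case_id}.png"
            out_path = Path(tmp) / f"{case_id}.txt"
            write_gray_png(img_path, image)
            cmd = self.command_template.format(image=img_path, output=out_path)
            res = subprocess.run(cmd, shell=True, cwd=self.workdir, capture_output=True, text=True)
            if res.returncode != 0:
                raise RuntimeError(f"detector command failed on {case_id}: {res.stderr.strip()}")
            if not out_path.exists():
                return []
            return LabelFileDetector(Path(tmp)).detect(case_id, image)


class MaskOracleDetector:
    """Derives perfect boxes from ground-truth per-mass masks (for testing)."""

    def __init__(self, masks_by_case: dict[str, Sequence[np.ndarray]] | None = None,
                 masks_dir: str | Path | None = None) -> None:
        if (masks_by_case is None) == (masks_dir is None):
            raise ValueError("provide exactly one of masks_by_case or masks_dir")
        self.masks_by_case = masks_by_case
        self.masks_dir = Path(masks_dir) if masks_dir else None

    def _masks(self, case_id: str) -> list[np.ndarray]:
        if self.masks_by_case is not None:
            return [np.asarray(m) for m in self.masks_by_case.get(case_id, [])]
        paths = sorted(self.masks_dir.glob(f"{case_id}_*.png"))
        return [(read_gray_png(p) > 0).astype(np.uint8) for p in paths]

    def detect(self, case_id: str, image: np.ndarray) -> list[Detection]:
        dets = []
        for m in self._masks(case_id):
            if m.any():
                dets.append(Detection(box=mask_to_bbox(m), confidence=1.0))
        return dets


# ---------------------------------------------------------------------------
# inference


def _roi_mask_to_frame(roi_mask: np.ndarray, record: TransformRecord) -> np.ndarray:
    """Place a predicted ROI mask back into the full canonical frame."""
    return invert_mask(roi_mask, record)


def segment_mammogram(
    image: np.ndarray,
    detections: Sequence[Detection],
    model: Callable[[np.ndarray], np.ndarray],
    record: TransformRecord | None = None,
    roi_side: int = 128,
    confidence_threshold: float = 0.25,
    prob_threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the segmentation stage over every accepted detection.

    ``model`` maps a ``roi_side`` square 8-bit ROI to a probability map (or a
    binary mask) of the same shape; estimators with ``predict_proba`` are
    accepted directly.  Per detection the ROI is cut with zero margin,
    segmented, thresholded, and mapped back; the per-mass masks are OR-ed.
    With ``record`` given, the mask is further inverted to raw coordinates.

    Returns ``(mask, overlay)`` where overlay is an RGB rendering of the
    boxes and mask contour on the input image.  An empty detection list
    yields an all-zero mask.
    """
    image = np.asarray(image)
    h, w = image.shape
    frame_mask = np.zeros((h, w), dtype=np.uint8)
    predict = model
    if hasattr(model, "predict_proba"):
        predict = lambda roi: model.predict_proba(roi[None])[0]  # noqa: E731
    for det in detections:
        if det.confidence < confidence_threshold:
            continue
        if not det.box.within(w, h):
            raise ValueError(f"detection box {det.box} outside the {w}x{h} frame")
        roi_img, _roi_mask, roi_rec = extract_roi(
            image, np.zeros_like(image, dtype=np.uint8), det.box, out_side=roi_side
        )
        prob = np.asarray(predict(roi_img), dtype=np.float64)
        if prob.shape != (roi_side, roi_side):
            raise ValueError(f"model output shape {prob.shape} != ({roi_side}, {roi_side})")
        roi_pred = (prob >= prob_threshold).astype(np.uint8)
        frame_mask |= _roi_mask_to_frame(roi_pred, roi_rec)
    overlay = render_overlay(image, detections, frame_mask, confidence_threshold)
    if record is not None:
        frame_mask = invert_mask(frame_mask, record)
    return frame_mask, overlay


def render_overlay(
    image: np.ndarray,
    detections: Sequence[Detection],
    mask: np.ndarray,
    confidence_threshold: float = 0.0,
) -> np.ndarray:
    """Burn boxes (green) and the mask contour (red) into an RGB image."""
    img = np.asarray(image, dtype=np.float64)
    if img.max(initial=0.0) > 255:
        img = img / img.max() * 255.0
    rgb = np.stack([img, img, img], axis=-1).astype(np.uint8)
    for det in detections:
        if det.confidence < confidence_threshold:
            continue
        b = det.box
        rgb[b.ymin, b.xmin : b.xmax + 1] = (0, 255, 0)
        rgb[b.ymax, b.xmin : b.xmax + 1] = (0, 255, 0)
        rgb[b.ymin : b.ymax + 1, b.xmin] = (0, 255, 0)
        rgb[b.ymin : b.ymax + 1, b.xmax] = (0, 255, 0)
    m = mask.astype(bool)
    interior = (
        np.roll(m, 1, 0) & np.roll(m, -1, 0) & np.roll(m, 1, 1) & np.roll(m, -1, 1)
    )
    contour = m & ~interior
    rgb[contour] = (255, 0, 0)
    return rgb


# ---------------------------------------------------------------------------
# evaluation


def run_evaluation(
    dataset_dir: str | Path,
    model: Callable[[np.ndarray], np.ndarray] | None,
    detector: DetectorInterface | None = None,
    roi_side: int = 128,
    include_otsu: bool = False,
    out_dir: str | Path | None = None,
) -> dict:
    """Evaluate segmentation (and optionally detection) on a preprocessed set.

    Expects the canonical layout with ``rois/images`` and ``rois/masks`` (from
    :func:`mammoseg.annotations.build_annotations`); per-ROI IoU and Dice are
    averaged over the set.  With a detector and ``labels/`` ground truth,
    mAP@50 and mAP@50:95 are added.  Missing masks are listed, not fatal.
    Writes ``report.json`` and ``report.csv`` when ``out_dir`` is given.
    """
    from .models import otsu_segment

    dataset_dir = Path(dataset_dir)
    roi_imgs = sorted((dataset_dir / "rois" / "images").glob("*.png"))
    if not roi_imgs:
        raise ValueError(f"no ROI images under {dataset_dir}")
    predict = model
    if model is not None and hasattr(model, "predict_proba"):
        predict = lambda roi: model.predict_proba(roi[None])[0]  # noqa: E731

    per_roi = []
    missing = []
    for ipath in roi_imgs:
        mpath = dataset_dir / "rois" / "masks" / ipath.name
        if not mpath.exists():
            missing.append(ipath.name)
            continue
        roi = read_gray_png(ipath)
        truth = (read_gray_png(mpath) > 0).astype(np.uint8)
        row = {"roi": ipath.stem}
        if predict is not None:
            prob = np.asarray(predict(roi), dtype=np.float64)
            pred = (prob >= 0.5).astype(np.uint8)
            row["iou"] = mask_iou(pred, truth)
            row["dice"] = dice(pred, truth)
        if include_otsu:
            om = otsu_segment(roi)
            row["otsu_iou"] = mask_iou(om, truth)
            row["otsu_dice"] = dice(om, truth)
        per_roi.append(row)
    if not per_roi:
        raise ValueError("dataset contains no evaluable ROI pairs")

    report: dict = {"n_rois": len(per_roi), "missing_masks": missing}
    for key in ("iou", "dice", "otsu_iou", "otsu_dice"):
        vals = [r[key] for r in per_roi if key in r]
        if vals:
            report[f"mean_{key}"] = float(np.mean(vals))

    if detector is not None:
        label_files = sorted((dataset_dir / "labels").glob("*.txt"))
        detections, truths = [], []
        for lpath in label_files:
            cid = lpath.stem
            img_path = dataset_dir / "images" / f"{cid}.png"
            image = read_gray_png(img_path) if img_path.exists() else np.zeros((640, 640))
            h, w = image.shape
            truths.append([yolo_to_bbox(lab, w, h) for lab in read_yolo_labels(lpath)])
            detections.append(detector.detect(cid, image))
        if any(truths):
            result = mean_average_precision(detections, truths)
            report["map50"] = result.map50
            report["map50_95"] = result.map50_95

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2))
        import csv as _csv

        keys = sorted({k for r in per_roi for k in r})
        with open(out_dir / "report.csv", "w", newline="") as fh:
            writer = _csv.DictWriter(fh, fieldnames=keys)
            writer.writeheader()
            writer.writerows(per_roi)
    return report
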