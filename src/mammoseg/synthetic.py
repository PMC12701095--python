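"""Seeded synthetic mammogram phantoms with exact ground truth.

Each case emulates the structural features a screening mammogram export
presents to the pipeline: a dark background, a bright half-elliptical breast
region anchored at the left or right edge with a radial intensity falloff,
optional bright scanner-border rows/columns and a corner identification tag,
and one to three soft-edged elliptical masses, each with its own exact binary
mask.  Intensities (8-bit scale) are drawn per case as

* background level ~ N(10, 3),
* breast tissue level ~ N(90, 10), modulated by the radial falloff,
* mass peak elevation ~ N(180, 10) with a Gaussian edge profile; the mass
  mask is the set of pixels whose elevation exceeds half the peak,

plus additive Gaussian pixel noise.  Every case derives its RNG stream from
``(dataset seed, case index)``, so cases are independently reproducible and
byte-identical across runs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .annotations import bbox_to_yolo, mask_to_bbox, write_yolo_labels
from .preprocess import write_gray_png

__all__ = ["SyntheticCase", "generate_case", "generate_dataset", "generate_roi_dataset"]


@dataclass
class SyntheticCase:
    """One generated mammogram-like image plus its exact annotations."""

    image: np.ndarray
    per_mass_masks: list[np.ndarray]
    laterality: Literal["left", "right"]
    has_border_artifact: bool
    has_tag: bool
    seed: int


def _breast_field(
    h: int, w: int, laterality: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Radial coordinate (0 centre .. 1 edge) of the half-elliptical breast.

    Returns ``(r, inside)`` where ``inside`` marks breast pixels.  The
    half-ellipse is anchored at the chosen side at mid-height.
    """
    cy = h / 2.0 + rng.uniform(-0.05, 0.05) * h
    ay = h * rng.uniform(0.38, 0.46)
    ax = w * rng.uniform(0.62, 0.78)
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
    x_from_edge = xs if laterality == "left" else (w - 1 - xs)
    r = np.sqrt((x_from_edge / ax) ** 2 + ((ys - cy) / ay) ** 2)
    return r, r <= 1.0


def generate_case(
    seed: int,
    side: int = 640,
    n_masses: int = 1,
    laterality: Literal["left", "right"] = "left",
    noise_sigma: float = 3.0,
    border_artifact: bool = True,
    tag: bool = True,
    bit_depth: int = 8,
    max_retries: int = 2000,
) -> SyntheticCase:
    """Generate one deterministic phantom case.

    ``side`` sets the image height; the width is a realistic non-square
    fraction of it, so the pad-to-square stage is exercised.  Masses are
    placed disjointly inside the breast region; if ``n_masses`` cannot be
    placed within ``max_retries`` attempts an error is raised.
    """
    if side < 64:
        raise ValueError("side must be >= 64")
    if not (0 <= n_masses <= 3):
        raise ValueError("n_masses must lie in [0, 3]")
    if laterality not in ("left", "right"):
        raise ValueError("laterality must be 'left' or 'right'")
    rng = np.random.default_rng([seed, side, n_masses])
    h = side
    w = int(round(side * rng.uniform(0.72, 0.85)))

    background = rng.normal(10.0, 3.0)
    tissue = rng.normal(90.0, 10.0)
    r, inside = _breast_field(h, w, laterality, rng)
    img = np.full((h, w), background, dtype=np.float64)
    falloff = np.sqrt(np.clip(1.0 - r**2, 0.0, 1.0))
    img[inside] += (tissue - background) * (0.55 + 0.45 * falloff[inside])

    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
    masks: list[np.ndarray] = []
    placed: list[tuple[float, float, float]] = []
    attempts = 0
    while len(masks) < n_masses:
        attempts += 1
        if attempts > max_retries:
            raise RuntimeError(
                f"could not place {n_masses} disjoint masses after {max_retries} attempts"
            )
        # candidate centre well inside the breast (radial coordinate <= 0.6)
        cy = rng.uniform(0.2 * h, 0.8 * h)
        cx = rng.uniform(0.05 * w, 0.9 * w)
        iy, ix = int(cy), int(cx)
        if not inside[iy, ix] or r[iy, ix] > 0.6:
            continue
        a = side * rng.uniform(0.035, 0.07)  # semi-axes in pixels
        b = a * rng.uniform(0.6, 1.0)
        theta = rng.uniform(0.0, np.pi)
        if any(np.hypot(cy - py, cx - px) < 1.4 * (a + pa) for py, px, pa in placed):
            continue
        ct, st = np.cos(theta), np.sin(theta)
        u = (xs - cx) * ct + (ys - cy) * st
        v = -(xs - cx) * st + (ys - cy) * ct
        d2 = (u / a) ** 2 + (v / b) ** 2
        peak = rng.normal(180.0, 10.0) - tissue  # elevation above tissue
        peak = max(peak, 40.0)
        # flat core with a Gaussian edge: a distinct intensity mode, soft rim
        d = np.sqrt(d2)
        edge = np.clip(d - 0.75, 0.0, None)
        elevation = peak * np.exp(-(edge / 0.18) ** 2 / 2.0)
        mask = (elevation > peak / 2.0).astype(np.uint8)
        if not mask.any() or mask[~inside].any():
            continue
        img += elevation
        masks.append(mask)
        placed.append((cy, cx, max(a, b)))

    noise = rng.normal(0.0, noise_sigma, size=img.shape)
    img = img + noise

    if border_artifact:
        # bright rows/columns thin enough for the border crop to remove
        t_rows = max(1, int(0.012 * h))
        t_cols = max(1, int(0.006 * w))
        img[:t_rows, :] = 250.0
        img[-t_rows:, :] = 250.0
        img[:, :t_cols] = 250.0
        img[:, -t_cols:] = 250.0
    if tag:
        th, tw = max(4, h // 40), max(6, w // 24)
        y0 = int(0.06 * h)
        x0 = int(0.8 * w) if laterality == "left" else int(0.05 * w)
        img[y0 : y0 + th, x0 : x0 + tw] = 240.0

    img = np.clip(img, 0.0, 255.0)
    if bit_depth == 8:
        image = np.rint(img).astype(np.uint8)
    elif bit_depth == 16:
        image = np.rint(img * 257.0).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    return SyntheticCase(
        image=image,
        per_mass_masks=masks,
        laterality=laterality,
        has_border_artifact=border_artifact,
        has_tag=tag,
        seed=seed,
    )


def generate_dataset(
    seed: int,
    n_cases: int,
    side: int = 640,
    out_dir: str | Path | None = None,
    mass_counts: Sequence[int] | None = None,
    noise_sigma: float = 3.0,
) -> list[SyntheticCase]:
    """Generate a dataset; optionally write it in the canonical raw layout.

    With ``out_dir`` set, writes ``images/<id>.png``, per-mass masks
    ``masks/<id>_<k>.png``, YOLO ``labels/<id>.txt`` (raw-frame coordinates)
    and a ``manifest.csv`` listing case id, laterality, mass count and seed.
    Lateralities alternate so both orientation branches are exercised; mass
    counts cycle 1, 2, 1, 3, ... unless given explicitly.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    default_counts = [1, 2, 1, 3]
    cases = []
    for i in range(n_cases):
        n_m = mass_counts[i] if mass_counts is not None else default_counts[i % 4]
        lat = "left" if i % 2 == 0 else "right"
        case_seed = int(np.random.default_rng([seed, i]).integers(0, 2**31 - 1))
        cases.append(
            generate_case(case_seed, side=side, n_masses=n_m, laterality=lat,
                          noise_sigma=noise_sigma)
        )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, case in enumerate(cases):
            cid = f"case{i:04d}"
            write_gray_png(out_dir / "images" / f"{cid}.png", case.image)
            labels = []
            h, w = case.image.shape
            for k, m in enumerate(case.per_mass_masks):
                write_gray_png(out_dir / "masks" / f"{cid}_{k}.png", m * 255)
                labels.append(bbox_to_yolo(mask_to_bbox(m), w, h))
            write_yolo_labels(out_dir / "labels" / f"{cid}.txt", labels)
            rows.append([cid, case.laterality, len(case.per_mass_masks), case.seed])
        with open(out_dir / "manifest.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["case_id", "laterality", "n_masses", "seed"])
            writer.writerows(rows)
    return cases


def generate_roi_dataset(
    seed: int,
    n_rois: int,
    roi_side: int = 64,
    case_side: int = 256,
    noise_sigma: float = 3.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mass-centred ROI image/mask pairs for segmentation training.

    Generates phantom cases and cuts the tight zero-margin ROI around each
    mass, exactly as the annotation stage would.  Returns
    ``(images, masks, case_ids)`` with images ``(n, roi_side, roi_side)``
    uint8, masks {0, 1}, and the originating case index per ROI so splits can
    be grouped by case.
    """
    from .annotations import extract_roi, mask_to_bbox

    images, masks, case_ids = [], [], []
    case_idx = 0
    while len(images) < n_rois:
        n_m = [1, 2, 1, 3][case_idx % 4]
        lat = "left" if case_idx % 2 == 0 else "right"
        case_seed = int(np.random.default_rng([seed, 7, case_idx]).integers(0, 2**31 - 1))
        case = generate_case(
            case_seed, side=case_side, n_masses=n_m, laterality=lat,
            noise_sigma=noise_sigma, border_artifact=False, tag=False,
        )
        for m in case.per_mass_masks:
            if len(images) >= n_rois:
                break
            roi_img, roi_mask, _ = extract_roi(
                case.image, m, mask_to_bbox(m), out_side=roi_side
            )
            images.append(roi_img)
            masks.append(roi_mask)
            case_ids.append(case_idx)
        case_idx += 1
    return np.stack(images), np.stack(masks), np.asarray(case_ids)
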