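"""Canonicalisation of raw mammogram/mask pairs.

Raw screening mammograms arrive as 8- or 16-bit single-channel images of
varying size and aspect ratio, frequently with bright scanner borders and with
either laterality.  The preprocessing chain turns each image (and its
pixel-aligned per-mass masks) into the canonical square 640x640 8-bit frame
used by the detection stage:

    crop borders -> orient to face right -> min-max normalise to [0,255]
    -> CLAHE (image only) -> pad to square -> resize

Every geometric step is logged in a :class:`TransformRecord` so that masks
predicted in the canonical frame can be mapped back to raw coordinates.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "TransformRecord",
    "crop_borders",
    "orient_right",
    "clahe",
    "pad_to_square",
    "resize_to",
    "normalize_range",
    "preprocess_pair",
    "invert_mask",
    "read_gray_png",
    "write_gray_png",
]


# ---------------------------------------------------------------------------
# validation helpers


def _check_image(img: np.ndarray, name: str = "image") -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"{name} must be a 2-D array, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError(f"{name} must have positive size, got {img.shape}")
    return img


def _check_mask(mask: np.ndarray, name: str = "mask") -> np.ndarray:
    mask = _check_image(mask, name)
    vals = np.unique(mask)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} must be binary with values in {{0,1}}")
    return mask.astype(np.uint8)


# ---------------------------------------------------------------------------
# transform record


@dataclass
class TransformRecord:
    """Composable log of the geometric transforms applied to one image.

    The forward transform maps a raw-frame coordinate ``(x, y)`` to the
    canonical output frame: subtract the crop offsets, mirror horizontally if
    ``flipped``, add the padding offsets, multiply by ``scale``.  ``raw_width``
    and ``raw_height`` record the pre-crop size so the record is
    self-contained for inversion.
    """

    crop_top: int = 0
    crop_bottom: int = 0
    crop_left: int = 0
    crop_right: int = 0
    flipped: bool = False
    pad_left: int = 0
    pad_top: int = 0
    scale: float = 1.0
    raw_height: int = 0
    raw_width: int = 0

    def __post_init__(self) -> None:
        for name in ("crop_top", "crop_bottom", "crop_left", "crop_right", "pad_left", "pad_top"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")

    # interior size after cropping
    @property
    def cropped_width(self) -> int:
        return self.raw_width - self.crop_left - self.crop_right

    @property
    def cropped_height(self) -> int:
        return self.raw_height - self.crop_top - self.crop_bottom

    def apply_xy(self, x: float, y: float) -> tuple[float, float]:
        """Map a raw-frame coordinate into the output frame."""
        xc = x - self.crop_left
        yc = y - self.crop_top
        if self.flipped:
            xc = (self.cropped_width - 1) - xc
        xp = xc + self.pad_left
        yp = yc + self.pad_top
        return xp * self.scale, yp * self.scale

    def invert_xy(self, x: float, y: float) -> tuple[float, float]:
        """Map an output-frame coordinate back into the raw frame."""
        xp = x / self.scale
        yp = y / self.scale
        xc = xp - self.pad_left
        yc = yp - self.pad_top
        if self.flipped:
            xc = (self.cropped_width - 1) - xc
        return xc + self.crop_left, yc + self.crop_top

    def merge(self, other: "TransformRecord") -> "TransformRecord":
        """Accumulate a single-step record into this one.

        Only valid for the fixed pipeline order (crop, flip, pad, scale):
        each step may contribute only the fields later in the chain than any
        field already set, which holds for records produced by this module's
        operations applied in pipeline order.
        """
        return TransformRecord(
            crop_top=self.crop_top + other.crop_top,
            crop_bottom=self.crop_bottom + other.crop_bottom,
            crop_left=self.crop_left + other.crop_left,
            crop_right=self.crop_right + other.crop_right,
            flipped=self.flipped ^ other.flipped,
            pad_left=self.pad_left + other.pad_left,
            pad_top=self.pad_top + other.pad_top,
            scale=self.scale * other.scale,
            raw_height=self.raw_height or other.raw_height,
            raw_width=self.raw_width or other.raw_width,
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TransformRecord":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# operations


def crop_borders(
    img: np.ndarray,
    top_bottom_frac: float = 0.025,
    side_frac: float = 0.01,
) -> tuple[np.ndarray, TransformRecord]:
    """Remove bright scanner borders by fractional cropping.

    ``floor(top_bottom_frac * height)`` rows are removed from the top and from
    the bottom, and ``floor(side_frac * width)`` columns from each side.
    """
    img = _check_image(img)
    if not (0 <= top_bottom_frac < 0.5 and 0 <= side_frac < 0.5):
        raise ValueError("crop fractions must lie in [0, 0.5)")
    h, w = img.shape
    dr = math.floor(top_bottom_frac * h)
    dc = math.floor(side_frac * w)
    if h - 2 * dr < 1:
        raise ValueError(f"cropping {dr} rows from top and bottom empties the height ({h})")
    if w - 2 * dc < 1:
        raise ValueError(f"cropping {dc} columns from each side empties the width ({w})")
    out = img[dr : h - dr, dc : w - dc]
    rec = TransformRecord(
        crop_top=dr, crop_bottom=dr, crop_left=dc, crop_right=dc, raw_height=h, raw_width=w
    )
    return out.copy(), rec


def orient_right(
    img: np.ndarray, companions: Sequence[np.ndarray] = ()
) -> tuple[np.ndarray, list[np.ndarray], bool]:
    """Mirror the image (and aligned companions) so breast tissue faces right.

    The canonical orientation anchors tissue at the left edge: the mean
    intensity of the left half-columns must be >= the mean of the right
    half-columns.  When violated, image and companions are flipped together.
    An exact tie keeps the image unchanged.
    """
    img = _check_image(img)
    outs = []
    for k, comp in enumerate(companions):
        comp = np.asarray(comp)
        if comp.shape != img.shape:
            raise ValueError(
                f"companion {k} shape {comp.shape} does not match image shape {img.shape}"
            )
        outs.append(comp)
    half = img.shape[1] // 2
    if half == 0:
        return img.copy(), [c.copy() for c in outs], False
    left = float(img[:, :half].mean())
    right = float(img[:, img.shape[1] - half :].mean())
    flip = right > left
    if flip:
        img = img[:, ::-1]
        outs = [c[:, ::-1] for c in outs]
    return img.copy(), [c.copy() for c in outs], flip


def _clahe_tile_lut(hist: np.ndarray, clip: int, n_pixels: int) -> np.ndarray:
    """Clip a 256-bin tile histogram, redistribute the excess, return the LUT."""
    hist = hist.astype(np.int64)
    excess = np.maximum(hist - clip, 0).sum()
    hist = np.minimum(hist, clip)
    # uniform redistribution; the remainder is spread one count per bin from 0
    hist += excess // 256
    rem = int(excess % 256)
    if rem:
        hist[:rem] += 1
    cdf = np.cumsum(hist)
    lut = np.rint(cdf * (255.0 / n_pixels)).astype(np.uint8)
    return lut


def clahe(
    img: np.ndarray, clip_limit: float = 2.0, tiles: tuple[int, int] = (8, 8)
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalisation for 8-bit images.

    The image is divided into a ``tiles`` grid; each tile's 256-bin histogram
    is clipped at ``clip_limit * tile_area / 256`` (excess redistributed
    uniformly) and turned into an equalisation LUT; each pixel is mapped by
    bilinear interpolation between the LUTs of the four surrounding tile
    centres.  Images whose sides are not multiples of the grid are reflected
    out to the next multiple and cropped back.
    """
    img = _check_image(img)
    if img.dtype != np.uint8:
        if img.max(initial=0) > 255 or img.min(initial=0) < 0:
            raise ValueError("clahe expects an 8-bit image (apply normalize_range first)")
        img = img.astype(np.uint8)
    ty, tx = int(tiles[0]), int(tiles[1])
    if clip_limit <= 0 or ty < 1 or tx < 1:
        raise ValueError("clip_limit and tile counts must be positive")
    h, w = img.shape
    # reflect-pad so the grid divides evenly
    ph = (ty - h % ty) % ty
    pw = (tx - w % tx) % tx
    work = np.pad(img, ((0, ph), (0, pw)), mode="reflect") if (ph or pw) else img
    hh, ww = work.shape
    th, tw = hh // ty, ww // tx
    n_pixels = th * tw
    clip = max(1, int(clip_limit * n_pixels / 256.0))

    luts = np.empty((ty, tx, 256), dtype=np.uint8)
    for i in range(ty):
        for j in range(tx):
            tile = work[i * th : (i + 1) * th, j * tw : (j + 1) * tw]
            hist = np.bincount(tile.ravel(), minlength=256)
            luts[i, j] = _clahe_tile_lut(hist, clip, n_pixels)

    # bilinear interpolation between tile-centre LUTs, clamped at the borders
    ys = np.arange(hh, dtype=np.float64)
    xs = np.arange(ww, dtype=np.float64)
    fy = (ys - (th - 1) / 2.0) / th
    fx = (xs - (tw - 1) / 2.0) / tw
    y0 = np.clip(np.floor(fy).astype(int), 0, ty - 1)
    x0 = np.clip(np.floor(fx).astype(int), 0, tx - 1)
    y1 = np.clip(y0 + 1, 0, ty - 1)
    x1 = np.clip(x0 + 1, 0, tx - 1)
    wy = np.clip(fy - np.floor(fy), 0.0, 1.0)
    wx = np.clip(fx - np.floor(fx), 0.0, 1.0)
    wy = np.where(fy < 0, 0.0, np.where(fy > ty - 1, 1.0, wy))
    wx = np.where(fx < 0, 0.0, np.where(fx > tx - 1, 1.0, wx))

    px = work
    v00 = luts[y0[:, None], x0[None, :], px].astype(np.float64)
    v01 = luts[y0[:, None], x1[None, :], px].astype(np.float64)
    v10 = luts[y1[:, None], x0[None, :], px].astype(np.float64)
    v11 = luts[y1[:, None], x1[None, :], px].astype(np.float64)
    wyc = wy[:, None]
    wxc = wx[None, :]
    out = (
        (1 - wyc) * ((1 - wxc) * v00 + wxc * v01)
        + wyc * ((1 - wxc) * v10 + wxc * v11)
    )
    out = np.rint(out).astype(np.uint8)
    return out[:h, :w].copy()


def pad_to_square(
    img: np.ndarray, fill: int = 0
) -> tuple[np.ndarray, TransformRecord]:
    """Pad with a constant fill to a centred square of side max(H, W).

    The surplus is split evenly; an odd surplus puts the extra pixel on the
    bottom/right.
    """
    img = _check_image(img)
    h, w = img.shape
    s = max(h, w)
    pad_top = (s - h) // 2
    pad_bottom = s - h - pad_top
    pad_left = (s - w) // 2
    pad_right = s - w - pad_left
    out = np.pad(
        img,
        ((pad_top, pad_bottom), (pad_left, pad_right)),
        mode="constant",
        constant_values=fill,
    )
    rec = TransformRecord(pad_left=pad_left, pad_top=pad_top, raw_height=h, raw_width=w)
    return out, rec


def resize_to(
    img: np.ndarray, side: int, is_mask: bool = False
) -> tuple[np.ndarray, TransformRecord]:
    """Resize a square image to ``side`` x ``side``.

    Images are interpolated bilinearly; masks use nearest-neighbour sampling
    and are re-binarised at 0.5.
    """
    img = _check_image(img)
    h, w = img.shape
    if h != w:
        raise ValueError(f"resize_to expects a square image, got {h}x{w}")
    if side < 1:
        raise ValueError("side must be >= 1")
    rec = TransformRecord(scale=side / h, raw_height=h, raw_width=w)
    if side == h:
        return img.copy(), rec
    if is_mask:
        out = _sk_resize(
            img.astype(np.float64), (side, side), order=0, anti_aliasing=False,
            preserve_range=True,
        )
        out = (out > 0.5).astype(np.uint8)
    else:
        out = _sk_resize(
            img.astype(np.float64), (side, side), order=1, anti_aliasing=False,
            preserve_range=True,
        )
        if np.issubdtype(img.dtype, np.integer):
            info = np.iinfo(img.dtype)
            out = np.clip(np.rint(out), info.min, info.max).astype(img.dtype)
    return out, rec


def normalize_range(img: np.ndarray) -> np.ndarray:
    """Min-max rescale intensities to 8-bit [0, 255] (constant image -> zeros)."""
    img = _check_image(img).astype(np.float64)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros(img.shape, dtype=np.uint8)
    out = (img - lo) * (255.0 / (hi - lo))
    return np.rint(out).astype(np.uint8)


# ---------------------------------------------------------------------------
# full chain


def preprocess_pair(
    image: np.ndarray,
    masks: Sequence[np.ndarray] = (),
    out_side: int = 640,
    top_bottom_frac: float = 0.025,
    side_frac: float = 0.01,
    clip_limit: float = 2.0,
    tiles: tuple[int, int] = (8, 8),
) -> tuple[np.ndarray, list[np.ndarray], TransformRecord]:
    """Run the full canonicalisation chain on one mammogram and its masks.

    Masks undergo the geometric subset only (crop, orient, pad, resize-as-
    mask); the image additionally passes min-max normalisation and CLAHE.
    Returns the 8-bit ``out_side`` x ``out_side`` image, the transformed
    masks, and the composite :class:`TransformRecord`.
    """
    image = _check_image(image)
    masks = [_check_mask(m, f"mask {k}") for k, m in enumerate(masks)]
    img, rec_crop = crop_borders(image, top_bottom_frac, side_frac)
    cropped_masks = [m[rec_crop.crop_top : image.shape[0] - rec_crop.crop_bottom,
                       rec_crop.crop_left : image.shape[1] - rec_crop.crop_right]
                     for m in masks]
    img, oriented_masks, flipped = orient_right(img, cropped_masks)
    img = normalize_range(img)
    img = clahe(img, clip_limit=clip_limit, tiles=tiles)
    img, rec_pad = pad_to_square(img, fill=0)
    padded_masks = [pad_to_square(m, fill=0)[0] for m in oriented_masks]
    img, rec_resize = resize_to(img, out_side, is_mask=False)
    out_masks = [resize_to(m, out_side, is_mask=True)[0] for m in padded_masks]
    record = TransformRecord(
        crop_top=rec_crop.crop_top,
        crop_bottom=rec_crop.crop_bottom,
        crop_left=rec_crop.crop_left,
        crop_right=rec_crop.crop_right,
        flipped=flipped,
        pad_left=rec_pad.pad_left,
        pad_top=rec_pad.pad_top,
        scale=rec_resize.scale,
        raw_height=image.shape[0],
        raw_width=image.shape[1],
    )
    return img, out_masks, record


def invert_mask(mask: np.ndarray, record: TransformRecord) -> np.ndarray:
    """Map a binary mask from the canonical frame back to raw coordinates.

    Undoes, in order: the resize (nearest-neighbour back to the padded side),
    the padding, the horizontal flip, and the crop (cropped-away borders are
    restored as background).
    """
    mask = _check_mask(mask)
    ch, cw = record.cropped_height, record.cropped_width
    side = max(ch, cw)
    if mask.shape[0] != mask.shape[1]:
        raise ValueError("canonical-frame mask must be square")
    un, _ = resize_to(mask, side, is_mask=True)
    un = un[record.pad_top : record.pad_top + ch, record.pad_left : record.pad_left + cw]
    if record.flipped:
        un = un[:, ::-1]
    out = np.zeros((record.raw_height, record.raw_width), dtype=np.uint8)
    out[record.crop_top : record.crop_top + ch, record.crop_left : record.crop_left + cw] = un
    return out


# ---------------------------------------------------------------------------
# PNG I/O


def read_gray_png(path: str | Path) -> np.ndarray:
    """Read an 8- or 16-bit single-channel PNG/TIFF as a 2-D array."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return np.asarray(arr)


def write_gray_png(path: str | Path, img: np.ndarray) -> None:
    import imageio.v3 as iio

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.asarray(img))


def preprocess_directory(
    in_dir: str | Path,
    out_dir: str | Path,
    out_side: int = 640,
    **kwargs,
) -> list[str]:
    """Preprocess every case of a dataset directory in the canonical layout.

    Expects ``images/<id>.png`` and per-mass ``masks/<id>_<k>.png``; writes
    8-bit ``images/<id>.png``, per-mass ``masks/<id>_<k>.png`` and a JSON
    sidecar ``transforms/<id>.transform.json`` under ``out_dir``.  Returns the
    processed case ids.
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    image_paths = sorted((in_dir / "images").glob("*.png"))
    if not image_paths:
        raise FileNotFoundError(f"no images found under {in_dir / 'images'}")
    ids = []
    for ipath in image_paths:
        cid = ipath.stem
        mask_paths = sorted((in_dir / "masks").glob(f"{cid}_*.png"))
        image = read_gray_png(ipath)
        masks = [(read_gray_png(p) > 0).astype(np.uint8) for p in mask_paths]
        img, out_masks, rec = preprocess_pair(image, masks, out_side=out_side, **kwargs)
        write_gray_png(out_dir / "images" / f"{cid}.png", img)
        for mpath, m in zip(mask_paths, out_masks):
            write_gray_png(out_dir / "masks" / mpath.name, m * 255)
        tdir = out_dir / "transforms"
        tdir.mkdir(parents=True, exist_ok=True)
        (tdir / f"{cid}.transform.json").write_text(rec.to_json())
        ids.append(cid)
    return ids
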