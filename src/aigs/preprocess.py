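"""Image normalization and region-of-interest preparation.

The models consume square RGB rasters (512 px by default) contrast-
normalized with CLAHE, and the hemorrhage models additionally consume a
square crop around the optic disc of side ~2x the disc diameter, resized
to the model side. All geometric metadata needed to map results back to
source coordinates is recorded (:class:`RoiCrop`, :class:`SquarePad`).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage import exposure

__all__ = ["RoiCrop", "SquarePad", "apply_clahe", "to_model_square",
           "crop_disc_roi", "stack_six_channel", "split_six_channel"]


def _require_rgb8(image: np.ndarray, op: str) -> np.ndarray:
    image = np.asarray(image)
    if image.dtype != np.uint8 or image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"{op} requires an 8-bit RGB image, "
                         f"got dtype={image.dtype}, shape={image.shape}")
    return image


def apply_clahe(image: np.ndarray, clip_limit: float = 2.0,
                tile_grid: tuple[int, int] = (8, 8),
                nbins: int = 256) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on the luminance.

    The image is taken to YCbCr, CLAHE is applied to the Y channel only
    (chroma preserved), and the result converted back to RGB.
    ``clip_limit`` is expressed as a multiple of the uniform histogram
    level (the common convention); it is divided by ``nbins`` for the
    normalized limit the underlying skimage implementation expects.
    """
    image = _require_rgb8(image, "apply_clahe")
    ycbcr = np.asarray(Image.fromarray(image).convert("YCbCr")).copy()
    y = ycbcr[..., 0]
    if y.max() == y.min():          # no contrast to redistribute
        return image.copy()
    rows, cols = tile_grid
    kernel = (max(y.shape[0] // rows, 1), max(y.shape[1] // cols, 1))
    y_eq = exposure.equalize_adapthist(y, kernel_size=kernel,
                                       clip_limit=clip_limit / nbins,
                                       nbins=nbins)
    ycbcr[..., 0] = np.clip(np.round(y_eq * 255.0), 0, 255).astype(np.uint8)
    return np.asarray(Image.fromarray(ycbcr, "YCbCr").convert("RGB"))


@dataclasses.dataclass
class SquarePad:
    """Affine record of center-pad-to-square + resample."""

    pad_x: int
    pad_y: int
    scale: float        # output pixels per padded-source pixel

    def to_model(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts + [self.pad_x, self.pad_y] + 0.5) * self.scale - 0.5

    def to_source(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts + 0.5) / self.scale - 0.5 - [self.pad_x, self.pad_y]


def to_model_square(image: np.ndarray, side: int = 512,
                    return_transform: bool = False):
    """Square model input. Non-square inputs are center-padded with black
    to square, then resampled (bilinear); an exactly-matching input passes
    through bit-identically."""
    if side < 64:
        raise ValueError("side must be >= 64")
    image = _require_rgb8(image, "to_model_square")
    h, w = image.shape[:2]
    big = max(h, w)
    pad_y, pad_x = (big - h) // 2, (big - w) // 2
    if h == w == side:
        out = image.copy()
        tf = SquarePad(0, 0, 1.0)
    else:
        canvas = np.zeros((big, big, 3), dtype=np.uint8)
        canvas[pad_y:pad_y + h, pad_x:pad_x + w] = image
        out = np.asarray(Image.fromarray(canvas)
                         .resize((side, side), Image.BILINEAR))
        tf = SquarePad(pad_x, pad_y, side / big)
    return (out, tf) if return_transform else out


@dataclasses.dataclass
class RoiCrop:
    """Square crop record around the optic disc (half-open box, source px)."""

    source_id: str
    box: tuple[int, int, int, int]       # (x0, y0, x1, y1)
    disc_center: tuple[float, float]
    disc_radius: float
    scale: float                          # output px per source px

    def __post_init__(self):
        x0, y0, x1, y1 = self.box
        if x1 - x0 != y1 - y0:
            raise ValueError("crop box must be square")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")

    def to_roi(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts - [self.box[0], self.box[1]] + 0.5) * self.scale - 0.5

    def to_source(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts + 0.5) / self.scale - 0.5 + [self.box[0], self.box[1]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "source_id": self.source_id,
            "x0": self.box[0], "y0": self.box[1],
            "x1": self.box[2], "y1": self.box[3],
            "disc_center_x": self.disc_center[0],
            "disc_center_y": self.disc_center[1],
            "disc_radius": self.disc_radius, "scale": self.scale,
        }])

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RoiCrop":
        r = pd.read_csv(path).iloc[0]
        return cls(source_id=str(r.source_id),
                   box=(int(r.x0), int(r.y0), int(r.x1), int(r.y1)),
                   disc_center=(float(r.disc_center_x), float(r.disc_center_y)),
                   disc_radius=float(r.disc_radius), scale=float(r.scale))


def crop_disc_roi(image: np.ndarray, disc_center: tuple[float, float],
                  disc_radius: float, factor: float = 2.0,
                  out_side: int = 512, interpolation: str = "bilinear",
                  source_id: str = "") -> tuple[np.ndarray, RoiCrop]:
    """Square crop of side ``factor x (2 x disc_radius)`` around the disc,
    black-padded where it leaves the image, resampled to ``out_side``."""
    image = np.asarray(image)
    if disc_radius <= 0:
        raise ValueError("disc_radius must be > 0")
    h, w = image.shape[:2]
    if not (0 <= disc_center[0] < w and 0 <= disc_center[1] < h):
        raise ValueError("disc center outside image")
    crop_side = int(round(factor * 2.0 * disc_radius))
    if crop_side > 4 * max(h, w):
        raise ValueError("crop side exceeds 4x the image side")
    x0 = int(round(disc_center[0] - crop_side / 2.0))
    y0 = int(round(disc_center[1] - crop_side / 2.0))
    x1, y1 = x0 + crop_side, y0 + crop_side
    chans = image.shape[2] if image.ndim == 3 else 1
    patch = np.zeros((crop_side, crop_side, chans), dtype=image.dtype)
    sx0, sy0 = max(x0, 0), max(y0, 0)
    sx1, sy1 = min(x1, w), min(y1, h)
    src = image[sy0:sy1, sx0:sx1]
    patch[sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = \
        src if src.ndim == 3 else src[..., None]
    resample = Image.BILINEAR if interpolation == "bilinear" else Image.NEAREST
    if patch.dtype != np.uint8:
        scaled = np.stack([
            np.asarray(Image.fromarray(patch[..., c].astype(np.float32),
                                       "F").resize((out_side, out_side),
                                                   resample))
            for c in range(chans)], axis=-1)
    else:
        scaled = np.asarray(Image.fromarray(patch.squeeze())
                            .resize((out_side, out_side), resample))
        if scaled.ndim == 2:
            scaled = scaled[..., None]
    roi = RoiCrop(source_id=source_id, box=(x0, y0, x1, y1),
                  disc_center=tuple(map(float, disc_center)),
                  disc_radius=float(disc_radius),
                  scale=out_side / crop_side)
    return scaled, roi


def stack_six_channel(roi_rgb: np.ndarray,
                      dh_mask_rgb: np.ndarray) -> np.ndarray:
    """[R, G, B, maskR, maskG, maskB] channel stack."""
    roi_rgb, dh_mask_rgb = np.asarray(roi_rgb), np.asarray(dh_mask_rgb)
    if roi_rgb.shape[:2] != dh_mask_rgb.shape[:2]:
        raise ValueError(f"spatial size mismatch: {roi_rgb.shape[:2]} vs "
                         f"{dh_mask_rgb.shape[:2]}")
    return np.concatenate([roi_rgb, dh_mask_rgb], axis=-1)


def split_six_channel(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return stack[..., :3], stack[..., 3:]
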