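"""Mask handling and optic-disc morphometry.

A :class:`SegMask` holds three probabilistic planes (disc, cup, fovea) in
[0, 1]. All measurements are made on planes binarized at 0.5, with the cup
intersected into the disc so containment holds by construction. The
morphometry vector (:class:`DiscAssessment`) covers the cup-to-disc ratios
(major-axis, vertical, horizontal, area, perimeter), the disc size index
(disc-to-fovea distance over maximum disc diameter), disc/cup circularity,
the neuroretinal-rim-to-disc area ratio, the disc ovality ("myopic factor",
major/minor axis ratio), the disc-fovea angle, and neuroretinal rim sector
ratios in a fovea-anchored frame.

Coordinates are 0-based ``(x=column, y=row)`` with the origin at the top
left; angles are measured in image space where "up" is decreasing ``y``.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from PIL import Image
from scipy.spatial import ConvexHull
from skimage import measure

__all__ = [
    "SegMask", "FoveaHeatmap", "DiscAssessment", "fovea_heatmap",
    "stamp_fovea_heatmap", "decode_fovea_center", "fit_disc_circle",
    "fit_ellipse", "compute_cdrs", "compute_disc_indices",
    "compute_sector_rims", "assess_mask", "encode_mask", "decode_mask",
    "CUPPING_FEATURES", "DISC_SIZE_SMALL", "DISC_SIZE_LARGE",
]

#: Disc size index cutoffs: a *small* disc sits many of its own diameters
#: from the fovea (index > 3.0); a *large* one fewer (index < 2.4).
DISC_SIZE_SMALL = 3.0
DISC_SIZE_LARGE = 2.4

#: Default heatmap spread as a fraction of the image side.
SIGMA_FRACTION = 0.08

#: Feature order of the cupping parameter vector fed to the FFCN.
CUPPING_FEATURES = (
    "disc_size_index", "cdr_major", "vcdr", "hcdr", "acdr", "pcdr",
    "nrra_da", "circularity_disc", "circularity_cup",
)


class NoDiscError(ValueError):
    """Raised when an operation requires a non-empty disc plane."""


# ---------------------------------------------------------------------------
# containers

class SegMask:
    """Disc/cup/fovea planes in [0, 1] with containment enforced on decode."""

    def __init__(self, disc: np.ndarray, cup: np.ndarray, fovea: np.ndarray,
                 pixel_scale: float = 1.0):
        disc = np.asarray(disc, dtype=np.float32)
        cup = np.asarray(cup, dtype=np.float32)
        fovea = np.asarray(fovea, dtype=np.float32)
        if not disc.shape == cup.shape == fovea.shape:
            raise ValueError("mask planes must share one shape")
        self.disc, self.cup, self.fovea = disc, cup, fovea
        self.pixel_scale = float(pixel_scale)

    @property
    def shape(self) -> tuple[int, int]:
        return self.disc.shape

    @property
    def disc_bin(self) -> np.ndarray:
        return self.disc >= 0.5

    @property
    def cup_bin(self) -> np.ndarray:
        # containment invariant: binarized cup is clipped into the disc
        return (self.cup >= 0.5) & self.disc_bin

    @property
    def fovea_bin(self) -> np.ndarray:
        return self.fovea >= 0.5

    @classmethod
    def from_model_output(cls, planes: np.ndarray,
                          pixel_scale: float = 1.0) -> "SegMask":
        """Build from an (H, W, 3) array ordered disc, cup, fovea."""
        return cls(planes[..., 0], planes[..., 1], planes[..., 2],
                   pixel_scale=pixel_scale)


@dataclasses.dataclass
class FoveaHeatmap:
    """Gaussian fovea heatmap H(x,y) = exp(-((x-a)^2+(y-b)^2) / (2 s^2))."""

    center: tuple[float, float]
    sigma: float
    values: np.ndarray

    @property
    def grid_side(self) -> int:
        return self.values.shape[0]


@dataclasses.dataclass
class DiscAssessment:
    """Full optic-disc morphometry vector; absent values are NaN."""

    disc_center: tuple[float, float]
    cup_center: tuple[float, float]
    fovea_center: tuple[float, float] | None
    disc_size_index: float
    disc_size_class: str
    disc_fovea_angle: float
    cdr_major: float
    vcdr: float
    hcdr: float
    acdr: float
    pcdr: float
    nrra_da: float
    circularity_disc: float
    circularity_cup: float
    myopic_factor: float
    ratio_s: float
    ratio_i: float
    ratio_n: float
    ratio_t: float
    ratio_it: float
    ratio_st: float

    def to_row(self) -> dict[str, float]:
        row = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name.endswith("_center"):
                x, y = (np.nan, np.nan) if v is None else v
                row[f"{f.name}_x"], row[f"{f.name}_y"] = float(x), float(y)
            elif isinstance(v, str):
                row[f.name] = v
            else:
                row[f.name] = float(v)
        return row

    def cupping_features(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in CUPPING_FEATURES],
                        dtype=np.float32)


# ---------------------------------------------------------------------------
# fovea heatmap

def fovea_heatmap(center: tuple[float, float], sigma: float,
                  image_side: int) -> FoveaHeatmap:
    """Gaussian heatmap on a grid whose side is 20% of ``image_side``.

    ``center`` is given in grid coordinates; the peak value is exactly 1
    there and decays radially with standard deviation ``sigma`` (pixels).
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    side = round(0.2 * image_side)
    alpha, beta = center
    if not (0 <= alpha < side and 0 <= beta < side):
        raise ValueError("center must lie within the heatmap grid")
    x = np.arange(side, dtype=np.float64)
    xx, yy = np.meshgrid(x, x)
    values = np.exp(-((xx - alpha) ** 2 + (yy - beta) ** 2)
                    / (2.0 * sigma ** 2))
    return FoveaHeatmap(center=(float(alpha), float(beta)),
                        sigma=float(sigma), values=values)


def stamp_fovea_heatmap(image_side: int, fovea_center: tuple[float, float],
                        sigma: float | None = None) -> np.ndarray:
    """Full-size fovea plane with the 20%-side heatmap centred on the fovea."""
    sigma = sigma if sigma is not None else SIGMA_FRACTION * image_side
    side = round(0.2 * image_side)
    half = side // 2
    fx, fy = fovea_center
    hm = fovea_heatmap((fx - round(fx) + half, fy - round(fy) + half),
                       sigma, image_side)
    plane = np.zeros((image_side, image_side), dtype=np.float64)
    x0, y0 = round(fx) - half, round(fy) - half
    sx0, sy0 = max(0, -x0), max(0, -y0)
    x0, y0 = max(0, x0), max(0, y0)
    x1 = min(image_side, x0 + side - sx0)
    y1 = min(image_side, y0 + side - sy0)
    plane[y0:y1, x0:x1] = hm.values[sy0:sy0 + (y1 - y0), sx0:sx0 + (x1 - x0)]
    return plane


def decode_fovea_center(fovea_plane: np.ndarray,
                        min_peak: float = 0.2) -> tuple[float, float] | None:
    """Intensity-weighted centroid of the peak region, or None if absent.

    The region is the connected component, among pixels at or above half the
    global maximum, that contains the maximum itself.
    """
    plane = np.asarray(fovea_plane, dtype=np.float64)
    peak = plane.max() if plane.size else 0.0
    if peak < min_peak:
        return None
    labels = measure.label(plane >= 0.5 * peak)
    ry, rx = np.unravel_index(np.argmax(plane), plane.shape)
    region = labels == labels[ry, rx]
    w = plane[region]
    ys, xs = np.nonzero(region)
    return (float((xs * w).sum() / w.sum()), float((ys * w).sum() / w.sum()))


# ---------------------------------------------------------------------------
# geometric fits

def _largest_component(binary: np.ndarray) -> np.ndarray:
    labels = measure.label(binary)
    if labels.max() == 0:
        raise NoDiscError("plane is empty")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def _outer_contour(binary: np.ndarray) -> np.ndarray:
    """Longest 0.5-level contour as (x, y) vertices."""
    padded = np.pad(binary.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    contour = max(contours, key=len) - 1.0     # un-pad; (row, col)
    return contour[:, ::-1]                    # -> (x, y)


def _perimeter(binary: np.ndarray) -> float:
    # Crofton-formula perimeter: nearly unbiased on rasterized ellipses,
    # unlike the staircase arc length of the marching-squares contour.
    return float(measure.perimeter_crofton(binary, directions=4))


def fit_disc_circle(disc_plane: np.ndarray) -> tuple[tuple[float, float], float]:
    """Least-squares (Kasa) circle fit to the outer contour of the disc."""
    comp = _largest_component(np.asarray(disc_plane) >= 0.5)
    pts = _outer_contour(comp)
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    sol, *_ = np.linalg.lstsq(A, x ** 2 + y ** 2, rcond=None)
    cx, cy, c = sol
    r = math.sqrt(max(c + cx ** 2 + cy ** 2, 0.0))
    return (float(cx), float(cy)), float(r)


def fit_ellipse(plane: np.ndarray) -> tuple[float, float, float]:
    """Moment-based ellipse fit of the largest component.

    Returns ``(a, b, rotation_deg)`` with ``a >= b``; rotation is the angle
    of the major axis from the +x image axis, in degrees, positive towards
    +y (down-screen), folded into (-90, 90].
    """
    comp = _largest_component(np.asarray(plane) >= 0.5)
    props = measure.regionprops(comp.astype(np.uint8))[0]
    a = props.axis_major_length / 2.0
    b = props.axis_minor_length / 2.0
    # regionprops orientation: angle from the row axis towards the column
    # axis; convert to angle from +x towards +y.
    rot = 90.0 - math.degrees(props.orientation)
    if rot > 90.0:
        rot -= 180.0
    return float(a), float(b), float(rot)


def _centroid(binary: np.ndarray) -> tuple[float, float]:
    ys, xs = np.nonzero(binary)
    return float(xs.mean()), float(ys.mean())


def _ellipse_extent(a: float, b: float, rot_deg: float,
                    direction_deg: float) -> float:
    """Extent of an (a, b) ellipse rotated by ``rot_deg`` along a
    direction; both angles from the +x image axis."""
    psi = math.radians(direction_deg - rot_deg)
    return 2.0 * math.sqrt((a * math.cos(psi)) ** 2
                           + (b * math.sin(psi)) ** 2)


def _max_diameter(binary: np.ndarray) -> float:
    pts = _outer_contour(binary)
    if len(pts) > 3:
        pts = pts[ConvexHull(pts).vertices]
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


# ---------------------------------------------------------------------------
# morphometry

def compute_cdrs(mask: SegMask) -> tuple[float, float, float, float, float]:
    """(CDR_major, VCDR, HCDR, ACDR, PCDR) from binarized planes.

    Vertical/horizontal/major-axis extents are measured on the
    moment-fitted equivalent ellipse of each plane (sub-pixel accurate on
    rasterized masks, where a raw pixel caliper quantizes to whole
    pixels); areas are pixel counts and perimeters Crofton estimates.
    """
    disc = mask.disc_bin
    if not disc.any():
        raise NoDiscError("empty disc plane")
    cup = mask.cup_bin
    if not cup.any():
        return (0.0, 0.0, 0.0, 0.0, 0.0)
    disc = _largest_component(disc)
    cup = _largest_component(cup)
    da, db, drot = fit_ellipse(disc)
    ca, cb, crot = fit_ellipse(cup)

    def ratio(direction_deg: float) -> float:
        return (_ellipse_extent(ca, cb, crot, direction_deg)
                / _ellipse_extent(da, db, drot, direction_deg))

    cdr_major = ratio(drot)
    vcdr = ratio(90.0)
    hcdr = ratio(0.0)
    acdr = cup.sum() / disc.sum()
    pcdr = _perimeter(cup) / _perimeter(disc)
    return tuple(float(min(v, 1.0)) for v in
                 (cdr_major, vcdr, hcdr, acdr, pcdr))


def compute_disc_indices(mask: SegMask,
                         fovea_center: tuple[float, float] | None) -> dict:
    """Disc size index/class, disc-fovea angle, circularity, NRRA/DA,
    myopic factor. Fovea-dependent entries are NaN when the fovea is absent."""
    disc = mask.disc_bin
    if not disc.any():
        raise NoDiscError("empty disc plane")
    disc = _largest_component(disc)
    cup = mask.cup_bin
    dc = _centroid(disc)
    a, b, _ = fit_ellipse(disc)
    disc_area = float(disc.sum())
    disc_perim = _perimeter(disc)
    ci_disc = 4.0 * math.pi * disc_area / disc_perim ** 2
    if cup.any():
        cup = _largest_component(cup)
        cup_perim = _perimeter(cup)
        ci_cup = 4.0 * math.pi * float(cup.sum()) / cup_perim ** 2
        acdr = float(cup.sum()) / disc_area
    else:
        ci_cup, acdr = float("nan"), 0.0
    out = {
        "disc_center": dc,
        "circularity_disc": float(ci_disc),
        "circularity_cup": float(ci_cup),
        "myopic_factor": float(a / b),
        "nrra_da": float(1.0 - acdr),
    }
    if fovea_center is None:
        out.update(disc_size_index=float("nan"), disc_size_class="unknown",
                   disc_fovea_angle=float("nan"))
        return out
    dx, dy = fovea_center[0] - dc[0], fovea_center[1] - dc[1]
    dist = math.hypot(dx, dy)
    index = dist / _max_diameter(disc)
    if index > DISC_SIZE_SMALL:
        size_class = "small"
    elif index < DISC_SIZE_LARGE:
        size_class = "large"
    else:
        size_class = "normal"
    angle = math.degrees(math.atan2(-dy, dx))      # up-screen positive
    if angle > 90.0:
        angle -= 180.0
    elif angle <= -90.0:
        angle += 180.0
    out.update(disc_size_index=float(index), disc_size_class=size_class,
               disc_fovea_angle=float(angle))
    return out


def fovea_frame_angles(xs: np.ndarray, ys: np.ndarray,
                       disc_center: tuple[float, float],
                       fovea_center: tuple[float, float],
                       laterality: str = "right") -> np.ndarray:
    """Angles (deg, in (-180, 180]) of points about the disc center, in a
    frame where 0 deg points at the fovea (temporal) and positive angles
    are on the superior side.

    The superior side is fixed by laterality: in an upright right-eye
    photograph the fovea lies to the left of the disc and image-up sits at
    +90 deg from the temporal axis; a left eye mirrors the frame. Using
    laterality (not image-up directly) keeps the frame covariant when the
    whole scene is rotated.
    """
    ux, uy = (fovea_center[0] - disc_center[0],
              fovea_center[1] - disc_center[1])
    vx, vy = xs - disc_center[0], ys - disc_center[1]
    phi = np.degrees(np.arctan2(ux * vy - uy * vx, ux * vx + uy * vy))
    if laterality == "left":
        phi = -phi
    return phi


def sector_masks(phi: np.ndarray) -> dict[str, np.ndarray]:
    """Angular wedge membership. T/N are +-45 deg quadrants about the
    temporal (0 deg) and nasal (180 deg) axes; S/I the superior/inferior
    quadrants; ST/IT 45-degree wedges at +-(45..90) deg flanking T."""
    return {
        "t": np.abs(phi) <= 45.0,
        "n": np.abs(phi) > 135.0,
        "s": (phi > 45.0) & (phi <= 135.0),
        "i": (phi < -45.0) & (phi >= -135.0),
        "st": (phi > 45.0) & (phi <= 90.0),
        "it": (phi < -45.0) & (phi >= -90.0),
    }


def compute_sector_rims(mask: SegMask, fovea_center: tuple[float, float],
                        laterality: str = "right") -> dict[str, float]:
    """Neuroretinal rim area per sector, as a fraction of disc area."""
    disc = mask.disc_bin
    if not disc.any():
        raise NoDiscError("empty disc plane")
    disc = _largest_component(disc)
    rim = disc & ~mask.cup_bin
    dc = _centroid(disc)
    ys, xs = np.nonzero(rim)
    phi = fovea_frame_angles(xs.astype(float), ys.astype(float),
                             dc, fovea_center, laterality)
    disc_area = float(disc.sum())
    return {f"ratio_{k}": float(m.sum() / disc_area)
            for k, m in sector_masks(phi).items()}


def assess_mask(mask: SegMask,
                fovea_center: tuple[float, float] | None = None,
                laterality: str = "right") -> DiscAssessment:
    """Full assessment of a segmentation mask.

    The fovea center is decoded from the fovea plane unless given. When no
    fovea is detectable, fovea-dependent parameters are NaN and sector
    ratios are reported as NaN (the frame needs the temporal axis).
    """
    if fovea_center is None:
        fovea_center = decode_fovea_center(mask.fovea)
    cdr_major, vcdr, hcdr, acdr, pcdr = compute_cdrs(mask)
    idx = compute_disc_indices(mask, fovea_center)
    cup = mask.cup_bin
    cup_center = _centroid(cup) if cup.any() else idx["disc_center"]
    if fovea_center is not None:
        sectors = compute_sector_rims(mask, fovea_center, laterality)
    else:
        sectors = {f"ratio_{k}": float("nan")
                   for k in ("s", "i", "n", "t", "it", "st")}
    return DiscAssessment(
        disc_center=idx["disc_center"], cup_center=cup_center,
        fovea_center=fovea_center,
        disc_size_index=idx["disc_size_index"],
        disc_size_class=idx["disc_size_class"],
        disc_fovea_angle=idx["disc_fovea_angle"],
        cdr_major=cdr_major, vcdr=vcdr, hcdr=hcdr, acdr=acdr, pcdr=pcdr,
        nrra_da=idx["nrra_da"],
        circularity_disc=idx["circularity_disc"],
        circularity_cup=idx["circularity_cup"],
        myopic_factor=idx["myopic_factor"], **sectors)


# ---------------------------------------------------------------------------
# PNG encoding (two dialects)

_DIALECT_CUP = {"training": (255, 255, 0), "output": (0, 255, 0)}


def encode_mask(mask: SegMask, dialect: str = "training") -> np.ndarray:
    """RGB encoding of binarized planes: disc red, cup yellow (training
    dialect) or green (model-output dialect), fovea white."""
    if dialect not in _DIALECT_CUP:
        raise ValueError(f"unknown dialect {dialect!r}")
    h, w = mask.shape
    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    rgb[mask.disc_bin] = (255, 0, 0)
    rgb[mask.cup_bin] = _DIALECT_CUP[dialect]
    rgb[mask.fovea_bin] = (255, 255, 255)
    return rgb


def decode_mask(rgb: np.ndarray | Image.Image,
                pixel_scale: float = 1.0) -> SegMask:
    """Decode either dialect back to a SegMask; rejects unknown colors."""
    if isinstance(rgb, Image.Image):
        rgb = np.asarray(rgb.convert("RGB"))
    high = rgb >= 128
    r, g, b = high[..., 0], high[..., 1], high[..., 2]
    fovea = r & g & b
    cup = g & ~fovea                      # yellow or green
    disc = (r & ~fovea) | cup
    known = (~(r | g | b)) | fovea | cup | (r & ~g & ~b)
    n_bad = int((~known).sum())
    if n_bad:
        raise ValueError(f"{n_bad} pixels with unrecognized mask colors")
    return SegMask(disc.astype(np.float32), cup.astype(np.float32),
                   fovea.astype(np.float32), pixel_scale=pixel_scale)
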