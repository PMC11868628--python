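"""Synthetic macula-centered fundus phantoms with analytic ground truth.

A phantom scene is an elliptical optic disc containing an elliptical cup,
a fovea displaced temporally from the disc, vessel-like curvilinear arcs,
and optionally dark-red peripapillary hemorrhage blobs and arcuate
nerve-fiber-layer-defect darkening bands. Every geometric parameter is
known in closed form, so pixel-based morphometry can be validated against
:func:`analytic_morphometry` without any clinical data.

The renderer aims at plausible geometry and contrast, not photorealism:
no camera color model, media opacities, or myopic texture are simulated.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from scipy.special import ellipe

from .morphometry import (DISC_SIZE_LARGE, DISC_SIZE_SMALL, DiscAssessment,
                          SegMask, encode_mask, fovea_frame_angles,
                          sector_masks)

__all__ = ["PhantomSpec", "PhantomLabels", "TruthRecord", "generate_phantom",
           "generate_mask", "generate_cohort", "analytic_morphometry",
           "sample_spec"]

#: Fovea ground-truth disk radius as a fraction of the image side.
FOVEA_RADIUS_FRAC = 0.035


@dataclasses.dataclass
class PhantomLabels:
    glaucoma: bool = False
    dh_positive: bool = False
    rnfld_positive: bool = False


@dataclasses.dataclass
class PhantomSpec:
    """Analytic scene description of one synthetic fundus."""

    image_side: int
    disc_center: tuple[float, float]
    disc_semi_axes: tuple[float, float]          # (a, b), pixels
    disc_rotation: float                         # deg, major axis from +x
    cup_semi_axes: tuple[float, float]
    cup_center_offset: tuple[float, float] = (0.0, 0.0)
    fovea_center: tuple[float, float] = (0.0, 0.0)
    laterality: str = "right"
    vessel_seed: int = 0
    dh_blobs: list = dataclasses.field(default_factory=list)
    rnfld_arcs: list = dataclasses.field(default_factory=list)
    background_seed: int = 0
    labels: PhantomLabels = dataclasses.field(default_factory=PhantomLabels)

    @property
    def cup_center(self) -> tuple[float, float]:
        return (self.disc_center[0] + self.cup_center_offset[0],
                self.disc_center[1] + self.cup_center_offset[1])

    def validate(self) -> None:
        """Raise ValueError naming the violated constraint."""
        if self.image_side < 64:
            raise ValueError("image_side must be >= 64")
        if min(self.disc_semi_axes) <= 0 or min(self.cup_semi_axes) <= 0:
            raise ValueError("all semi-axes must be > 0")
        if self.laterality not in ("right", "left"):
            raise ValueError("laterality must be 'right' or 'left'")
        # cup containment: every boundary point of the cup inside the disc
        t = np.linspace(0.0, 2 * math.pi, 720, endpoint=False)
        ca, cb = self.cup_semi_axes
        rot = math.radians(self.disc_rotation)
        bx = ca * np.cos(t) * math.cos(rot) - cb * np.sin(t) * math.sin(rot)
        by = ca * np.cos(t) * math.sin(rot) + cb * np.sin(t) * math.cos(rot)
        q = _ellipse_q(bx + self.cup_center[0], by + self.cup_center[1],
                       self.disc_center, self.disc_semi_axes,
                       self.disc_rotation)
        if (q > 1.0 + 1e-9).any():        # tolerate exact-tangency round-off
            raise ValueError("cup ellipse not contained in disc ellipse")
        if _ellipse_q(np.array([self.fovea_center[0]]),
                      np.array([self.fovea_center[1]]),
                      self.disc_center, self.disc_semi_axes,
                      self.disc_rotation)[0] <= 1.0:
            raise ValueError("fovea_center must lie outside the disc ellipse")
        max_diam = 2.0 * max(self.disc_semi_axes)
        for blob in self.dh_blobs:
            (bx_, by_), _, _ = blob
            if math.hypot(bx_ - self.disc_center[0],
                          by_ - self.disc_center[1]) > 2.0 * max_diam:
                raise ValueError("dh blob center farther than 2x disc max "
                                 "diameter from disc_center")
        if self.labels.dh_positive != bool(self.dh_blobs):
            raise ValueError("dh_positive label inconsistent with dh_blobs")
        if self.labels.rnfld_positive != bool(self.rnfld_arcs):
            raise ValueError("rnfld_positive label inconsistent with "
                             "rnfld_arcs")


@dataclasses.dataclass
class TruthRecord:
    spec_id: str
    assessment: DiscAssessment
    labels: PhantomLabels
    image_path: str | None = None
    mask_path: str | None = None


# ---------------------------------------------------------------------------
# geometry helpers

def _ellipse_q(x: np.ndarray, y: np.ndarray, center, semi_axes,
               rotation_deg: float) -> np.ndarray:
    """Quadratic form of the ellipse; q <= 1 inside."""
    a, b = semi_axes
    rot = math.radians(rotation_deg)
    dx, dy = x - center[0], y - center[1]
    u = dx * math.cos(rot) + dy * math.sin(rot)
    v = -dx * math.sin(rot) + dy * math.cos(rot)
    return (u / a) ** 2 + (v / b) ** 2


def _ellipse_mask(side: int, center, semi_axes, rotation_deg) -> np.ndarray:
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    return _ellipse_q(xx, yy, center, semi_axes, rotation_deg) <= 1.0


def _ellipse_extents(a: float, b: float, rotation_deg: float
                     ) -> tuple[float, float]:
    """(horizontal, vertical) extent of a rotated ellipse."""
    rot = math.radians(rotation_deg)
    w = 2.0 * math.sqrt((a * math.cos(rot)) ** 2 + (b * math.sin(rot)) ** 2)
    h = 2.0 * math.sqrt((a * math.sin(rot)) ** 2 + (b * math.cos(rot)) ** 2)
    return w, h


def _ellipse_perimeter(a: float, b: float) -> float:
    return float(4.0 * a * ellipe(1.0 - (b / a) ** 2))


# ---------------------------------------------------------------------------
# analytic morphometry

def analytic_morphometry(spec: PhantomSpec) -> DiscAssessment:
    """Closed-form disc assessment from ellipse geometry.

    Areas are pi*a*b; extents come from the rotated-ellipse bounding box;
    perimeters from the complete elliptic integral; sector rim areas from
    polar quadrature about the disc center (4096 rays).
    """
    spec.validate()
    ad, bd = spec.disc_semi_axes
    ac, bc = spec.cup_semi_axes
    wd, hd = _ellipse_extents(ad, bd, spec.disc_rotation)
    wc, hc = _ellipse_extents(ac, bc, spec.disc_rotation)
    acdr = (ac * bc) / (ad * bd)
    pcdr = _ellipse_perimeter(ac, bc) / _ellipse_perimeter(ad, bd)
    dc = spec.disc_center
    fx, fy = spec.fovea_center
    dist = math.hypot(fx - dc[0], fy - dc[1])
    index = dist / (2.0 * ad)
    if index > DISC_SIZE_SMALL:
        size_class = "small"
    elif index < DISC_SIZE_LARGE:
        size_class = "large"
    else:
        size_class = "normal"
    angle = math.degrees(math.atan2(-(fy - dc[1]), fx - dc[0]))
    if angle > 90.0:
        angle -= 180.0
    elif angle <= -90.0:
        angle += 180.0
    ci_disc = 4.0 * math.pi * (math.pi * ad * bd) \
        / _ellipse_perimeter(ad, bd) ** 2
    ci_cup = 4.0 * math.pi * (math.pi * ac * bc) \
        / _ellipse_perimeter(ac, bc) ** 2
    sectors = _analytic_sectors(spec)
    return DiscAssessment(
        disc_center=dc, cup_center=spec.cup_center,
        fovea_center=spec.fovea_center,
        disc_size_index=index, disc_size_class=size_class,
        disc_fovea_angle=angle,
        cdr_major=ac / ad, vcdr=hc / hd, hcdr=wc / wd,
        acdr=acdr, pcdr=pcdr, nrra_da=1.0 - acdr,
        circularity_disc=ci_disc, circularity_cup=ci_cup,
        myopic_factor=ad / bd, **sectors)


def _analytic_sectors(spec: PhantomSpec, n: int = 4096) -> dict[str, float]:
    """Rim area per angular sector by polar quadrature about disc center."""
    ad, bd = spec.disc_semi_axes
    ac, bc = spec.cup_semi_axes
    rot = math.radians(spec.disc_rotation)
    dc = np.asarray(spec.disc_center)
    cc = np.asarray(spec.cup_center)
    ang = np.linspace(-math.pi, math.pi, n, endpoint=False)
    ux, uy = np.cos(ang), np.sin(ang)
    # disc polar radius about its own center
    psi = ang - rot
    r_disc = ad * bd / np.sqrt((bd * np.cos(psi)) ** 2
                               + (ad * np.sin(psi)) ** 2)
    # cup segment along each ray: roots of a quadratic in the cup frame
    w = dc - cc
    wx = w[0] * math.cos(rot) + w[1] * math.sin(rot)
    wy = -w[0] * math.sin(rot) + w[1] * math.cos(rot)
    vx = ux * math.cos(rot) + uy * math.sin(rot)
    vy = -ux * math.sin(rot) + uy * math.cos(rot)
    A = (vx / ac) ** 2 + (vy / bc) ** 2
    B = 2.0 * (wx * vx / ac ** 2 + wy * vy / bc ** 2)
    C = wx ** 2 / ac ** 2 + wy ** 2 / bc ** 2 - 1.0
    disc4 = B ** 2 - 4.0 * A * C
    hit = disc4 > 0
    sq = np.sqrt(np.clip(disc4, 0.0, None))
    t1 = np.clip((-B - sq) / (2.0 * A), 0.0, None)
    t2 = np.clip((-B + sq) / (2.0 * A), 0.0, None)
    cup_term = np.where(hit, t2 ** 2 - t1 ** 2, 0.0)
    rim_area_density = 0.5 * (r_disc ** 2 - cup_term)   # per radian
    dphi = 2.0 * math.pi / n
    phi = fovea_frame_angles(dc[0] + ux, dc[1] + uy, tuple(dc),
                             spec.fovea_center, spec.laterality)
    disc_area = math.pi * ad * bd
    return {f"ratio_{k}": float((rim_area_density[m]).sum() * dphi
                                / disc_area)
            for k, m in sector_masks(phi).items()}


# ---------------------------------------------------------------------------
# rendering

def _smooth_noise(rng: np.random.Generator, side: int, sigma: float,
                  amp: float) -> np.ndarray:
    field = ndimage.gaussian_filter(rng.standard_normal((side, side)), sigma)
    s = field.std()
    return amp * field / s if s > 0 else field


def _soft_edge(q: np.ndarray, width: float = 0.06) -> np.ndarray:
    """Anti-aliased inside-ellipse alpha from the quadratic form."""
    return np.clip((1.0 + width - np.sqrt(np.maximum(q, 0.0))) / width,
                   0.0, 1.0) ** 1.5


def _bezier_points(p0, p1, p2, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    return ((1 - t) ** 2) * p0 + 2 * (1 - t) * t * p1 + (t ** 2) * p2


def _stamp_curve(canvas: np.ndarray, pts: np.ndarray, width: float) -> None:
    side = canvas.shape[0]
    ij = np.round(pts[:, ::-1]).astype(int)       # (row, col)
    ok = ((ij >= 0) & (ij < side)).all(axis=1)
    line = np.zeros_like(canvas)
    line[ij[ok, 0], ij[ok, 1]] = True
    r = max(int(round(width / 2.0)), 1)
    canvas |= ndimage.binary_dilation(line, ndimage.generate_binary_structure(2, 2),
                                      iterations=r)


def _draw_vessels(side: int, spec: PhantomSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.vessel_seed)
    dc = np.asarray(spec.disc_center, dtype=float)
    fv = np.asarray(spec.fovea_center, dtype=float)
    d = np.linalg.norm(fv - dc)
    t_hat = (fv - dc) / d
    n_hat = np.array([t_hat[1], -t_hat[0]])
    if n_hat[1] > 0:                               # point up-screen
        n_hat = -n_hat
    canvas = np.zeros((side, side), dtype=bool)
    for s in (+1.0, -1.0):                         # superior/inferior arcade
        bend = rng.uniform(0.9, 1.3)
        p1 = dc + s * n_hat * d * 0.55 * bend + t_hat * d * 0.15
        p2 = fv + s * n_hat * d * 0.45 + t_hat * d * rng.uniform(0.25, 0.45)
        _stamp_curve(canvas, _bezier_points(dc, p1, p2, 400),
                     width=0.016 * side)
        for _ in range(2):                         # smaller branches
            u = rng.uniform(0.3, 0.8)
            base = _bezier_points(dc, p1, p2, 400)[int(u * 399)]
            q2 = base + t_hat * d * rng.uniform(0.2, 0.5) \
                + s * n_hat * d * rng.uniform(-0.15, 0.25)
            q1 = (base + q2) / 2 + n_hat * s * d * rng.uniform(0.0, 0.1)
            _stamp_curve(canvas, _bezier_points(base, q1, q2, 200),
                         width=0.008 * side)
    # nasal twigs
    for _ in range(3):
        ang = math.atan2(-t_hat[1], -t_hat[0]) + rng.uniform(-0.9, 0.9)
        length = d * rng.uniform(0.4, 0.8)
        p2 = dc + length * np.array([math.cos(ang), math.sin(ang)])
        p1 = (dc + p2) / 2 + rng.uniform(-0.05, 0.05, 2) * side
        _stamp_curve(canvas, _bezier_points(dc, p1, p2, 200),
                     width=0.009 * side)
    return canvas


def _rnfld_band(side: int, spec: PhantomSpec, arc,
                sign: float = -1.0) -> np.ndarray:
    """Feathered multiplicative weight for one arcuate darkening band.

    ``arc`` is (angular span deg, radial extent px, contrast fraction); the
    band starts at the disc margin on the temporal side, centred midway
    between the temporal axis and the pole chosen by ``sign`` (-1 inferior,
    +1 superior; inferior-temporal defects are the most common).
    """
    span, radial_width, contrast = arc
    center_phi = sign * 60.0
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    dc = spec.disc_center
    phi = fovea_frame_angles(xx.ravel(), yy.ravel(), dc, spec.fovea_center,
                             spec.laterality).reshape(side, side)
    rr = np.hypot(xx - dc[0], yy - dc[1])
    r0 = max(spec.disc_semi_axes)
    in_band = (np.abs(phi - center_phi) <= span / 2.0) \
        & (rr >= r0) & (rr <= r0 + radial_width)
    weight = ndimage.gaussian_filter(in_band.astype(float), side / 128.0)
    mx = weight.max()
    if mx > 0:
        weight = weight / mx
    return 1.0 - contrast * weight


def generate_mask(spec: PhantomSpec) -> SegMask:
    """Rasterize only the ground-truth mask of a scene (pixel centers)."""
    spec.validate()
    side = spec.image_side
    disc = _ellipse_mask(side, spec.disc_center, spec.disc_semi_axes,
                         spec.disc_rotation)
    cup = _ellipse_mask(side, spec.cup_center, spec.cup_semi_axes,
                        spec.disc_rotation)
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    fovea = (np.hypot(xx - spec.fovea_center[0], yy - spec.fovea_center[1])
             <= FOVEA_RADIUS_FRAC * side)
    return SegMask(disc.astype(np.float32), (cup & disc).astype(np.float32),
                   fovea.astype(np.float32))


def generate_phantom(spec: PhantomSpec, seed: int = 0
                     ) -> tuple[np.ndarray, SegMask, TruthRecord]:
    """Render one phantom. Identical (spec, seed) gives identical bytes.

    Returns (uint8 RGB image, ground-truth SegMask, TruthRecord with the
    analytic assessment).
    """
    mask = generate_mask(spec)
    side = spec.image_side
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)

    # image
    bg_rng = np.random.default_rng(spec.background_seed)
    grain_rng = np.random.default_rng(seed)
    r_norm = np.hypot(xx - side / 2.0, yy - side / 2.0) / (side / math.sqrt(2))
    vignette = 1.0 - 0.35 * r_norm ** 2
    img = np.empty((side, side, 3), dtype=np.float64)
    base = (0.80, 0.36, 0.13)
    for c in range(3):
        img[..., c] = base[c] * vignette \
            + _smooth_noise(bg_rng, side, side / 24.0, 0.025) \
            + _smooth_noise(bg_rng, side, side / 80.0, 0.015)
    # optic disc and cup (soft-edged)
    q_disc = _ellipse_q(xx, yy, spec.disc_center, spec.disc_semi_axes,
                        spec.disc_rotation)
    q_cup = _ellipse_q(xx, yy, spec.cup_center, spec.cup_semi_axes,
                       spec.disc_rotation)
    for q, color in ((q_disc, (0.96, 0.80, 0.48)),
                     (q_cup, (0.99, 0.91, 0.66))):
        alpha = _soft_edge(q)[..., None]
        img = img * (1 - alpha) + alpha * np.asarray(color)
    # vessels
    vessels = _draw_vessels(side, spec)
    v_alpha = ndimage.gaussian_filter(vessels.astype(float), 0.6)[..., None]
    v_alpha = np.clip(v_alpha, 0.0, 1.0) * 0.85
    img = img * (1 - v_alpha) + v_alpha * np.asarray((0.42, 0.10, 0.07))
    # fovea: radially darker pit
    sigma_f = 0.05 * side
    pit = np.exp(-((xx - spec.fovea_center[0]) ** 2
                   + (yy - spec.fovea_center[1]) ** 2) / (2 * sigma_f ** 2))
    img *= (1.0 - 0.30 * pit[..., None])
    # RNFLD bands (multiplicative darkening; alternate hemispheres)
    for i, arc in enumerate(spec.rnfld_arcs):
        img *= _rnfld_band(side, spec, arc,
                           sign=-1.0 if i % 2 == 0 else 1.0)[..., None]
    # disc hemorrhages
    for (bx, by), radius, color in spec.dh_blobs:
        stretch = grain_rng.uniform(1.2, 1.8)
        angle = grain_rng.uniform(0.0, 180.0)
        q = _ellipse_q(xx, yy, (bx, by), (radius * stretch, radius), angle)
        alpha = _soft_edge(q, width=0.25)[..., None] * 0.9
        img = img * (1 - alpha) + alpha * np.asarray(color) / 255.0
    img += grain_rng.normal(0.0, 0.008, img.shape)
    image = (np.clip(img, 0.0, 1.0) * 255.0).round().astype(np.uint8)

    truth = TruthRecord(spec_id=f"phantom-{seed}",
                        assessment=analytic_morphometry(spec),
                        labels=spec.labels)
    return image, mask, truth


# ---------------------------------------------------------------------------
# cohorts

def sample_spec(rng: np.random.Generator, image_side: int = 512,
                glaucoma: bool = False, dh_positive: bool = False,
                rnfld_positive: bool = False,
                min_disc_diameter: float | None = None) -> PhantomSpec:
    """Draw a plausible scene with the requested findings.

    Disc diameter defaults to 13-16% of the image side (typical for a
    45-degree macula-centered photograph); the fovea sits temporally at a
    disc size index uniform in 2.4-3.4 disc diameters; glaucomatous scenes
    get a linear cup-to-disc ratio of 0.65-0.85 against 0.25-0.5 in
    normals.
    """
    side = image_side
    laterality = "right" if rng.random() < 0.5 else "left"
    ad = rng.uniform(0.065, 0.08) * side
    if min_disc_diameter is not None:
        ad = max(ad, min_disc_diameter / 2.0)
    ovality = rng.uniform(1.0, 1.25)
    bd = ad / ovality
    rotation = 90.0 + rng.uniform(-20.0, 20.0)    # discs tend vertical-oval
    index = rng.uniform(2.45, 3.35)
    dist = index * 2.0 * ad
    angle = math.radians(rng.uniform(-8.0, 8.0))
    sgn = 1.0 if laterality == "right" else -1.0
    fx = side / 2.0 - sgn * dist * 0.42 + rng.uniform(-0.01, 0.01) * side
    fy = side / 2.0 + rng.uniform(-0.02, 0.02) * side
    dcx = fx + sgn * dist * math.cos(angle)
    dcy = fy + dist * math.sin(angle)
    cdr = rng.uniform(0.65, 0.85) if glaucoma else rng.uniform(0.25, 0.5)
    anis = rng.uniform(0.9, 1.0)
    ac, bc = cdr * ad, cdr * bd * anis
    max_off = 0.4 * (1.0 - cdr) * bd
    offset = (rng.uniform(-max_off, max_off), rng.uniform(-max_off, max_off))
    dh_blobs = []
    if dh_positive:
        for _ in range(rng.integers(1, 3)):
            phi = rng.uniform(45.0, 90.0) * (1 if rng.random() < 0.5 else -1)
            # place at the disc margin, in the fovea-anchored frame
            ux = (fx - dcx) / dist
            uy = (fy - dcy) / dist
            th = math.radians(phi) * (1.0 if laterality == "right" else -1.0)
            dirx = ux * math.cos(th) - uy * math.sin(th)
            diry = ux * math.sin(th) + uy * math.cos(th)
            rr = ad * rng.uniform(1.0, 1.2)
            dh_blobs.append(((dcx + rr * dirx, dcy + rr * diry),
                             float(ad * rng.uniform(0.10, 0.2)),
                             (110, 16, 22)))
    rnfld_arcs = []
    if rnfld_positive:
        for _ in range(int(rng.integers(1, 3))):
            rnfld_arcs.append((float(rng.uniform(16.0, 36.0)),
                               float(dist * rng.uniform(0.7, 1.1)),
                               float(rng.uniform(0.08, 0.2))))
    spec = PhantomSpec(
        image_side=side, disc_center=(dcx, dcy), disc_semi_axes=(ad, bd),
        disc_rotation=rotation, cup_semi_axes=(ac, bc),
        cup_center_offset=offset, fovea_center=(fx, fy),
        laterality=laterality,
        vessel_seed=int(rng.integers(0, 2 ** 31 - 1)),
        dh_blobs=dh_blobs, rnfld_arcs=rnfld_arcs,
        background_seed=int(rng.integers(0, 2 ** 31 - 1)),
        labels=PhantomLabels(glaucoma=glaucoma, dh_positive=dh_positive,
                             rnfld_positive=rnfld_positive))
    spec.validate()
    return spec


def generate_cohort(n: int, prevalence: dict[str, float] | float,
                    seed: int, out_dir: str | Path,
                    image_side: int = 512) -> pd.DataFrame:
    """Emit n image/mask PNG pairs plus a truth CSV; fully seeded.

    ``prevalence`` maps label names ({'glaucoma', 'dh_positive',
    'rnfld_positive'}) to fractions in [0, 1]; a bare float sets the
    glaucoma prevalence. Returns the truth table (also written as
    ``truth.csv``).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if np.isscalar(prevalence):
        prevalence = {"glaucoma": float(prevalence)}
    prev = {"glaucoma": 0.0, "dh_positive": 0.0, "rnfld_positive": 0.0,
            **prevalence}
    if any(not 0.0 <= p <= 1.0 for p in prev.values()):
        raise ValueError("prevalences must be in [0, 1]")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"out_dir not writable: {out_dir}: {exc}") from exc
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        flags = {k: bool(rng.random() < p) for k, p in prev.items()}
        spec = sample_spec(rng, image_side, **{
            "glaucoma": flags["glaucoma"],
            "dh_positive": flags["dh_positive"],
            "rnfld_positive": flags["rnfld_positive"]})
        image, mask, truth = generate_phantom(
            spec, seed=int(rng.integers(0, 2 ** 31 - 1)))
        image_path = out_dir / f"image_{i:05d}.png"
        mask_path = out_dir / f"mask_{i:05d}.png"
        Image.fromarray(image).save(image_path)
        Image.fromarray(encode_mask(mask, dialect="training")).save(mask_path)
        row = {
            "id": f"{i:05d}", "image_path": image_path.name,
            "mask_path": mask_path.name, "laterality": spec.laterality,
            "image_side": image_side,
            "disc_center_x_true": spec.disc_center[0],
            "disc_center_y_true": spec.disc_center[1],
            "disc_a": spec.disc_semi_axes[0],
            "disc_b": spec.disc_semi_axes[1],
            "disc_rotation": spec.disc_rotation,
            "cup_a": spec.cup_semi_axes[0], "cup_b": spec.cup_semi_axes[1],
            **{k: int(v) for k, v in flags.items()},
            **truth.assessment.to_row(),
        }
        rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "truth.csv", index=False)
    return table
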