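"""Multi-model screening decision: fusion, escalation, and reporting.

The screening network combines four findings — the direct deep-learning
glaucoma prediction, the cupping decision from disc-assessment parameters,
disc hemorrhage, and nerve-fiber-layer defect — through a small
feed-forward fusion network. The referral ground truth for training that
network is the logical OR of the four sub-model decisions. An adjustable
escalation rule upgrades fused-negative cases to "glaucoma suspect" when
any structural sub-model probability is high (cupping > 0.65,
RNFLD > 0.8, DH > 0.75 by default); a fused-positive referral is never
downgraded.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw
from skimage import measure

from .morphometry import (DiscAssessment, NoDiscError, SegMask, assess_mask,
                          decode_fovea_center, fit_disc_circle)
from .nets import FFCN, ModelBundle
from .preprocess import (apply_clahe, crop_disc_roi, stack_six_channel,
                         to_model_square)

__all__ = ["PredictionBundle", "ScreeningReport", "GradabilityError",
           "DEFAULT_ESCALATION", "referral_label", "fuse_predictions",
           "adjust_decision", "screen_image", "render_report"]

#: Escalation thresholds (strict inequalities) of the adjusted rule.
DEFAULT_ESCALATION = {"cupping": 0.65, "rnfld": 0.8, "dh": 0.75}

MODEL_KEYS = ("mtl", "cupping", "dh", "rnfld")


class GradabilityError(ValueError):
    """The image cannot be screened (e.g. no optic disc found)."""


@dataclasses.dataclass
class PredictionBundle:
    """Per-model probabilities and decisions plus fused/adjusted outcome."""

    probabilities: dict[str, float]
    thresholds: dict[str, float]
    decisions: dict[str, bool]
    fused_probability: float
    fused_decision: bool
    adjusted_decision: str           # normal | glaucoma_suspect | referral

    def __post_init__(self):
        for k, d in self.decisions.items():
            p, t = self.probabilities.get(k), self.thresholds.get(k)
            if p is not None and t is not None and not np.isnan(p):
                if d != (p >= t):
                    raise ValueError(f"decision for {k} inconsistent with "
                                     f"probability {p} and threshold {t}")
        if self.fused_decision and self.adjusted_decision != "referral":
            raise ValueError("a positive fused decision must stay a referral")

    def to_row(self) -> dict:
        row = {f"prob_{k}": self.probabilities.get(k, np.nan)
               for k in MODEL_KEYS}
        row.update({f"decision_{k}": int(self.decisions.get(k, False))
                    for k in MODEL_KEYS})
        row["fused_probability"] = self.fused_probability
        row["fused_decision"] = int(self.fused_decision)
        row["adjusted_decision"] = self.adjusted_decision
        return row


@dataclasses.dataclass
class ScreeningReport:
    overlay: np.ndarray              # uint8 RGB, same size as the input
    row: dict                        # serialized CSV row
    flags: list[str] = dataclasses.field(default_factory=list)


def referral_label(d_mtl: int, d_cup: int, d_dh: int, d_rnfld: int) -> int:
    """Referral ground truth: positive if any sub-model decision is."""
    return int(bool(d_mtl) or bool(d_cup) or bool(d_dh) or bool(d_rnfld))


def fuse_predictions(inputs: np.ndarray, fusion_ffcn: FFCN,
                     threshold: float = 0.5) -> tuple[float, bool]:
    """Fused probability (FFCN forward pass) and thresholded decision."""
    if fusion_ffcn is None:
        raise ValueError("fusion model missing")
    inputs = np.asarray(inputs, dtype=np.float32).reshape(1, -1)
    if inputs.shape[1] != fusion_ffcn.n_inputs:
        raise ValueError(f"fusion model expects {fusion_ffcn.n_inputs} "
                         f"inputs, got {inputs.shape[1]}")
    prob = float(fusion_ffcn.predict_proba(inputs)[0, 1])
    return prob, bool(prob >= threshold)


def adjust_decision(fused_decision: bool, probs: dict[str, float],
                    escalation: dict[str, float] | None = None) -> str:
    """Three-level decision with the escalation rule.

    A positive fused decision is a referral regardless of the
    probabilities. A negative one becomes "glaucoma_suspect" when any
    structural probability strictly exceeds its escalation threshold.
    """
    if fused_decision:
        return "referral"
    esc = {**DEFAULT_ESCALATION, **(escalation or {})}
    for key, cut in esc.items():
        p = probs.get(key)
        if p is not None and not np.isnan(p) and p > cut:
            return "glaucoma_suspect"
    return "normal"


# ---------------------------------------------------------------------------
# end-to-end pipeline

def screen_image(image: np.ndarray, bundle: ModelBundle,
                 config=None) -> tuple[PredictionBundle, ScreeningReport]:
    """Run the full pipeline on one fundus photograph.

    preprocess -> multi-task segmentation+classification -> morphometry ->
    cupping FFCN -> DH segmentation + mask-assisted classification ->
    RNFLD classification -> fusion -> escalation -> report. Deterministic
    for a fixed bundle and input. Raises :class:`GradabilityError` when no
    optic disc is found; an undetectable fovea only disables the
    fovea-dependent parameters and the cupping model.
    """
    from .config import RunConfig
    cfg = config or RunConfig()
    flags: list[str] = []
    mtl = bundle.models["mtl"]
    side = mtl.cfg.input_side
    square, pad = to_model_square(np.asarray(image), side,
                                  return_transform=True)
    square = apply_clahe(square, cfg.clahe_clip_limit,
                         tuple(cfg.clahe_tile_grid))
    x = square.astype(np.float32) / 255.0
    seg, cls = mtl.predict(x[None])
    mask = SegMask.from_model_output(seg[0])
    p_mtl = float(cls[0, 1])
    if not mask.disc_bin.any():
        raise GradabilityError("no optic disc detected; image not gradable")
    fovea = decode_fovea_center(mask.fovea)
    assessment = assess_mask(mask, fovea_center=fovea)
    if fovea is None:
        flags.append("fovea_not_detected")
        p_cup = float("nan")
        d_cup = False
    else:
        feats = assessment.cupping_features()
        p_cup = float(bundle.models["cupping_ffcn"]
                      .predict_proba(feats[None])[0, 1])
        d_cup = p_cup >= bundle.thresholds["cupping_ffcn"]
    # DH branch on the disc ROI
    (dc, radius) = fit_disc_circle(mask.disc)
    roi, roi_crop = crop_disc_roi(square, dc, radius, factor=cfg.roi_factor,
                                  out_side=side)
    roi_f = roi.astype(np.float32) / 255.0
    dh_mask = bundle.models["dh_segmenter"].predict(roi_f[None])[0]
    six = stack_six_channel(roi_f, dh_mask.astype(np.float32))
    p_dh = float(bundle.models["dh_classifier"]
                 .predict_proba(six[None])[0, 1])
    p_rnfld = float(bundle.models["rnfld_classifier"]
                    .predict_proba(x[None])[0, 1])
    thresholds = {
        "mtl": bundle.thresholds["mtl"],
        "cupping": bundle.thresholds["cupping_ffcn"],
        "dh": bundle.thresholds["dh_mask_assisted"],
        "rnfld": bundle.thresholds["rnfld"],
    }
    probs = {"mtl": p_mtl, "cupping": p_cup, "dh": p_dh, "rnfld": p_rnfld}
    decisions = {k: bool(not np.isnan(probs[k])
                         and probs[k] >= thresholds[k]) for k in MODEL_KEYS}
    fused_prob, fused = fuse_predictions(
        np.array([float(decisions[k]) for k in MODEL_KEYS]),
        bundle.models["fusion_ffcn"], bundle.thresholds["fusion"])
    adjusted = adjust_decision(fused, probs, cfg.escalation)
    pred = PredictionBundle(probabilities=probs, thresholds=thresholds,
                            decisions=decisions, fused_probability=fused_prob,
                            fused_decision=fused, adjusted_decision=adjusted)
    report = render_report(np.asarray(image), mask, assessment, pred,
                           dh_mask=dh_mask if decisions["dh"] else None,
                           roi_crop=roi_crop, pad=pad, flags=flags)
    return pred, report


def _draw_contours(draw: ImageDraw.ImageDraw, plane: np.ndarray, color,
                   transform=None, width: int = 2) -> None:
    for contour in measure.find_contours(np.pad(plane, 1), 0.5):
        pts = contour[:, ::-1] - 1.0            # (x, y)
        if transform is not None:
            pts = transform(pts)
        draw.line([tuple(p) for p in pts] + [tuple(pts[0])],
                  fill=color, width=width)


def render_report(image: np.ndarray, mask: SegMask,
                  assessment: DiscAssessment, pred: PredictionBundle,
                  dh_mask: np.ndarray | None = None, roi_crop=None,
                  pad=None, flags: list[str] | None = None
                  ) -> ScreeningReport:
    """Overlay (disc/cup boundaries, fovea marker, DH outline if detected)
    in source-image coordinates plus the serialized CSV row."""
    image = np.asarray(image)
    if image.ndim != 3:
        raise ValueError("overlay needs an RGB source image")
    to_src = (lambda pts: pts) if pad is None else pad.to_source
    canvas = Image.fromarray(image.copy())
    draw = ImageDraw.Draw(canvas)
    _draw_contours(draw, mask.disc_bin.astype(float), (80, 220, 80), to_src)
    _draw_contours(draw, mask.cup_bin.astype(float), (250, 250, 60), to_src)
    if assessment.fovea_center is not None:
        fx, fy = to_src(np.array([assessment.fovea_center]))[0]
        r = max(image.shape[0] // 80, 3)
        draw.line([(fx - r, fy), (fx + r, fy)], fill=(60, 160, 255), width=2)
        draw.line([(fx, fy - r), (fx, fy + r)], fill=(60, 160, 255), width=2)
    if dh_mask is not None and roi_crop is not None:
        def roi_to_src(pts):
            return to_src(roi_crop.to_source(pts))
        dh_bin = (np.asarray(dh_mask)[..., 0] >= 0.5).astype(float)
        if dh_bin.any():
            _draw_contours(draw, dh_bin, (255, 40, 40), roi_to_src)
    overlay = np.asarray(canvas)
    if overlay.shape != image.shape:
        raise ValueError("coordinate frame mismatch between overlay and "
                         "input image")
    recommendation = {
        "normal": "no referral recommended",
        "glaucoma_suspect": "glaucoma suspect: follow-up recommended",
        "referral": "referral to an ophthalmologist recommended",
    }[pred.adjusted_decision]
    row = {**assessment.to_row(), **pred.to_row(),
           "recommendation": recommendation,
           "flags": ";".join(flags or [])}
    return ScreeningReport(overlay=overlay, row=row, flags=list(flags or []))


def screen_to_frame(rows: list[dict]) -> pd.DataFrame:
    """Stack report rows with a fixed, documented column order."""
    return pd.DataFrame(rows)
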