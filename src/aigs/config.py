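"""Run configuration (YAML), dataset manifests, and run logging."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .nets import DEFAULT_THRESHOLDS
from .screen import DEFAULT_ESCALATION

__all__ = ["RunConfig", "load_config", "save_config", "build_manifest",
           "write_run_log"]


@dataclasses.dataclass
class RunConfig:
    """All tunables of a run; defaults are the published operating points
    where printed, and the package's documented choices elsewhere."""

    seed: int = 0
    image_side: int = 512
    clahe_clip_limit: float = 2.0
    clahe_tile_grid: tuple[int, int] = (8, 8)
    roi_factor: float = 2.0
    heatmap_sigma_frac: float = 0.08
    thresholds: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    escalation: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_ESCALATION))
    training: dict = dataclasses.field(default_factory=lambda: {
        "learning_rate": 1e-3, "batch_size": 8, "epochs": 30})
    paths: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        for name, value in {**self.thresholds, **self.escalation}.items():
            if not 0.0 <= float(value) <= 1.0:
                raise ValueError(f"threshold {name}={value} outside [0, 1]")
        self.clahe_tile_grid = tuple(self.clahe_tile_grid)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["clahe_tile_grid"] = list(self.clahe_tile_grid)
        return d


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; missing keys take defaults, unknown
    keys are rejected by name."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValueError(f"malformed YAML in {path}: {exc}") from exc
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw)}")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("thresholds", "escalation", "training"):
        if key in raw:
            base = getattr(RunConfig(), key)
            raw[key] = {**base, **raw[key]}
    return RunConfig(**raw)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def build_manifest(data_dir: str | Path) -> pd.DataFrame:
    """Validated manifest of a cohort directory (images, masks, labels).

    Pairing errors (an image without its mask or vice versa) are reported
    with the offending file names. Ordering is deterministic.
    """
    data_dir = Path(data_dir)
    images = sorted(p.name for p in data_dir.glob("image_*.png"))
    masks = sorted(p.name for p in data_dir.glob("mask_*.png"))
    img_ids = {n[len("image_"):-len(".png")] for n in images}
    mask_ids = {n[len("mask_"):-len(".png")] for n in masks}
    orphans = sorted([f"image_{i}.png" for i in img_ids - mask_ids]
                     + [f"mask_{i}.png" for i in mask_ids - img_ids])
    if orphans:
        raise ValueError(f"unpaired files in {data_dir}: {orphans}")
    rows = []
    truth_path = data_dir / "truth.csv"
    truth = pd.read_csv(truth_path, dtype={"id": str}) \
        if truth_path.exists() else None
    for ident in sorted(img_ids):
        row = {"id": ident, "image_path": f"image_{ident}.png",
               "mask_path": f"mask_{ident}.png"}
        if truth is not None:
            match = truth[truth["id"] == ident]
            if len(match) == 1:
                for col in ("glaucoma", "dh_positive", "rnfld_positive",
                            "laterality"):
                    if col in match:
                        row[col] = match.iloc[0][col]
        rows.append(row)
    return pd.DataFrame(rows)


def write_run_log(out_dir: str | Path, cfg: RunConfig,
                  command: str = "") -> Path:
    """Structured log: config hash, seed, and library versions."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = {
        "command": command,
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    path = out_dir / "run_log.json"
    path.write_text(json.dumps(log, indent=1, sort_keys=True))
    return path
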