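"""Model family for the screening network.

All models share one design language: a convolutional encoder whose channel
count doubles (capped) while the image halves, an attention bottleneck that
progressively narrows channels ("BNA" block: each narrowing step is a 3x3
convolution followed by a per-channel sigmoid attention gate), and compact
fully-connected heads. Five builders cover the family:

* :func:`build_binary_classifier` -- encoder + BNA + FC head (2-way softmax).
  At the reference configuration (512x512x3 input, 16 initial filters,
  16x16x256 encoder terminal, 16x16x8 bottleneck output, head widths 144/176)
  the trainable parameter count is exactly 1,718,770.
* :func:`build_lwbna_unet` -- same encoder, bottleneck narrowing, and a
  mirrored decoder with skip connections; 3-channel sigmoid output
  (disc, cup, fovea heatmap).
* :func:`build_mtl_unet` -- the U-net plus a classification branch taken from
  the bottleneck output (32x32x16 at the reference), flatten + FC head.
* :func:`build_ffcn` -- feed-forward net on numeric features with hidden
  widths 16, 32, 64, 128, 64, 32, 16, dropout after every hidden layer.
* :func:`build_bna_module` -- the bottleneck block on its own.

Training helpers implement Dice-loss segmentation training and categorical
cross-entropy classification training with Adam, plus stratified five-fold
splitting.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import nn
from .nn import Tensor

__all__ = [
    "ArchConfig", "BNAModule", "BinaryClassifier", "LwbnaUnet", "MtlUnet",
    "FFCN", "ModelBundle", "build_bna_module", "build_binary_classifier",
    "build_lwbna_unet", "build_mtl_unet", "build_ffcn", "count_parameters",
    "train_segmenter", "train_classifier", "train_multitask",
    "five_fold_split", "DEFAULT_THRESHOLDS",
]

#: Operating thresholds at the published optimal points (Youden index);
#: the RNFLD classifier has no printed threshold and defaults to 0.5.
DEFAULT_THRESHOLDS = {
    "mtl": 0.5245,
    "cupping_ffcn": 0.4638,
    "dh": 0.4373,
    "dh_mask_assisted": 0.4004,
    "rnfld": 0.5,
    "fusion": 0.5,
}

FFCN_WIDTHS = (16, 32, 64, 128, 64, 32, 16)


@dataclasses.dataclass
class ArchConfig:
    """Architecture hyperparameters shared by the encoder-based models.

    The reference configuration reproduces the published layer shapes:
    512x512x3 input, 16 initial filters doubling per stage (capped at 256)
    down to a 16x16x256 encoder terminal, bottleneck narrowing to 16x16x8,
    and FC head widths (144, 176) resolved so the binary classifier's
    trainable parameter count equals the printed total.
    """

    input_side: int = 512
    input_channels: int = 3
    base_channels: int = 16
    encoder_stages: int = 5
    channel_cap: int = 256
    bna_out_channels: int = 8
    fc_widths: tuple[int, int] = (144, 176)
    dropout_rates: tuple[float, float] = (0.3, 0.3)
    heads: tuple[str, ...] = ("classification",)
    seg_channels: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.input_side % (2 ** self.encoder_stages) != 0:
            raise ValueError("input_side must be divisible by 2**encoder_stages")
        if any(w <= 0 for w in self.fc_widths):
            raise ValueError("fc widths must be positive")
        if self.bna_out_channels >= self.channel_schedule()[-1]:
            raise ValueError("bna_out_channels must be below the encoder "
                             "terminal channel count")

    def channel_schedule(self) -> list[int]:
        """Channel count after the initial conv and after each stage."""
        chans = [self.base_channels]
        for _ in range(self.encoder_stages):
            chans.append(min(chans[-1] * 2, self.channel_cap))
        return chans

    @property
    def encoder_terminal(self) -> tuple[int, int]:
        return (self.input_side // 2 ** self.encoder_stages,
                self.channel_schedule()[-1])


def reference_classifier_config() -> ArchConfig:
    return ArchConfig()


def reference_unet_config() -> ArchConfig:
    """U-net reference: 4 stages (32x32x256 terminal), bottleneck to 16."""
    return ArchConfig(encoder_stages=4, bna_out_channels=16,
                      heads=("segmentation",))


# ---------------------------------------------------------------------------
# blocks

class Encoder(nn.Module):
    def __init__(self, cfg: ArchConfig, rng: np.random.Generator):
        super().__init__()
        chans = cfg.channel_schedule()
        self.conv_in = nn.Conv2D(cfg.input_channels, chans[0], 3, rng=rng)
        self.stage_convs = [nn.Conv2D(cin, cout, 3, rng=rng)
                            for cin, cout in zip(chans[:-1], chans[1:])]
        self.pool = nn.MaxPool2()

    def forward(self, x: Tensor) -> Tensor:
        out, _ = self.forward_with_skips(x)
        return out

    def forward_with_skips(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        feat = self.conv_in(x)
        skips = [feat]
        for conv in self.stage_convs:
            feat = conv(self.pool(feat))
            skips.append(feat)
        return feat, skips[:-1]


class BNAModule(nn.Module):
    """Bottleneck narrowing with attention.

    Channels are halved step by step down to ``out_channels`` (with a final
    adjustment conv if the run of halvings does not land exactly); each step
    is a 3x3 convolution followed by a per-channel attention gate, so the
    block condenses features while weighting the surviving channels.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if out_channels >= in_channels:
            raise ValueError("out_channels must be < in_channels "
                             f"({out_channels} >= {in_channels})")
        rng = rng or np.random.default_rng(0)
        schedule = [in_channels]
        while schedule[-1] // 2 >= out_channels:
            schedule.append(schedule[-1] // 2)
        if schedule[-1] != out_channels:
            schedule.append(out_channels)
        self.steps = []
        for cin, cout in zip(schedule[:-1], schedule[1:]):
            self.steps.append(nn.Conv2D(cin, cout, 3, rng=rng))
            self.steps.append(nn.ChannelAttention(cout, rng=rng))
        self.schedule = schedule

    def forward(self, x: Tensor) -> Tensor:
        for step in self.steps:
            x = step(x)
        return x


def build_bna_module(in_tensor_shape, out_channels: int,
                     seed: int = 0) -> BNAModule:
    """``in_tensor_shape`` is (H, W, C) or a bare channel count."""
    cin = in_tensor_shape if np.isscalar(in_tensor_shape) else in_tensor_shape[-1]
    return BNAModule(int(cin), int(out_channels),
                     rng=np.random.default_rng(seed))


class _FCHead(nn.Module):
    def __init__(self, fin: int, widths: tuple[int, int],
                 rates: tuple[float, float], rng: np.random.Generator):
        super().__init__()
        w1, w2 = widths
        self.fc1 = nn.Dense(fin, w1, activation="relu", rng=rng)
        self.drop1 = nn.Dropout(rates[0])
        self.fc2 = nn.Dense(w1, w2, activation="relu", rng=rng)
        self.drop2 = nn.Dropout(rates[1])
        self.out = nn.Dense(w2, 2, activation="softmax", rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.out(self.drop2(self.fc2(self.drop1(self.fc1(x)))))


# ---------------------------------------------------------------------------
# models

class BinaryClassifier(nn.Module):
    """Encoder + BNA bottleneck + flatten + FC/dropout x2 + 2-way softmax."""

    def __init__(self, cfg: ArchConfig):
        super().__init__()
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.encoder = Encoder(cfg, rng)
        side, term_c = cfg.encoder_terminal
        self.bna = BNAModule(term_c, cfg.bna_out_channels, rng=rng)
        self.flatten = nn.Flatten()
        self.head = _FCHead(side * side * cfg.bna_out_channels,
                            cfg.fc_widths, cfg.dropout_rates, rng)
        self.shapes: dict[str, tuple] = {}

    def forward(self, x: Tensor) -> Tensor:
        feat = self.encoder(x)
        self.shapes["encoder_terminal"] = feat.shape[1:]
        bna = self.bna(feat)
        self.shapes["bna_out"] = bna.shape[1:]
        flat = self.flatten(bna)
        self.shapes["flatten"] = flat.shape[1:]
        return self.head(flat)

    def predict_proba(self, images: np.ndarray, batch_size: int = 8) -> np.ndarray:
        return _predict_in_batches(self, images, batch_size)


class Decoder(nn.Module):
    def __init__(self, cfg: ArchConfig, rng: np.random.Generator):
        super().__init__()
        chans = cfg.channel_schedule()
        skip_chans = chans[:-1][::-1]           # deepest skip first
        cin = cfg.bna_out_channels
        self.up = nn.UpSample2()
        self.stage_convs = []
        for sc in skip_chans:
            self.stage_convs.append(nn.Conv2D(cin + sc, sc, 3, rng=rng))
            cin = sc
        self.conv_out = nn.Conv2D(cin, cfg.seg_channels, 1,
                                  activation="sigmoid", rng=rng)

    def forward_with_skips(self, x: Tensor, skips: list[Tensor]) -> Tensor:
        for conv, skip in zip(self.stage_convs, skips[::-1]):
            x = conv(nn.concat([self.up(x), skip]))
        return self.conv_out(x)


class LwbnaUnet(nn.Module):
    """U-net with attention-narrowed bottleneck; 3-channel sigmoid output."""

    def __init__(self, cfg: ArchConfig):
        super().__init__()
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.encoder = Encoder(cfg, rng)
        _, term_c = cfg.encoder_terminal
        self.bna = BNAModule(term_c, cfg.bna_out_channels, rng=rng)
        self.decoder = Decoder(cfg, rng)
        self.shapes: dict[str, tuple] = {}

    def _bottleneck(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        feat, skips = self.encoder.forward_with_skips(x)
        self.shapes["encoder_terminal"] = feat.shape[1:]
        bott = self.bna(feat)
        self.shapes["bottleneck"] = bott.shape[1:]
        return bott, skips

    def forward(self, x: Tensor) -> Tensor:
        bott, skips = self._bottleneck(x)
        seg = self.decoder.forward_with_skips(bott, skips)
        self.shapes["segmentation"] = seg.shape[1:]
        return seg

    def predict(self, images: np.ndarray, batch_size: int = 4) -> np.ndarray:
        return _predict_in_batches(self, images, batch_size)


class MtlUnet(LwbnaUnet):
    """Multi-task U-net: segmentation plus a classification branch from the
    bottleneck output (flatten, FC+dropout twice, 2-way softmax)."""

    def __init__(self, cfg: ArchConfig):
        super().__init__(cfg)
        rng = np.random.default_rng(cfg.seed + 1)
        side = cfg.input_side // 2 ** cfg.encoder_stages
        fin = side * side * cfg.bna_out_channels
        self.cls_head = _FCHead(fin, cfg.fc_widths, cfg.dropout_rates, rng)
        self.flatten = nn.Flatten()

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        bott, skips = self._bottleneck(x)
        self.shapes["branch_point"] = bott.shape[1:]
        seg = self.decoder.forward_with_skips(bott, skips)
        self.shapes["segmentation"] = seg.shape[1:]
        cls = self.cls_head(self.flatten(bott))
        return seg, cls

    def predict(self, images: np.ndarray,
                batch_size: int = 4) -> tuple[np.ndarray, np.ndarray]:
        segs, clss = [], []
        self.eval()
        for start in range(0, len(images), batch_size):
            seg, cls = self.forward(Tensor(images[start:start + batch_size]))
            segs.append(seg.data)
            clss.append(cls.data)
        return np.concatenate(segs), np.concatenate(clss)


class FFCN(nn.Module):
    """Feed-forward net on numeric inputs; hidden widths 16..128..16."""

    def __init__(self, n_inputs: int, dropout_rate: float = 0.2,
                 seed: int = 0):
        super().__init__()
        if n_inputs < 1:
            raise ValueError("n_inputs must be >= 1")
        rng = np.random.default_rng(seed)
        self.n_inputs = int(n_inputs)
        self.hidden = []
        fin = self.n_inputs
        for w in FFCN_WIDTHS:
            self.hidden.append(nn.Dense(fin, w, activation="relu", rng=rng))
            self.hidden.append(nn.Dropout(dropout_rate))
            fin = w
        self.out = nn.Dense(fin, 2, activation="softmax", rng=rng)

    @property
    def hidden_widths(self) -> tuple[int, ...]:
        return tuple(layer.w.shape[1] for layer in self.hidden
                     if isinstance(layer, nn.Dense))

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.hidden:
            x = layer(x)
        return self.out(x)

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        self.eval()
        return self.forward(Tensor(np.atleast_2d(features))).data


def _predict_in_batches(model: nn.Module, images: np.ndarray,
                        batch_size: int) -> np.ndarray:
    model.eval()
    outs = [model(Tensor(images[s:s + batch_size])).data
            for s in range(0, len(images), batch_size)]
    return np.concatenate(outs)


# ---------------------------------------------------------------------------
# builders

def build_binary_classifier(cfg: ArchConfig | None = None) -> BinaryClassifier:
    cfg = cfg or reference_classifier_config()
    if "classification" not in cfg.heads or "segmentation" in cfg.heads:
        raise ValueError("binary classifier needs a classification-only head")
    return BinaryClassifier(cfg)


def build_lwbna_unet(cfg: ArchConfig | None = None) -> LwbnaUnet:
    cfg = cfg or reference_unet_config()
    if "segmentation" not in cfg.heads:
        raise ValueError("segmentation head required")
    return LwbnaUnet(cfg)


def build_mtl_unet(cfg: ArchConfig | None = None) -> MtlUnet:
    if cfg is None:
        cfg = ArchConfig(encoder_stages=4, bna_out_channels=16,
                         heads=("segmentation", "classification"))
    if set(cfg.heads) != {"segmentation", "classification"}:
        raise ValueError("multi-task model needs both heads")
    return MtlUnet(cfg)


def build_ffcn(n_inputs: int, dropout_rate: float = 0.2, seed: int = 0) -> FFCN:
    return FFCN(n_inputs, dropout_rate=dropout_rate, seed=seed)


def count_parameters(model: nn.Module) -> int:
    """Total number of trainable weights and biases."""
    return int(sum(p.size for p in model.parameters()))


def layer_audit(model: nn.Module) -> list[dict]:
    """Per-parameter audit: name, shape, count (for the JSON manifest)."""
    return [{"name": name, "shape": list(p.shape), "count": int(p.size)}
            for name, p in model.named_parameters()]


# ---------------------------------------------------------------------------
# training

def _reseed_dropouts(model: nn.Module, seed: int) -> None:
    def walk(mod, base):
        for i, (name, sub) in enumerate(sorted(mod.submodules())):
            if isinstance(sub, nn.Dropout):
                sub.reseed(base + i)
            walk(sub, base + 1000 * (i + 1))
    walk(model, seed)


def _history_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["epoch", "train_loss", "val_loss"])


def _iterate(n: int, batch_size: int, rng: np.random.Generator):
    idx = rng.permutation(n)
    for s in range(0, n, batch_size):
        yield idx[s:s + batch_size]


def train_segmenter(model: nn.Module, dataset: tuple[np.ndarray, np.ndarray],
                    epochs: int, seed: int, lr: float = 1e-3,
                    batch_size: int = 8,
                    validation: tuple[np.ndarray, np.ndarray] | None = None,
                    smooth: float = 1.0) -> tuple[nn.Module, pd.DataFrame]:
    """Train with Dice loss (1 - soft Dice). Returns (model, history)."""
    X, Y = dataset
    if len(X) == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed)
    _reseed_dropouts(model, seed)
    opt = nn.Adam(model.parameters(), lr=lr)
    rows = []
    for epoch in range(epochs):
        model.train()
        losses = []
        for batch in _iterate(len(X), batch_size, rng):
            opt.zero_grad()
            loss = nn.dice_loss(model(Tensor(X[batch])), Tensor(Y[batch]),
                                smooth=smooth)
            loss.backward()
            opt.step()
            losses.append(float(loss.data) * len(batch))
        val = np.nan
        if validation is not None:
            model.eval()
            val = float(nn.dice_loss(model(Tensor(validation[0])),
                                     Tensor(validation[1]),
                                     smooth=smooth).data)
        rows.append({"epoch": epoch, "train_loss": sum(losses) / len(X),
                     "val_loss": val})
    model.eval()
    return model, _history_frame(rows)


def _onehot(y: np.ndarray) -> np.ndarray:
    return np.eye(2, dtype=np.float32)[np.asarray(y, dtype=int)]


def train_classifier(model: nn.Module, dataset: tuple[np.ndarray, np.ndarray],
                     epochs: int, seed: int, lr: float = 1e-3,
                     batch_size: int = 8,
                     validation: tuple[np.ndarray, np.ndarray] | None = None
                     ) -> tuple[nn.Module, pd.DataFrame]:
    """Train with categorical cross-entropy. Returns (model, history)."""
    X, y = dataset
    if len(X) == 0:
        raise ValueError("empty dataset")
    Y = _onehot(y)
    rng = np.random.default_rng(seed)
    _reseed_dropouts(model, seed)
    opt = nn.Adam(model.parameters(), lr=lr)
    rows = []
    for epoch in range(epochs):
        model.train()
        losses = []
        for batch in _iterate(len(X), batch_size, rng):
            opt.zero_grad()
            loss = nn.categorical_crossentropy(model(Tensor(X[batch])),
                                               Tensor(Y[batch]))
            loss.backward()
            opt.step()
            losses.append(float(loss.data) * len(batch))
        val = np.nan
        if validation is not None:
            model.eval()
            val = float(nn.categorical_crossentropy(
                Tensor(_predict_in_batches(model, validation[0], batch_size)),
                Tensor(_onehot(validation[1]))).data)
        rows.append({"epoch": epoch, "train_loss": sum(losses) / len(X),
                     "val_loss": val})
    model.eval()
    return model, _history_frame(rows)


def train_multitask(model: MtlUnet,
                    dataset: tuple[np.ndarray, np.ndarray, np.ndarray],
                    epochs: int, seed: int, lr: float = 1e-3,
                    batch_size: int = 8, seg_weight: float = 1.0,
                    cls_weight: float = 1.0) -> tuple[MtlUnet, pd.DataFrame]:
    """Joint Dice + cross-entropy training of the multi-task model."""
    X, Ymask, y = dataset
    if len(X) == 0:
        raise ValueError("empty dataset")
    Ycls = _onehot(y)
    rng = np.random.default_rng(seed)
    _reseed_dropouts(model, seed)
    opt = nn.Adam(model.parameters(), lr=lr)
    rows = []
    for epoch in range(epochs):
        model.train()
        losses = []
        for batch in _iterate(len(X), batch_size, rng):
            opt.zero_grad()
            seg, cls = model(Tensor(X[batch]))
            loss = (seg_weight * nn.dice_loss(seg, Tensor(Ymask[batch]))
                    + cls_weight * nn.categorical_crossentropy(
                        cls, Tensor(Ycls[batch])))
            loss.backward()
            opt.step()
            losses.append(float(loss.data) * len(batch))
        rows.append({"epoch": epoch, "train_loss": sum(losses) / len(X),
                     "val_loss": np.nan})
    model.eval()
    return model, _history_frame(rows)


def five_fold_split(labels: np.ndarray, seed: int
                    ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified 5-fold partitions (train_idx, val_idx).

    Folds are disjoint, exhaustive, and each keeps the class ratio within
    one item of the global ratio.
    """
    labels = np.asarray(labels)
    if len(labels) < 5:
        raise ValueError("need at least 5 items for five folds")
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    return [(tr, va) for tr, va in skf.split(np.zeros(len(labels)), labels)]


# ---------------------------------------------------------------------------
# bundle

_REQUIRED_MODELS = ("mtl", "cupping_ffcn", "dh_segmenter", "dh_classifier",
                    "rnfld_classifier", "fusion_ffcn")


@dataclasses.dataclass
class ModelBundle:
    """The six operational models plus per-model decision thresholds."""

    models: dict[str, nn.Module]
    thresholds: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS))

    def __post_init__(self):
        missing = set(_REQUIRED_MODELS) - set(self.models)
        if missing:
            raise ValueError(f"bundle missing models: {sorted(missing)}")
        for key, thr in self.thresholds.items():
            if not 0.0 < thr < 1.0:
                raise ValueError(f"threshold {key}={thr} outside (0,1)")

    def manifest(self) -> dict:
        return {
            "thresholds": self.thresholds,
            "models": {
                name: {
                    "kind": type(model).__name__,
                    "config": _model_config(model),
                    "parameter_count": count_parameters(model),
                    "layers": layer_audit(model),
                }
                for name, model in self.models.items()
            },
        }

    def save(self, path: str | Path) -> None:
        """Write weights (npz) plus a JSON architecture manifest."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        (path / "manifest.json").write_text(
            json.dumps(self.manifest(), indent=1))
        for name, model in self.models.items():
            np.savez(path / f"{name}.npz", **model.state_dict())

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        models = {}
        for name, entry in manifest["models"].items():
            model = _model_from_config(entry["kind"], entry["config"])
            with np.load(path / f"{name}.npz") as z:
                model.load_state_dict(dict(z))
            models[name] = model
        return cls(models=models, thresholds=manifest["thresholds"])


def _model_config(model: nn.Module) -> dict:
    if isinstance(model, FFCN):
        return {"n_inputs": model.n_inputs}
    cfg = dataclasses.asdict(model.cfg)
    cfg["fc_widths"] = list(cfg["fc_widths"])
    cfg["dropout_rates"] = list(cfg["dropout_rates"])
    cfg["heads"] = list(cfg["heads"])
    return cfg


def _model_from_config(kind: str, config: dict) -> nn.Module:
    if kind == "FFCN":
        return FFCN(config["n_inputs"])
    cfg = ArchConfig(**{**config,
                        "fc_widths": tuple(config["fc_widths"]),
                        "dropout_rates": tuple(config["dropout_rates"]),
                        "heads": tuple(config["heads"])})
    builders = {"BinaryClassifier": BinaryClassifier, "LwbnaUnet": LwbnaUnet,
                "MtlUnet": MtlUnet}
    return builders[kind](cfg)
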