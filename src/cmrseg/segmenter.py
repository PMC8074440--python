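"""Sequence-specific 2D U-Net segmenters: configs, losses, training, inference.

One independent model is trained per sequence kind.  All models use the
Adam optimizer (lr 0.01, beta1 0.9, beta2 0.999, batch size 5) and
maximize the foreground Dice, except the cine model which minimizes a
weighted cross-entropy loss with inverse-frequency class weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from cmrseg.core import SequenceKind
from cmrseg.nn import UNet, Adam, softmax

DICE_EPS = 1e-5


@dataclass
class UNetConfig:
    kind: SequenceKind
    depth: int = 4
    base_channels: int = 16
    input_shape: tuple[int, int] = (212, 212)

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("U-Net depth must be >= 2")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")

    @property
    def n_classes(self) -> int:
        return self.kind.n_classes


@dataclass
class TrainConfig:
    learning_rate: float = 0.01
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 5
    max_epochs: int = 40
    seed: int = 0

    def loss_for(self, kind: SequenceKind) -> str:
        # the loss is forced by the sequence kind
        return "weighted_cross_entropy" if kind is SequenceKind.CINE else "foreground_dice"


def build_model(cfg: UNetConfig, seed: int = 0) -> UNet:
    """Instantiate a randomly initialized U-Net for ``cfg``.

    Output spatial shape always equals the input shape; inputs whose
    size is not a multiple of ``2**(depth-1)`` are padded internally.
    """
    return UNet(
        n_classes=cfg.n_classes, depth=cfg.depth, base=cfg.base_channels, in_ch=1, seed=seed
    )


# ---------------------------------------------------------------------------
# losses (public functions operate on probabilities; the training loop uses
# the fused logit-gradient versions below them)


def foreground_dice_loss(probs: np.ndarray, target_onehot: np.ndarray, eps: float = DICE_EPS) -> float:
    """``1 - mean over non-background classes of soft Dice``.

    ``probs`` and ``target_onehot`` are ``(N, H, W, C)`` with class
    channel last and channel 0 the background.
    """
    if probs.shape != target_onehot.shape:
        raise ValueError("prediction / target shape mismatch")
    p = probs.reshape(-1, probs.shape[-1]).astype(np.float64)
    t = target_onehot.reshape(-1, probs.shape[-1]).astype(np.float64)
    inter = (p * t).sum(axis=0)[1:]
    denom = p.sum(axis=0)[1:] + t.sum(axis=0)[1:] + eps
    dice = (2.0 * inter + eps) / denom
    return float(1.0 - dice.mean())


def weighted_cross_entropy(
    probs: np.ndarray, target_onehot: np.ndarray, class_weights: np.ndarray
) -> float:
    """Pixel-mean of ``-w_c log p_c`` at the true class."""
    class_weights = np.asarray(class_weights, dtype=np.float64)
    if probs.shape != target_onehot.shape:
        raise ValueError("prediction / target shape mismatch")
    if class_weights.shape != (probs.shape[-1],):
        raise ValueError("one weight per class required")
    if np.any(class_weights <= 0):
        raise ValueError("class weights must be positive")
    p = np.clip(probs, 1e-12, None)
    ll = (target_onehot * np.log(p)).sum(axis=-1)
    w = (target_onehot * class_weights).sum(axis=-1)
    return float(-(w * ll).mean())


def one_hot(classes: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((*classes.shape, n_classes), dtype=np.float32)
    np.put_along_axis(out, classes[..., None], 1.0, axis=-1)
    return out


def _dice_loss_and_grad(logits: np.ndarray, classes: np.ndarray) -> tuple[float, np.ndarray]:
    """Foreground soft-Dice loss and its gradient w.r.t. the logits."""
    C = logits.shape[-1]
    p = softmax(logits)
    t = one_hot(classes, C)
    pf = p.reshape(-1, C).astype(np.float64)
    tf = t.reshape(-1, C)
    inter = (pf * tf).sum(axis=0)
    psum, tsum = pf.sum(axis=0), tf.sum(axis=0)
    denom = psum + tsum + DICE_EPS
    dice = (2.0 * inter + DICE_EPS) / denom
    loss = float(1.0 - dice[1:].mean())
    # dL/dp_c = -(1/(C-1)) * (2 t_c - dice_c) / denom_c   for c >= 1
    dLdp = np.zeros_like(pf)
    nfg = C - 1
    dLdp[:, 1:] = -(2.0 * tf[:, 1:] - dice[1:]) / denom[1:] / nfg
    # chain through softmax
    dot = (dLdp * pf).sum(axis=1, keepdims=True)
    dlogits = (pf * (dLdp - dot)).reshape(logits.shape).astype(np.float32)
    return loss, dlogits


def _wce_loss_and_grad(
    logits: np.ndarray, classes: np.ndarray, class_weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Weighted cross-entropy loss and gradient w.r.t. the logits."""
    C = logits.shape[-1]
    p = softmax(logits)
    t = one_hot(classes, C)
    w_px = class_weights[classes]  # (N, H, W)
    npx = classes.size
    ll = (t * np.log(np.clip(p, 1e-12, None))).sum(axis=-1)
    loss = float(-(w_px * ll).mean())
    dlogits = (p - t) * w_px[..., None] / npx
    return loss, dlogits.astype(np.float32)


def inverse_frequency_weights(classes: np.ndarray, n_classes: int) -> np.ndarray:
    """Inverse class-frequency weights, renormalized to mean 1."""
    counts = np.bincount(classes.ravel(), minlength=n_classes).astype(np.float64)
    counts = np.maximum(counts, 1.0)
    w = 1.0 / counts
    return (w / w.mean()).astype(np.float32)


# ---------------------------------------------------------------------------
# training / inference


@dataclass
class TrainedModel:
    model: UNet
    unet_cfg: UNetConfig
    train_cfg: TrainConfig
    loss_history: list[float] = field(default_factory=list)
    class_weights: Optional[np.ndarray] = None


def train(
    model: UNet,
    images: np.ndarray,
    classes: np.ndarray,
    kind: SequenceKind,
    cfg: TrainConfig,
    unet_cfg: Optional[UNetConfig] = None,
) -> TrainedModel:
    """Train ``model`` on a corpus of 2D slices.

    ``images`` is ``(N, H, W)`` z-scored float32; ``classes`` is
    ``(N, H, W)`` contiguous class indices.  Loss history records the
    per-epoch mean training loss.  Deterministic given ``cfg.seed``.
    """
    if images.shape[0] == 0:
        raise ValueError("empty training set")
    if images.shape != classes.shape:
        raise ValueError("images and masks disagree in shape")
    if classes.max() >= model.n_classes:
        raise ValueError("mask classes exceed the model's class count")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model, lr=cfg.learning_rate, beta1=cfg.beta1, beta2=cfg.beta2)
    loss_kind = cfg.loss_for(kind)
    weights = None
    if loss_kind == "weighted_cross_entropy":
        weights = inverse_frequency_weights(classes, model.n_classes)
    n = images.shape[0]
    history = []
    for _epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = images[idx][..., None]
            yb = classes[idx]
            logits = model.forward(xb, train=True)
            if loss_kind == "weighted_cross_entropy":
                loss, dlogits = _wce_loss_and_grad(logits, yb, weights)
            else:
                loss, dlogits = _dice_loss_and_grad(logits, yb)
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return TrainedModel(
        model=model,
        unet_cfg=unet_cfg or UNetConfig(kind=kind),
        train_cfg=cfg,
        loss_history=history,
        class_weights=weights,
    )


def predict_slice(model: UNet, image2d: np.ndarray) -> np.ndarray:
    """Softmax map ``(n_classes, H, W)`` for one z-scored 2D slice."""
    image2d = np.asarray(image2d, dtype=np.float32)
    if image2d.ndim != 2:
        raise ValueError(f"expected a 2D slice, got {image2d.ndim}D")
    logits = model.forward(image2d[None, :, :, None], train=False)
    probs = softmax(logits)[0]  # (H, W, C)
    return np.ascontiguousarray(np.moveaxis(probs, -1, 0))


def predict_batch(model: UNet, images: np.ndarray, batch_size: int = 8) -> np.ndarray:
    """Softmax maps ``(N, n_classes, H, W)`` for a batch of slices."""
    out = []
    for start in range(0, images.shape[0], batch_size):
        logits = model.forward(images[start : start + batch_size][..., None], train=False)
        out.append(np.moveaxis(softmax(logits), -1, 1))
    return np.concatenate(out, axis=0)


# ---------------------------------------------------------------------------
# checkpointing: framework-native npz + JSON sidecar with the configs


def save_checkpoint(trained: TrainedModel, path: str | Path) -> None:
    path = Path(path)
    np.savez_compressed(path, **trained.model.state_dict())
    meta = {
        "kind": trained.unet_cfg.kind.value,
        "unet": {k: v for k, v in asdict(trained.unet_cfg).items() if k != "kind"},
        "train": asdict(trained.train_cfg),
        "loss_history": trained.loss_history,
    }
    if trained.class_weights is not None:
        meta["class_weights"] = [float(w) for w in trained.class_weights]
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path) -> TrainedModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text())
    unet_cfg = UNetConfig(
        kind=SequenceKind(meta["kind"]),
        depth=meta["unet"]["depth"],
        base_channels=meta["unet"]["base_channels"],
        input_shape=tuple(meta["unet"]["input_shape"]),
    )
    model = build_model(unet_cfg)
    with np.load(path if path.suffix == ".npz" else str(path)) as data:
        model.load_state_dict(dict(data))
    weights = meta.get("class_weights")
    return TrainedModel(
        model=model,
        unet_cfg=unet_cfg,
        train_cfg=TrainConfig(**meta["train"]),
        loss_history=list(meta.get("loss_history", [])),
        class_weights=None if weights is None else np.asarray(weights, dtype=np.float32),
    )
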