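"""Training loop: AdamW, per-epoch validation DSC, best-checkpoint selection.

The recipe follows the segmentation-network training it scales down from:
AdamW at an initial learning rate of 1e-5, each augmentation transform with
probability 0.1, and the checkpoint achieving the best validation dice
similarity kept as the final model (ties broken toward the earlier epoch).
The full-scale schedule is 400 epochs; the "tiny" preset (30 epochs, lr
2e-3) is the CPU-scale analogue used for testing, where the far smaller
model and schedule need a proportionally larger step size. The loss curve
is recorded per epoch and a non-finite loss aborts with diagnostics.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from ..errors import ParameterError, StageError
from .augment import AugmentConfig, augment
from .autograd import Tensor
from .infer import sliding_window_probabilities
from .losses import combined_loss_from_logits, one_hot
from .unetr import NetworkConfig, UNETR3D, build_network

__all__ = ["TrainConfig", "Checkpoint", "AdamW", "clip_gradients", "train", "restore_network", "map_labels_to_network_classes"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 400
    lr: float = 1e-5
    weight_decay: float = 1e-2
    p_augment: float = 0.1
    val_interval: int = 5
    warmup_fraction: float = 0.1  # linear lr warmup over this share of steps
    cosine_decay: bool = False  # optional cosine decay of lr after warmup
    clip_grad_norm: float | None = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0:
            raise ParameterError("learning rate must be positive")
        if not (0.0 <= self.p_augment <= 1.0):
            raise ParameterError("augmentation probability must lie in [0, 1]")
        if not (0.0 <= self.warmup_fraction < 1.0):
            raise ParameterError("warmup fraction must lie in [0, 1)")

    @staticmethod
    def paper() -> "TrainConfig":
        return TrainConfig()

    @staticmethod
    def tiny(seed: int = 0, epochs: int = 30) -> "TrainConfig":
        return TrainConfig(epochs=epochs, lr=2e-3, val_interval=5, seed=seed)


@dataclass
class Checkpoint:
    """Best-validation parameter snapshot with its provenance."""

    state: dict
    net_cfg: NetworkConfig
    epoch: int
    val_dsc: float
    seed: int
    history: list = field(default_factory=list)  # (epoch, mean loss, val dsc or None)

    @property
    def fingerprint(self) -> str:
        blob = json.dumps(asdict(self.net_cfg), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def save(self, path):
        meta = {
            "net_cfg": asdict(self.net_cfg),
            "epoch": self.epoch,
            "val_dsc": self.val_dsc,
            "seed": self.seed,
            "fingerprint": self.fingerprint,
            "history": self.history,
        }
        arrays = {f"arr_{i}": v for i, (_, v) in enumerate(sorted(self.state.items()))}
        names = [k for k, _ in sorted(self.state.items())]
        np.savez(path, __meta__=json.dumps(meta), __names__=json.dumps(names), **arrays)

    @staticmethod
    def load(path) -> "Checkpoint":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"]))
            names = json.loads(str(z["__names__"]))
            state = {n: z[f"arr_{i}"] for i, n in enumerate(names)}
        cfg = meta["net_cfg"]
        for key in ("patch_size", "decoder_channels"):
            cfg[key] = tuple(cfg[key])
        return Checkpoint(
            state=state,
            net_cfg=NetworkConfig(**cfg),
            epoch=meta["epoch"],
            val_dsc=meta["val_dsc"],
            seed=meta["seed"],
            history=[tuple(h) for h in meta["history"]],
        )


def restore_network(checkpoint: Checkpoint) -> UNETR3D:
    net = build_network(checkpoint.net_cfg)
    net.load_state_dict(checkpoint.state)
    return net


class AdamW(object):
    """AdamW with decoupled weight decay (bias-corrected moments)."""

    def __init__(self, params, lr, weight_decay=1e-2, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr_scale: float = 1.0):
        self.t += 1
        lr = self.lr * lr_scale
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            update = (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
            p.data = p.data - lr * (update + self.wd * p.data)


def clip_gradients(params, max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    total = np.sqrt(sum(float((p.grad**2).sum()) for p in params if p.grad is not None))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale
    return total


def map_labels_to_network_classes(labels: np.ndarray, scheme) -> np.ndarray:
    """Collapse a phase scheme onto the 3 network channels.

    Post-contrast: cortex -> 1, medulla -> 2, pelvis-fat -> background.
    Pre-contrast: parenchyma -> 1 (channel 2 stays empty), pelvis-fat ->
    background. Parenchyma is always the union of channels 1 and 2.
    """
    ids = scheme.class_ids
    out = np.zeros_like(labels, dtype=np.uint8)
    if "cortex" in ids:
        out[labels == ids["cortex"]] = 1
        out[labels == ids["medulla"]] = 2
    elif "cortex_or_parenchyma" in ids:
        out[labels == ids["cortex_or_parenchyma"]] = 1
        out[labels == ids["medulla"]] = 2
    else:
        out[labels == ids["parenchyma"]] = 1
    return out


def _sample_patch(image, labels, patch, rng):
    pads = [max(0, p - s) for p, s in zip(patch, image.shape)]
    if any(pads):
        image = np.pad(image, [(0, p) for p in pads])
        labels = np.pad(labels, [(0, p) for p in pads])
    starts = [int(rng.integers(0, s - p + 1)) for s, p in zip(image.shape, patch)]
    sl = tuple(slice(a, a + p) for a, p in zip(starts, patch))
    return image[sl], labels[sl]


def _parenchyma_dsc(pred_labels, true_labels):
    a = np.isin(pred_labels, (1, 2))
    b = np.isin(true_labels, (1, 2))
    tp = float(np.logical_and(a, b).sum())
    denom = 2 * tp + float(np.logical_and(a, ~b).sum()) + float(np.logical_and(~a, b).sum())
    return 1.0 if denom == 0 else 2 * tp / denom


def _validate(net, val_set):
    scores = []
    for image, labels in val_set:
        probs = sliding_window_probabilities(net, image)
        scores.append(_parenchyma_dsc(np.argmax(probs, axis=0), labels))
    return float(np.mean(scores))


def train(train_set, val_set, net_cfg: NetworkConfig, train_cfg: TrainConfig,
          augment_cfg: AugmentConfig | None = None, log=None) -> Checkpoint:
    """Train the network and return the best-validation-DSC checkpoint.

    ``train_set`` / ``val_set`` are sequences of ``(image, labels)`` pairs:
    normalized [0, 1] intensity grids and integer network-class labels (see
    :func:`map_labels_to_network_classes`), both ``(z, y, x)``. One random
    patch is drawn per volume per epoch (batch of one patch per step).
    """
    if not val_set:
        raise ParameterError("at least one validation case is required")
    train_ids = {id(img) for img, _ in train_set}
    if any(id(img) in train_ids for img, _ in val_set):
        raise ParameterError("train and validation sets must be disjoint")

    rng = np.random.default_rng(train_cfg.seed)
    net = build_network(net_cfg)
    opt = AdamW(net.parameters(), lr=train_cfg.lr, weight_decay=train_cfg.weight_decay)
    aug_cfg = augment_cfg or AugmentConfig(p=train_cfg.p_augment)
    patch = tuple(net_cfg.patch_size)
    n_classes = net_cfg.out_channels

    best = None  # (val_dsc, epoch, state)
    history = []
    total_steps = train_cfg.epochs * max(1, len(train_set))
    warmup_steps = max(1, int(round(train_cfg.warmup_fraction * total_steps)))
    step_no = 0
    for epoch in range(1, train_cfg.epochs + 1):
        net.train()
        order = rng.permutation(len(train_set))
        losses = []
        for idx in order:
            image, labels = train_set[idx]
            image, labels = augment(image, labels, aug_cfg, rng=rng)
            image, labels = _sample_patch(image, labels, patch, rng)
            net.zero_grad()
            logits = net(Tensor(image.astype(np.float32)[None]))
            loss = combined_loss_from_logits(logits, one_hot(labels, n_classes))
            lval = float(loss.data)
            if not np.isfinite(lval):
                raise StageError("segnet", f"non-finite loss at epoch {epoch} (case {idx})")
            loss.backward()
            if train_cfg.clip_grad_norm is not None:
                clip_gradients(opt.params, train_cfg.clip_grad_norm)
            step_no += 1
            scale = min(1.0, step_no / warmup_steps)
            if train_cfg.cosine_decay and step_no > warmup_steps:
                frac = (step_no - warmup_steps) / max(1, total_steps - warmup_steps)
                scale = 0.5 * (1.0 + np.cos(np.pi * frac))
            opt.step(lr_scale=scale)
            losses.append(lval)
        val_dsc = None
        if epoch % train_cfg.val_interval == 0 or epoch == train_cfg.epochs:
            val_dsc = _validate(net, val_set)
            if best is None or val_dsc > best[0]:
                best = (val_dsc, epoch, net.state_dict())
        history.append((epoch, float(np.mean(losses)), val_dsc))
        if log is not None:
            log(epoch, float(np.mean(losses)), val_dsc)

    val_dsc, epoch, state = best
    return Checkpoint(state=state, net_cfg=net_cfg, epoch=epoch, val_dsc=val_dsc,
                      seed=train_cfg.seed, history=history)


def select_best_epoch(val_dscs) -> int:
    """1-based argmax with ties broken toward the earlier epoch."""
    arr = np.asarray(val_dscs, dtype=float)
    return int(np.argmax(arr)) + 1
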