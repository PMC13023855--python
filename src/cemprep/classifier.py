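"""Training protocol and a self-contained reference CNN.

The training recipe mirrors the transfer-learning protocol used for the
representation comparison: a warm-up phase in which only the classification
head is optimized while the backbone is frozen, followed by joint
fine-tuning with differential learning rates under cosine annealing, with
early stopping on validation loss.

The :class:`SmallCNNAdapter` is a compact convolutional classifier (three
conv blocks plus one fully connected head) implemented directly on numpy,
with an explicit head/backbone parameter-group split so the whole protocol
— freezing, per-group learning rates, decoupled weight decay — is exercised
end to end.  Deeper pretrained backbones can be plugged in through the same
adapter interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Protocol

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage


@dataclass(frozen=True)
class AugmentParams:
    """Light geometric augmentation applied during training only."""

    enabled: bool = True
    rotation_deg: float = 10.0
    translate_frac: float = 0.05
    scale_range: tuple[float, float] = (0.9, 1.1)
    shear_deg: float = 8.0
    hflip_prob: float = 0.5


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol parameters.

    Defaults follow the fine-tuning recipe the representation comparison
    was designed around: batch 32, 5 head-only warm-up epochs out of a
    30-epoch budget, head/backbone learning rates 1e-4 / 3e-5 with weight
    decay 1e-4, cosine annealing with T_max 20, early-stopping patience 6,
    and fixed seed 42.  ``channel_mode``/``norm_*`` configure the input
    convention for three-channel pretrained backbones; the reference CNN
    consumes the single grayscale channel directly.
    """

    batch_size: int = 32
    max_epochs: int = 30
    warmup_epochs: int = 5
    lr_head: float = 1e-4
    lr_backbone: float = 3e-5
    weight_decay: float = 1e-4
    cosine_t_max: int = 20
    early_stop_patience: int = 6
    augment: AugmentParams = AugmentParams()
    channel_mode: str = "replicate3"
    norm_mean: tuple[float, ...] = (0.485, 0.456, 0.406)
    norm_std: tuple[float, ...] = (0.229, 0.224, 0.225)
    seed: int = 42

    def __post_init__(self) -> None:
        if not self.warmup_epochs < self.max_epochs:
            raise ValueError("warmup_epochs must be < max_epochs")
        if self.lr_head <= 0 or self.lr_backbone <= 0:
            raise ValueError("learning rates must be > 0")
        if self.cosine_t_max < 1:
            raise ValueError("cosine_t_max must be >= 1")

    def scaled_down(self) -> "TrainConfig":
        """A desk-scale profile for small phantom experiments.

        Shorter schedule and larger learning rates, appropriate for a small
        randomly initialized network rather than a pretrained backbone.
        """
        return replace(self, max_epochs=20, warmup_epochs=2, cosine_t_max=14,
                       early_stop_patience=5, lr_head=6e-3, lr_backbone=2e-3)


def cosine_lr(base_lr: float, t: int, t_max: int) -> float:
    """Cosine annealing eta(t) = eta0 * (1 + cos(pi t / T_max)) / 2, floored at t_max."""
    t = min(t, t_max)
    return base_lr * 0.5 * (1.0 + math.cos(math.pi * t / t_max))


class ClassifierAdapter(Protocol):
    """The seam between the experiment protocol and any classifier."""

    def set_backbone_trainable(self, trainable: bool) -> None: ...

    def parameter_groups(self) -> dict[str, list[str]]: ...

    def train_epoch(self, images: np.ndarray, labels: np.ndarray,
                    lr_head: float, lr_backbone: float, weight_decay: float,
                    rng: np.random.Generator,
                    augment: AugmentParams | None = None) -> tuple[float, float]: ...

    def predict_proba(self, images: np.ndarray) -> np.ndarray: ...


# ---------------------------------------------------------------------------
# augmentation


def _augment_batch(batch: np.ndarray, params: AugmentParams,
                   rng: np.random.Generator) -> np.ndarray:
    """Random affine + horizontal flip per image; bilinear, edge-padded."""
    out = np.empty_like(batch)
    h, w = batch.shape[1:]
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    for i, img in enumerate(batch):
        ang = math.radians(rng.uniform(-params.rotation_deg, params.rotation_deg))
        shear = math.radians(rng.uniform(-params.shear_deg, params.shear_deg))
        scale = rng.uniform(*params.scale_range)
        ty = rng.uniform(-params.translate_frac, params.translate_frac) * h
        tx = rng.uniform(-params.translate_frac, params.translate_frac) * w
        flip = rng.random() < params.hflip_prob
        ca, sa = math.cos(ang), math.sin(ang)
        mat = np.array([[ca, -sa], [sa, ca]]) @ np.array([[1.0, math.tan(shear)], [0.0, 1.0]])
        mat = mat / scale
        offset = center - mat @ center + np.array([ty, tx])
        warped = ndimage.affine_transform(img, mat, offset=offset, order=1,
                                          mode="nearest")
        out[i] = warped[:, ::-1] if flip else warped
    return out


def _balanced_batches(y: np.ndarray, batch_size: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    """Class-balanced mini-batches: every batch is drawn half from each class.

    The majority class is covered once per epoch; the minority class is
    recycled (reshuffled) as needed, so batches stay balanced even after
    ratio-limited undersampling.  Falls back to plain shuffling when only
    one class is present.
    """
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) == 0 or len(neg) == 0:
        order = rng.permutation(len(y))
        return [order[s:s + batch_size] for s in range(0, len(y), batch_size)]
    major, minor = (pos, neg) if len(pos) >= len(neg) else (neg, pos)
    half = max(1, batch_size // 2)
    n_batches = max(1, int(np.ceil(len(major) / half)))
    major_order = rng.permutation(major)
    minor_stream: list[np.ndarray] = []
    while len(minor_stream) * len(minor) < n_batches * half:
        minor_stream.append(rng.permutation(minor))
    minor_order = np.concatenate(minor_stream)
    batches = []
    for b in range(n_batches):
        mj = major_order[b * half:(b + 1) * half]
        mn = minor_order[b * half:b * half + len(mj)]
        batches.append(rng.permutation(np.concatenate([mj, mn])))
    return batches


# ---------------------------------------------------------------------------
# numpy CNN


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """3x3 same-padding convolution on NHWC via im2col; returns (y, cols).

    Weight layout is (c*9, cout) with the input channel as the slowest axis,
    matching the (c, 3, 3) window layout so im2col needs no transpose.
    """
    n, h, wd, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    cols = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (n, h, w, c, 3, 3)
    cols = np.ascontiguousarray(cols).reshape(n * h * wd, c * 9)
    y = cols @ w + b
    return y.reshape(n, h, wd, -1), cols


def _conv_backward(dy: np.ndarray, cols: np.ndarray, w: np.ndarray,
                   x_shape: tuple, need_dx: bool = True
                   ) -> tuple[np.ndarray | None, np.ndarray, np.ndarray]:
    n, h, wd, c = x_shape
    cout = dy.shape[-1]
    dy_flat = dy.reshape(-1, cout)
    dw = cols.T @ dy_flat
    db = dy_flat.sum(axis=0)
    if not need_dx:
        return None, dw, db
    # dx = full correlation of dy with the flipped kernel
    w_spatial = w.reshape(c, 3, 3, cout)
    w_rot = np.ascontiguousarray(
        w_spatial[:, ::-1, ::-1].transpose(3, 1, 2, 0)).reshape(cout * 9, c)
    dyp = np.pad(dy, ((0, 0), (1, 1), (1, 1), (0, 0)))
    dcols = sliding_window_view(dyp, (3, 3), axis=(1, 2))
    dcols = np.ascontiguousarray(dcols).reshape(n * h * wd, cout * 9)
    dx = (dcols @ w_rot).reshape(n, h, wd, c)
    return dx, dw, db


def _pool_forward(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, h, w, c = x.shape
    xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
    y = xr.max(axis=(2, 4))
    mask = xr == y[:, :, None, :, None, :]
    mask = mask / mask.sum(axis=(2, 4), keepdims=True)  # split ties evenly
    return y, mask


def _pool_backward(dy: np.ndarray, mask: np.ndarray) -> np.ndarray:
    n, hh, _, ww, _, c = mask.shape
    dx = mask * dy[:, :, None, :, None, :]
    return dx.reshape(n, hh * 2, ww * 2, c)


class SmallCNNAdapter:
    """Three 3x3 conv blocks (conv-ReLU-maxpool) plus one linear head.

    The conv stack is the "backbone" parameter group, the final linear layer
    the "head"; optimization is Adam with decoupled weight decay.  All
    computation is float32 numpy, deterministic under the construction seed.
    Inputs are u8 or unit-float grayscale images; they are standardized to
    zero mean / unit-ish scale internally.
    """

    def __init__(self, seed: int = 42, input_size: int = 64,
                 channels: tuple[int, int, int] = (4, 8, 16)) -> None:
        if input_size % 8 != 0:
            raise ValueError("input_size must be divisible by 8")
        self.input_size = input_size
        self.channels = channels
        rng = np.random.default_rng(seed)
        c0 = 1
        self.params: dict[str, np.ndarray] = {}
        for i, c in enumerate(channels):
            fan_in = 9 * c0
            self.params[f"conv{i}_w"] = (rng.standard_normal((fan_in, c))
                                         * math.sqrt(2.0 / fan_in)).astype(np.float32)
            self.params[f"conv{i}_b"] = np.zeros(c, dtype=np.float32)
            c0 = c
        feat = (input_size // 8) ** 2 * channels[-1]
        # zero head init: training starts from calibrated (uniform) logits
        self.params["fc_w"] = np.zeros((feat, 2), dtype=np.float32)
        self.params["fc_b"] = np.zeros(2, dtype=np.float32)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0
        self._backbone_trainable = True

    # -- adapter interface ---------------------------------------------------

    def parameter_groups(self) -> dict[str, list[str]]:
        head = ["fc_w", "fc_b"]
        backbone = [k for k in self.params if k not in head]
        return {"head": head, "backbone": backbone}

    def set_backbone_trainable(self, trainable: bool) -> None:
        self._backbone_trainable = bool(trainable)

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k, v in weights.items():
            self.params[k] = v.copy()

    # -- forward / backward --------------------------------------------------

    @staticmethod
    def _standardize(images: np.ndarray) -> np.ndarray:
        """Per-image z-scoring over each image's support (nonzero pixels).

        Masked representations zero everything outside the breast; including
        those pixels in the statistics would couple the effective tissue
        contrast to the mask area.  Suppressed pixels stay 0 after scaling.
        """
        x = np.asarray(images, dtype=np.float32)
        if x.max() > 1.5:  # u8 input
            x = x / 255.0
        out = np.empty_like(x)
        for i, im in enumerate(x):
            nz = im > 0
            if nz.sum() < 16:  # (near-)empty support: plain z-score
                m, s = im.mean(), im.std() + 1e-6
                out[i] = (im - m) / s
            else:
                m, s = im[nz].mean(), im[nz].std() + 1e-6
                out[i] = np.where(nz, (im - m) / s, 0.0)
        return out

    def _forward(self, x: np.ndarray, keep_cache: bool = False):
        cache = []
        a = x[..., None]  # NHWC with one channel
        for i in range(len(self.channels)):
            z, cols = _conv_forward(a, self.params[f"conv{i}_w"], self.params[f"conv{i}_b"])
            r = np.where(z > 0, z, 0.01 * z)  # leaky ReLU avoids dead-unit collapse
            p, mask = _pool_forward(r)
            if keep_cache:
                cache.append((a.shape, cols, z, mask))
            a = p
        flat = a.reshape(a.shape[0], -1)
        logits = flat @ self.params["fc_w"] + self.params["fc_b"]
        if keep_cache:
            return logits, (cache, flat, a.shape)
        return logits

    def _backward(self, dlogits: np.ndarray, cache) -> dict[str, np.ndarray]:
        blocks, flat, pooled_shape = cache
        grads = {
            "fc_w": flat.T @ dlogits,
            "fc_b": dlogits.sum(axis=0),
        }
        da = (dlogits @ self.params["fc_w"].T).reshape(pooled_shape)
        if self._backbone_trainable:
            for i in reversed(range(len(self.channels))):
                a_shape, cols, z, mask = blocks[i]
                dr = _pool_backward(da, mask)
                dz = dr * np.where(z > 0, 1.0, 0.01).astype(np.float32)
                da, dw, db = _conv_backward(dz, cols, self.params[f"conv{i}_w"],
                                            a_shape, need_dx=i > 0)
                grads[f"conv{i}_w"] = dw
                grads[f"conv{i}_b"] = db
        return grads

    # -- optimization --------------------------------------------------------

    def _adam_step(self, grads: dict[str, np.ndarray], lrs: dict[str, float],
                   weight_decay: float, beta1: float = 0.9, beta2: float = 0.999,
                   eps: float = 1e-8) -> None:
        self._adam_t += 1
        groups = self.parameter_groups()
        for group, names in groups.items():
            lr = lrs[group]
            for k in names:
                if k not in grads:
                    continue
                g = grads[k].astype(np.float32)
                self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
                self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g * g
                m_hat = self._adam_m[k] / (1 - beta1**self._adam_t)
                v_hat = self._adam_v[k] / (1 - beta2**self._adam_t)
                update = m_hat / (np.sqrt(v_hat) + eps)
                if k.endswith("_w"):  # decoupled weight decay on weights only
                    update = update + weight_decay * self.params[k]
                self.params[k] = self.params[k] - lr * update

    # -- training / inference ------------------------------------------------

    def train_epoch(self, images: np.ndarray, labels: np.ndarray,
                    lr_head: float, lr_backbone: float, weight_decay: float,
                    rng: np.random.Generator,
                    augment: AugmentParams | None = None,
                    batch_size: int = 32) -> tuple[float, float]:
        """One pass over the data; returns (mean loss, accuracy)."""
        x = self._standardize(images)
        y = np.asarray(labels, dtype=np.int64)
        batches = _balanced_batches(y, batch_size, rng)
        total_loss, total_correct = 0.0, 0
        for idx in batches:
            xb = x[idx]
            if augment is not None and augment.enabled:
                xb = _augment_batch(xb, augment, rng)
            yb = y[idx]
            logits, cache = self._forward(xb, keep_cache=True)
            shifted = logits - logits.max(axis=1, keepdims=True)
            expz = np.exp(shifted)
            probs = expz / expz.sum(axis=1, keepdims=True)
            loss = -np.mean(np.log(probs[np.arange(len(yb)), yb] + 1e-12))
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            grads = self._backward(dlogits.astype(np.float32), cache)
            self._adam_step(grads, {"head": lr_head, "backbone": lr_backbone},
                            weight_decay)
            total_loss += loss * len(yb)
            total_correct += int((logits.argmax(axis=1) == yb).sum())
        return total_loss / len(x), total_correct / len(x)

    def predict_proba(self, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """P(malignant) per image; deterministic given fixed weights."""
        x = self._standardize(images)
        out = np.empty(len(x), dtype=np.float64)
        for start in range(0, len(x), batch_size):
            logits = self._forward(x[start:start + batch_size])
            shifted = logits - logits.max(axis=1, keepdims=True)
            expz = np.exp(shifted)
            out[start:start + batch_size] = (expz[:, 1] / expz.sum(axis=1))
        return out

    def evaluate(self, images: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
        """(cross-entropy loss, accuracy) without gradient bookkeeping."""
        probs1 = self.predict_proba(images)
        y = np.asarray(labels, dtype=np.int64)
        p_true = np.where(y == 1, probs1, 1.0 - probs1)
        loss = float(-np.mean(np.log(p_true + 1e-12)))
        acc = float(np.mean((probs1 >= 0.5).astype(int) == y))
        return loss, acc


def reference_small_cnn_adapter(seed: int, input_size: int = 64) -> SmallCNNAdapter:
    """Construct the reference classifier used in phantom experiments."""
    return SmallCNNAdapter(seed=seed, input_size=input_size)


# ---------------------------------------------------------------------------
# training protocol


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    lr_head: list[float] = field(default_factory=list)
    lr_backbone: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0


def train_protocol(adapter, train_images: np.ndarray, train_labels: np.ndarray,
                   val_images: np.ndarray, val_labels: np.ndarray,
                   config: TrainConfig = TrainConfig()) -> TrainHistory:
    """Warm-up + fine-tune with cosine annealing and early stopping.

    Epochs 1..warmup train the head only at ``lr_head`` with the backbone
    frozen; afterwards all parameters train with per-group cosine-annealed
    learning rates.  Training stops when validation loss has not improved
    for ``early_stop_patience`` epochs; the best-validation weights are
    restored on exit.
    """
    if len(val_images) == 0:
        raise ValueError("empty validation set")
    if not hasattr(adapter, "parameter_groups"):
        raise TypeError("adapter lacks parameter groups")
    rng = np.random.default_rng(config.seed)
    history = TrainHistory()
    best_val = math.inf
    best_weights = adapter.get_weights()
    since_best = 0
    for epoch in range(1, config.max_epochs + 1):
        warming = epoch <= config.warmup_epochs
        adapter.set_backbone_trainable(not warming)
        if warming:
            lr_h, lr_b = config.lr_head, config.lr_backbone
        else:
            t = epoch - config.warmup_epochs - 1
            lr_h = cosine_lr(config.lr_head, t, config.cosine_t_max)
            lr_b = cosine_lr(config.lr_backbone, t, config.cosine_t_max)
        tr_loss, tr_acc = adapter.train_epoch(
            train_images, train_labels, lr_h, lr_b, config.weight_decay, rng,
            augment=config.augment if config.augment.enabled else None,
            batch_size=config.batch_size,
        )
        val_loss, val_acc = adapter.evaluate(val_images, val_labels)
        history.train_loss.append(tr_loss)
        history.val_loss.append(val_loss)
        history.train_acc.append(tr_acc)
        history.val_acc.append(val_acc)
        history.lr_head.append(lr_h)
        history.lr_backbone.append(lr_b)
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_weights = adapter.get_weights()
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.early_stop_patience:
                history.stopped_epoch = epoch
                break
    adapter.set_weights(best_weights)
    adapter.set_backbone_trainable(True)
    if history.stopped_epoch == 0:
        history.stopped_epoch = len(history.train_loss)
    return history
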