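"""Capsule classifier head with squashing and routing-by-agreement.

Capsules are vector-valued units: the vector's length (squashed below 1)
encodes the probability that an entity is present, its direction encodes
pose.  Child capsules cast prediction vectors for each parent; routing
iteratively reweights child-to-parent couplings by the agreement between
predictions and the parents' squashed outputs.

Two input modes are supported:

* ``features`` — a (selected, fused) feature vector feeds the primary
  capsules through a linear map; this is the fast path used in the
  federated experiments.
* ``image`` — a small residual convolutional backbone (shared block
  semantics with the segmentation module) is global-average-pooled into the
  primary capsules.  The pooled backbone activations are also the "deep
  features" consumed by the feature-fusion stage.

Training minimizes the standard margin loss (m+ = 0.9, m- = 0.1,
lambda = 0.5); binary cross-entropy over capsule norms is available as an
alternative.  For backpropagation the routing coefficients are treated as
constants of the forward pass (the usual simplification); gradients flow
through the squash, the prediction weights and the backbone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .nn import Adam, BatchNorm2d, Conv2d, Layer, Linear, MaxPool2, Module, ReLU
from .segmentation import ResidualBlock
from .synthetic_data import LabeledScan, derive_seed

__all__ = [
    "ClassifierConfig",
    "squash",
    "squash_backward",
    "dynamic_routing",
    "margin_loss",
    "CapsuleNet",
    "build_classifier",
    "train_classifier",
    "predict",
    "deep_features",
]


@dataclass(frozen=True)
class ClassifierConfig:
    mode: str = "features"             # "features" | "image"
    in_dim: int = 8                    # feature mode: input feature count
    backbone: str = "tiny-res"         # image mode preset
    n_primary: int = 8
    primary_dim: int = 8
    n_classes: int = 2
    digit_dim: int = 8
    routing_iters: int = 3
    loss: str = "margin"               # "margin" | "bce"
    seed: int = 0

    def __post_init__(self):
        if self.routing_iters < 1:
            raise ValueError("routing_iters must be >= 1")
        if self.n_classes < 2:
            raise ValueError("need >= 2 classes")
        if self.mode not in ("features", "image"):
            raise ValueError("mode must be 'features' or 'image'")


def squash(s: np.ndarray, axis: int = -1, eps: float = 1e-12) -> np.ndarray:
    """v = (||s||^2 / (1 + ||s||^2)) * s / ||s||, with squash(0) = 0.

    Short vectors are crushed toward zero, long ones saturate just below
    unit norm; direction is preserved.
    """
    s = np.asarray(s, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite capsule input")
    n2 = (s**2).sum(axis=axis, keepdims=True)
    n = np.sqrt(n2)
    return s * (n / (1.0 + n2 + eps))


def squash_backward(dv: np.ndarray, s: np.ndarray, axis: int = -1,
                    eps: float = 1e-12) -> np.ndarray:
    """Gradient of squash: v = s * h(n), h(n) = n / (1 + n^2)."""
    n2 = (s**2).sum(axis=axis, keepdims=True)
    n = np.sqrt(n2) + eps
    h = n / (1.0 + n2)
    hp = (1.0 - n2) / (1.0 + n2) ** 2          # dh/dn
    sdots = (s * dv).sum(axis=axis, keepdims=True)
    return h * dv + (hp / n) * sdots * s


def dynamic_routing(
    u_hat: np.ndarray, iters: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Routing-by-agreement over prediction vectors.

    ``u_hat`` has shape (batch, n_child, n_parent, parent_dim).  Logits
    b_ij start at zero; couplings c_ij are a softmax over parents; parents
    aggregate s_j = sum_i c_ij u_hat_ij and squash; logits grow by the
    agreement u_hat_ij . v_j.  Returns (v, c) from the final iteration.
    """
    if iters < 1:
        raise ValueError("iters must be >= 1")
    u_hat = np.asarray(u_hat, dtype=float)
    B, n_child, n_parent, dim = u_hat.shape
    b = np.zeros((B, n_child, n_parent))
    for _ in range(iters):
        bmax = b.max(axis=2, keepdims=True)
        e = np.exp(b - bmax)
        c = e / e.sum(axis=2, keepdims=True)
        s = (c[..., None] * u_hat).sum(axis=1)      # (B, n_parent, dim)
        v = squash(s)
        b = b + (u_hat * v[:, None, :, :]).sum(axis=-1)
    return v, c


def margin_loss(
    v: np.ndarray,
    targets: np.ndarray,
    m_pos: float = 0.9,
    m_neg: float = 0.1,
    lam: float = 0.5,
) -> tuple[float, np.ndarray]:
    """Margin loss over capsule norms; returns (loss, dL/dv).

    L = sum_j [T_j max(0, m+ - ||v_j||)^2 + lam (1-T_j) max(0, ||v_j|| - m-)^2],
    averaged over the batch.  ``targets`` is one-hot (batch, n_classes).
    """
    norms = np.sqrt((v**2).sum(axis=-1) + 1e-12)    # (B, J)
    pos = np.maximum(0.0, m_pos - norms)
    neg = np.maximum(0.0, norms - m_neg)
    B = v.shape[0]
    loss = float((targets * pos**2 + lam * (1 - targets) * neg**2).sum() / B)
    dnorm = (-2.0 * targets * pos + 2.0 * lam * (1 - targets) * neg) / B
    dv = dnorm[..., None] * (v / norms[..., None])
    return loss, dv


class CapsPredict(Layer):
    """Per child-parent linear prediction u_hat_ij = W_ij u_i."""

    def __init__(self, n_child: int, n_parent: int, child_dim: int, parent_dim: int):
        super().__init__()
        self.dims = (n_child, n_parent, child_dim, parent_dim)
        self.params["W"] = np.zeros((n_child, n_parent, child_dim, parent_dim))

    def init(self, rng: np.random.Generator) -> None:
        n_child, n_parent, child_dim, parent_dim = self.dims
        self.params["W"] = rng.normal(
            0.0, np.sqrt(1.0 / child_dim), size=self.params["W"].shape
        )

    def forward(self, u: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._u = u
        return np.einsum("bip,ijpq->bijq", u, self.params["W"])

    def backward(self, du_hat: np.ndarray) -> np.ndarray:
        self.grads["W"] = np.einsum("bip,bijq->ijpq", self._u, du_hat)
        return np.einsum("bijq,ijpq->bip", du_hat, self.params["W"])


class TinyResBackbone(Module):
    """Conv stem + two residual blocks with 2x pooling between stages."""

    def __init__(self):
        super().__init__()
        self.conv = self.add("conv", Conv2d(1, 8, 3))
        self.bn = self.add("bn", BatchNorm2d(8))
        self.relu = self.add("relu", ReLU())
        self.pool1 = self.add("pool1", MaxPool2())
        self.block1 = self.add("block1", ResidualBlock(8, 16))
        self.pool2 = self.add("pool2", MaxPool2())
        self.block2 = self.add("block2", ResidualBlock(16, 32))
        self.out_channels = 32

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h = self.relu.forward(self.bn.forward(self.conv.forward(x, train), train), train)
        h = self.block1.forward(self.pool1.forward(h, train), train)
        h = self.block2.forward(self.pool2.forward(h, train), train)
        return h

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.pool2.backward(self.block2.backward(dout))
        d = self.pool1.backward(self.block1.backward(d))
        return self.conv.backward(self.bn.backward(self.relu.backward(d)))


class CapsuleNet(Module):
    """Backbone (optional) -> primary capsules -> routed digit capsules."""

    def __init__(self, config: ClassifierConfig):
        super().__init__()
        self.config = config
        if config.mode == "image":
            self.backbone = self.add("backbone", TinyResBackbone())
            feat_dim = self.backbone.out_channels
        else:
            self.backbone = None
            feat_dim = config.in_dim
        self.feat_dim = feat_dim
        self.primary = self.add(
            "primary", Linear(feat_dim, config.n_primary * config.primary_dim)
        )
        self.predictor = self.add(
            "predictor",
            CapsPredict(
                config.n_primary, config.n_classes,
                config.primary_dim, config.digit_dim,
            ),
        )
        self.init_params(config.seed)

    def _features(self, x: np.ndarray, train: bool) -> np.ndarray:
        if self.backbone is None:
            return x
        maps = self.backbone.forward(x, train)
        if train:
            self._map_shape = maps.shape
        return maps.mean(axis=(2, 3))

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Return digit-capsule outputs v of shape (batch, n_classes, dim)."""
        feat = self._features(np.asarray(x, dtype=float), train)
        cfg = self.config
        u_raw = self.primary.forward(feat, train).reshape(
            -1, cfg.n_primary, cfg.primary_dim
        )
        u = squash(u_raw)
        u_hat = self.predictor.forward(u, train)
        v, c = dynamic_routing(u_hat, cfg.routing_iters)
        if train:
            s = (c[..., None] * u_hat).sum(axis=1)
            self._cache = (u_raw, c, s)
        return v

    def backward(self, dv: np.ndarray) -> None:
        u_raw, c, s = self._cache
        ds = squash_backward(dv, s)
        du_hat = c[..., None] * ds[:, None, :, :]
        du = self.predictor.backward(du_hat)
        du_raw = squash_backward(du, u_raw)
        dfeat = self.primary.backward(du_raw.reshape(du_raw.shape[0], -1))
        if self.backbone is not None:
            B, C, H, W = self._map_shape
            dmaps = np.broadcast_to(
                dfeat[:, :, None, None] / (H * W), self._map_shape
            )
            self.backbone.backward(np.ascontiguousarray(dmaps))


def build_classifier(config: ClassifierConfig | None = None) -> CapsuleNet:
    """Seeded, deterministically initialized capsule classifier."""
    return CapsuleNet(config or ClassifierConfig())


def deep_features(model: CapsuleNet, image: np.ndarray) -> np.ndarray:
    """Pooled backbone activations for one image (the deep feature block)."""
    if model.backbone is None:
        raise ValueError("deep features require an image-mode classifier")
    maps = model.backbone.forward(
        np.asarray(image, dtype=float)[None, None, :, :], train=False
    )
    return maps[0].mean(axis=(1, 2))


def _bce_loss(v: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Binary cross-entropy on capsule norms as per-class probabilities."""
    norms = np.sqrt((v**2).sum(axis=-1) + 1e-12)
    p = np.clip(norms, 1e-7, 1.0 - 1e-7)
    B = v.shape[0]
    loss = float(-(targets * np.log(p) + (1 - targets) * np.log(1 - p)).sum() / B)
    dnorm = (-(targets / p) + (1 - targets) / (1 - p)) / B
    dv = dnorm[..., None] * (v / norms[..., None])
    return loss, dv


def train_classifier(
    X: np.ndarray | Sequence[LabeledScan],
    y: np.ndarray | None = None,
    config: ClassifierConfig | None = None,
    epochs: int = 20,
    lr: float = 1e-3,
    batch_size: int = 16,
    seed: int = 0,
    model: CapsuleNet | None = None,
) -> tuple[CapsuleNet, list[dict]]:
    """Train on feature rows (X, y) or on LabeledScans (image mode).

    Returns (model, history) where history holds per-epoch mean loss and
    training accuracy.  Deterministic under ``seed``.
    """
    if y is None:
        scans: Sequence[LabeledScan] = X  # type: ignore[assignment]
        Xarr = np.stack([s.image for s in scans])[:, None, :, :]
        yarr = np.array([1 if s.label == "tumor" else 0 for s in scans])
        config = config or ClassifierConfig(mode="image")
    else:
        Xarr = np.asarray(X, dtype=float)
        yarr = np.asarray(y, dtype=int)
        config = config or ClassifierConfig(mode="features", in_dim=Xarr.shape[1])
    if len(np.unique(yarr)) < 2:
        raise ValueError("training data must contain >= 2 classes")
    net = model if model is not None else build_classifier(config)
    cfg = net.config
    onehot = np.eye(cfg.n_classes)[yarr]
    n = len(yarr)
    opt = Adam(net, lr=lr)
    rng = np.random.default_rng(derive_seed(seed, "clftrain"))
    history: list[dict] = []
    loss_fn = margin_loss if cfg.loss == "margin" else _bce_loss
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            net.zero_grad()
            v = net.forward(Xarr[idx], train=True)
            loss, dv = loss_fn(v, onehot[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            net.backward(dv)
            opt.step()
            losses.append(loss)
            norms = np.sqrt((v**2).sum(axis=-1))
            correct += int((norms.argmax(axis=1) == yarr[idx]).sum())
        history.append(
            {"epoch": epoch, "loss": float(np.mean(losses)), "accuracy": correct / n}
        )
    return net, history


def predict(
    model: CapsuleNet, x: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(labels, per-class confidences) for a batch or a single input.

    Confidences are digit-capsule norms in [0, 1); the label is the argmax,
    ties broken toward the lowest class index.
    """
    x = np.asarray(x, dtype=float)
    single = False
    if model.backbone is not None:
        if x.ndim == 2:
            x, single = x[None, None, :, :], True
        elif x.ndim == 3:
            x = x[:, None, :, :]
    elif x.ndim == 1:
        x, single = x[None, :], True
    v = model.forward(x, train=False)
    conf = np.sqrt((v**2).sum(axis=-1))
    labels = conf.argmax(axis=1)
    if single:
        return labels[0], conf[0]
    return labels, conf
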