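"""Recognition model zoo.

Families spanning a no-feature baseline to deep convolutional stacks, all
ending in the same single-layer classifier head (16, 4 or 2 output units):

* ``PIXEL`` — linear classifier on raw flattened pixels.
* ``PCA`` — linear classifier on principal-component scores.
* ``CNN_SHALLOW`` — a single Conv/MaxPool/ReLU/BatchNorm block (the
  shallowest convolutional model; the best performer on phosphene input).
* ``ALEXNET_LIKE`` / ``VGG_LIKE`` / ``RESNET_LIKE`` — scaled-down versions
  of the canonical stacks, behavior-level not weight-level replicas.

Models train on high-resolution faces (optionally mixed with top-quality
phosphene images for the fine-tuned variant) with cross-entropy or
multimargin loss, Adam (lr 1e-4, weight decay 1e-4), batch 16, at most 30
epochs with strict-no-improvement early stopping and plateau learning-rate
reduction, and are scored on phosphene test stimuli as softmax probability
vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from . import nn
from .faces import FaceDataset
from .phosphenes import PIQLevel, histogram_equalize, phosphenize

ARCHS = ("PIXEL", "PCA", "CNN_SHALLOW", "ALEXNET_LIKE", "VGG_LIKE", "RESNET_LIKE")
LOSSES = ("cel", "mml")


@dataclass(frozen=True)
class ModelSpec:
    """Architecture family, loss, head width and instance seed."""

    arch: str = "CNN_SHALLOW"
    loss: str = "cel"
    n_classes: int = 16
    instance_seed: int = 0
    pca_components: int = 128

    def __post_init__(self):
        if self.arch not in ARCHS:
            raise ValueError(f"unsupported architecture {self.arch!r}; known: {ARCHS}")
        if self.loss not in LOSSES:
            raise ValueError(f"unsupported loss {self.loss!r}; known: {LOSSES}")
        if self.n_classes not in (16, 4, 2) and self.n_classes < 2:
            raise ValueError("head needs at least 2 classes")


@dataclass
class TrainConfig:
    """Optimization schedule (defaults follow the study procedure)."""

    max_epochs: int = 30
    early_stop_patience: int = 7  # strict no-improvement epochs on val loss
    batch_size: int = 16
    lr: float = 1e-4
    weight_decay: float = 1e-4
    lr_reduce_factor: float = 1e-2  # on val-accuracy plateau
    lr_reduce_patience: int = 5
    min_lr: float = 1e-8
    finetune_mix: str = "none"  # "none" | "ngb_highest_piq"
    equalize_input: bool = True  # train in the contrast-normalized domain

    def __post_init__(self):
        if not 7 <= self.early_stop_patience <= 10:
            raise ValueError("early-stop patience is specified in the range 7-10")
        if self.finetune_mix not in ("none", "ngb_highest_piq"):
            raise ValueError(f"unknown finetune_mix {self.finetune_mix!r}")


# conv depth per family (used for the depth-ordering contract)
_CONV_DEPTH = {
    "PIXEL": 0,
    "PCA": 0,
    "CNN_SHALLOW": 1,
    "ALEXNET_LIKE": 3,
    "VGG_LIKE": 4,
    "RESNET_LIKE": 4,
}


def conv_depth(arch: str) -> int:
    """Number of convolution layers in the family's feature encoder."""
    return _CONV_DEPTH[arch]


def _block(filters: int, kernel: int, stride: int, pad: int, pool: int | None) -> list[nn.Layer]:
    layers: list[nn.Layer] = [nn.Conv2d(filters, kernel, stride, pad)]
    if pool:
        layers.append(nn.MaxPool2d(pool))
    layers += [nn.ReLU(), nn.BatchNorm2d()]
    return layers


def _backbone(arch: str) -> list[nn.Layer]:
    """Feature encoder (without the classifier head) on 1x128x128 input."""
    if arch in ("PIXEL", "PCA"):
        return [nn.Flatten()]
    if arch == "CNN_SHALLOW":
        # one 5x5 conv, 16 filters, stride 2; aggressive pooling keeps the
        # flattened feature small
        return _block(16, 5, 2, 0, pool=4) + [nn.Flatten()]
    if arch == "ALEXNET_LIKE":
        return (
            _block(16, 7, 4, 0, pool=2)
            + _block(32, 5, 1, 2, pool=2)
            + _block(48, 3, 1, 1, pool=2)
            + [nn.Flatten()]
        )
    if arch == "VGG_LIKE":
        return (
            _block(8, 3, 1, 1, pool=2)
            + _block(16, 3, 1, 1, pool=2)
            + _block(32, 3, 1, 1, pool=2)
            + _block(32, 3, 1, 1, pool=2)
            + [nn.GlobalAvgPool()]
        )
    if arch == "RESNET_LIKE":
        # stem, then a residual block of two conv layers with a 1x1-conv
        # identity shortcut
        body = nn.Sequential(
            _block(16, 3, 1, 1, pool=None) + [nn.Conv2d(16, 3, 1, 1), nn.BatchNorm2d()]
        )
        shortcut = nn.Sequential([nn.Conv2d(16, 1, 1, 0), nn.BatchNorm2d()])
        return (
            _block(16, 5, 2, 2, pool=2)
            + [nn.Residual(body, shortcut), nn.ReLU(), nn.GlobalAvgPool()]
        )
    raise ValueError(f"unsupported architecture {arch!r}")


class Model:
    """A built (possibly trained) recognition model."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.pca: PCA | None = None
        self._rng = np.random.default_rng(spec.instance_seed)
        if spec.arch == "PCA":
            # head alone; the PCA feature map is fitted from training data
            self.net = nn.Sequential([nn.Dense(spec.n_classes)])
            in_shape: tuple = (spec.pca_components,)
        else:
            self.net = nn.Sequential(_backbone(spec.arch) + [nn.Dense(spec.n_classes)])
            in_shape = (1, 128, 128)
        self.net.init_shapes(self._rng, in_shape)

    # -- feature path --------------------------------------------------
    def _features(self, images: np.ndarray) -> np.ndarray:
        x = images.astype(np.float64) / 255.0
        if self.spec.arch == "PCA":
            if self.pca is None:
                raise RuntimeError("PCA model not fitted; call train_model first")
            return self.pca.transform(x.reshape(len(x), -1))
        return x[:, None, :, :]

    def logits(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(self._features(images), train=train)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return nn.softmax(self.logits(images))

    def head_param_count(self) -> int:
        dense = self.net.layers[-1]
        return dense.w.size + dense.b.size


def build_model(spec: ModelSpec) -> Model:
    """Instantiate a model family with seeded initialization."""
    return Model(spec)


def fit_pca_features(train_images: np.ndarray, k: int) -> PCA:
    """Fit a k-component PCA feature map on flattened images.

    Returns the fitted transformer (mean, components and explained-variance
    ratios accessible as attributes).
    """
    x = np.asarray(train_images, dtype=np.float64).reshape(len(train_images), -1) / 255.0
    bound = min(x.shape)
    if k > bound:
        raise ValueError(f"k={k} exceeds min(n_samples, n_features)={bound}")
    return PCA(n_components=k, svd_solver="full").fit(x)


def _phosphenize_batch(images: np.ndarray, piq: PIQLevel, mode: str) -> np.ndarray:
    return np.stack([phosphenize(im, piq, mode) for im in images])


def train_model(
    spec: ModelSpec,
    data: FaceDataset,
    cfg: TrainConfig | None = None,
) -> tuple[Model, pd.DataFrame]:
    """Train one model instance; returns (model, per-epoch history).

    Deterministic given ``spec.instance_seed`` (weights, shuffling).  With
    ``cfg.finetune_mix == "ngb_highest_piq"`` half of the training images
    are replaced by their highest-quality phosphene renderings (128 px,
    16 gray levels, square-bitmap mode), the mixed-resolution regime of the
    fine-tuned variant.
    """
    cfg = cfg or TrainConfig()
    train, val = data.subset("train"), data.subset("val")
    if len(train) == 0 or len(val) == 0:
        raise ValueError("dataset must provide non-empty train and val splits")

    x_train, y_train = train.images, train.labels
    x_val, y_val = val.images, val.labels
    if cfg.equalize_input:
        # phosphene stimuli are histogram-equalized as their first stage;
        # training in the same contrast-normalized domain keeps the model's
        # input distribution consistent between training and testing
        x_train = np.stack([histogram_equalize(im) for im in x_train])
        x_val = np.stack([histogram_equalize(im) for im in x_val])
    if cfg.finetune_mix == "ngb_highest_piq":
        half = len(x_train) // 2
        order = np.random.default_rng(spec.instance_seed).permutation(len(x_train))
        mixed = x_train.copy()
        mixed[order[:half]] = _phosphenize_batch(
            x_train[order[:half]], PIQLevel(128, 16), "ngb"
        )
        x_train = mixed

    model = build_model(spec)
    if spec.arch == "PCA":
        model.pca = fit_pca_features(x_train, spec.pca_components)

    loss_fn = nn.LOSSES[spec.loss]
    opt = nn.Adam(model.net.params(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng([spec.instance_seed, 1])

    best_val_loss = np.inf
    best_val_acc = -np.inf
    best_state = model.net.state()
    stall_loss = 0
    stall_acc = 0
    rows = []
    stop_epoch = None

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(x_train))
        tl, ta, nb = 0.0, 0.0, 0
        for s in range(0, len(order), cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            logits = model.logits(x_train[idx], train=True)
            loss, grad = loss_fn(logits, y_train[idx])
            model.net.backward(grad)
            opt.step()
            tl += loss * len(idx)
            ta += (logits.argmax(1) == y_train[idx]).sum()
            nb += len(idx)
        val_logits = model.logits(x_val)
        val_loss, _ = loss_fn(val_logits, y_val)
        val_acc = float((val_logits.argmax(1) == y_val).mean())
        rows.append(
            dict(
                epoch=epoch,
                train_loss=tl / nb,
                train_acc=ta / nb,
                val_loss=float(val_loss),
                val_acc=val_acc,
                lr=opt.lr,
            )
        )

        # strict-no-improvement early stopping on validation loss
        if val_loss < best_val_loss:
            best_val_loss = val_loss
            best_state = model.net.state()
            stall_loss = 0
        else:
            stall_loss += 1
            if stall_loss >= cfg.early_stop_patience:
                stop_epoch = epoch
                break
        # plateau learning-rate reduction on validation accuracy
        if val_acc > best_val_acc:
            best_val_acc = val_acc
            stall_acc = 0
        else:
            stall_acc += 1
            if stall_acc >= cfg.lr_reduce_patience:
                opt.lr = max(opt.lr * cfg.lr_reduce_factor, cfg.min_lr)
                stall_acc = 0

    model.net.load_state(best_state)
    history = pd.DataFrame(rows)
    history.attrs["stop_epoch"] = stop_epoch
    return model, history


def predict_probs(
    model: Model,
    images: np.ndarray,
    meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Score images; one row per image with a softmax probability vector.

    ``meta`` (optional) supplies per-image annotation columns (true class,
    PIQ level, condition, ...) carried through to the output.
    """
    images = np.asarray(images)
    if images.ndim != 3 or images.shape[1:] != (128, 128):
        raise ValueError(f"expected (N, 128, 128) images, got {images.shape}")
    probs = model.predict_proba(images)
    out = pd.DataFrame(
        probs, columns=[f"prob_{c}" for c in range(probs.shape[1])]
    )
    out.insert(0, "image_id", np.arange(len(out)))
    if meta is not None:
        if len(meta) != len(out):
            raise ValueError("meta length does not match image count")
        out = pd.concat([out, meta.reset_index(drop=True)], axis=1)
    return out


def restrict_probs(probs: np.ndarray, options: Iterable[int]) -> np.ndarray:
    """Renormalize probability vectors over an option subset.

    Emulates presenting the observer only ``options`` choices (the 4-way
    protocol) from a wider head: non-option probabilities are masked out
    and the rest renormalized.  Never decreases the probability of an
    option that is kept.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    options = list(options)
    mask = np.zeros(probs.shape[1], dtype=bool)
    mask[options] = True
    masked = probs * mask
    total = masked.sum(axis=1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("no probability mass on the kept options")
    return masked / total


def train_ensemble(
    spec: ModelSpec,
    data: FaceDataset,
    cfg: TrainConfig | None = None,
    n_instances: int = 5,
) -> list[tuple[Model, pd.DataFrame]]:
    """Train independent instances differing only in instance_seed."""
    return [
        train_model(replace(spec, instance_seed=spec.instance_seed + i), data, cfg)
        for i in range(n_instances)
    ]
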