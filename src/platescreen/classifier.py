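"""Crop-level classification behind a pluggable backend contract.

The screening pipeline only requires an object that can be fit on labelled
crops and emit class probabilities; any backend honouring
:class:`ClassifierBackend` plugs in (a fine-tuned CNN would, via an adapter).
The reference backend shipped here is deliberately lightweight and fully
deterministic: each crop is summarised by a 22-dimensional morphology
feature vector (per-channel intensity statistics, foreground geometry,
object circularity 4*pi*A/P^2 and skeleton length per object as a
ramification proxy, plus the microglia/neuron foreground ratio), and a
multinomial logistic regression is trained on standardized features with
mini-batch gradient descent under the screening schedule (batch size 8,
learning rate x0.25 every 5 epochs, categorical cross-entropy).

Features are invariant to horizontal/vertical flips and 90-degree
rotations, so geometric augmentation never moves a crop in feature space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import remove_small_objects, skeletonize

from .imaging import CropImage
from .preprocessing import ChannelStats

__all__ = [
    "ClassifierConfig",
    "TrainedModel",
    "ClassifierBackend",
    "extract_features",
    "feature_matrix",
    "train_classifier",
    "predict_proba",
    "predict_class",
    "predict_binary",
    "cross_entropy",
    "FEATURE_NAMES",
]

_MIN_OBJECT_PX = 8

_PER_CHANNEL = (
    "mean_intensity", "intensity_sd", "foreground_fraction",
    "object_count", "mean_object_area", "mean_circularity",
    "skeleton_len_per_object",
)
FEATURE_NAMES = tuple(
    f"{ch}_{name}" for ch in ("microglia", "neuron", "nucleus") for name in _PER_CHANNEL
) + ("microglia_neuron_fg_ratio",)


@dataclass(frozen=True)
class ClassifierConfig:
    """Training hyperparameters for the reference backend."""

    n_classes: int = 6
    batch_size: int = 8
    lr: float = 0.1
    lr_decay: float = 0.25
    decay_every: int = 5
    epochs: int = 20
    l2: float = 1e-4
    seed: int = 0
    loss: str = "categorical_cross_entropy"

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def lr_at(self, epoch: int) -> float:
        return self.lr * self.lr_decay ** (epoch // self.decay_every)


def _dihedral_canonical(mask: np.ndarray) -> np.ndarray:
    """Canonical representative of a mask under flips/rot90.

    Skeletonization by iterative thinning is not exactly isotropic, so the
    skeleton is always computed on this canonical orientation; the feature
    becomes invariant to the dihedral group by construction.
    """
    variants = []
    m = mask
    for _ in range(4):
        variants.append(m)
        variants.append(m[:, ::-1])
        m = np.rot90(m)
    variants = [np.ascontiguousarray(v) for v in variants]
    keys = [(v.shape, v.tobytes()) for v in variants]
    return variants[keys.index(min(keys))]


def _channel_features(px01: np.ndarray) -> list[float]:
    mean = float(px01.mean())
    sd = float(px01.std())
    if px01.max() - px01.min() <= 1e-12:
        return [mean, sd, 0.0, 0.0, 0.0, 0.0, 0.0]
    fg = px01 > threshold_otsu(px01)
    fg = remove_small_objects(fg, max_size=_MIN_OBJECT_PX - 1)
    frac = float(fg.mean())
    if not fg.any():
        return [mean, sd, 0.0, 0.0, 0.0, 0.0, 0.0]
    lbl = cc_label(fg)
    props = regionprops(lbl)
    areas = [p.area for p in props]
    circs = [4.0 * np.pi * p.area / p.perimeter ** 2 for p in props if p.perimeter > 0]
    skel = skeletonize(_dihedral_canonical(fg))
    skel_per_obj = float(skel.sum()) / len(props)
    return [
        mean, sd, frac, float(len(props)), float(np.mean(areas)),
        float(np.mean(circs)) if circs else 0.0, skel_per_obj,
    ]


def extract_features(c: CropImage) -> np.ndarray:
    """22-dimensional morphology summary of one crop (deterministic)."""
    px = np.asarray(c.pixels)
    if px.size == 0:
        raise ValueError("empty image")
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError(f"expected HxWx3 crop, got shape {px.shape}")
    px01 = px.astype(np.float64) / 255.0 if px.dtype == np.uint8 else px.astype(np.float64)
    feats: list[float] = []
    fracs = []
    for ch in range(3):
        f = _channel_features(px01[:, :, ch])
        fracs.append(f[2])
        feats.extend(f)
    feats.append(fracs[0] / (fracs[1] + 1e-6))  # microglia / neuron foreground
    out = np.asarray(feats, dtype=np.float64)
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite feature encountered")
    return out


def feature_matrix(crops: Sequence[CropImage]) -> np.ndarray:
    return np.vstack([extract_features(c) for c in crops])


@runtime_checkable
class ClassifierBackend(Protocol):
    """Minimal contract an external backend must satisfy."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ClassifierBackend": ...

    def predict_proba(self, X: np.ndarray) -> np.ndarray: ...


@dataclass
class TrainedModel:
    """A fitted crop classifier: weights + the statistics needed at inference."""

    weights: np.ndarray                  # (d + 1, k) including bias row
    feat_mean: np.ndarray
    feat_sd: np.ndarray
    classes: np.ndarray
    config: ClassifierConfig
    backend: str = "reference"
    channel_stats: ChannelStats | None = None
    loss_history: list = field(default_factory=list)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def save(self, path: Path) -> None:
        d = {
            "backend": self.backend,
            "weights": self.weights.tolist(),
            "feat_mean": self.feat_mean.tolist(),
            "feat_sd": self.feat_sd.tolist(),
            "classes": self.classes.tolist(),
            "config": self.config.__dict__,
            "channel_stats": None if self.channel_stats is None else {
                "mu": list(self.channel_stats.mu),
                "sigma": list(self.channel_stats.sigma),
                "n_pixels": self.channel_stats.n_pixels,
            },
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def load(cls, path: Path) -> "TrainedModel":
        d = json.loads(Path(path).read_text())
        cs = d["channel_stats"]
        return cls(
            weights=np.asarray(d["weights"]),
            feat_mean=np.asarray(d["feat_mean"]),
            feat_sd=np.asarray(d["feat_sd"]),
            classes=np.asarray(d["classes"]),
            config=ClassifierConfig(**d["config"]),
            backend=d["backend"],
            channel_stats=None if cs is None else ChannelStats(
                mu=tuple(cs["mu"]), sigma=tuple(cs["sigma"]), n_pixels=cs["n_pixels"]),
        )


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(P: np.ndarray, Y: np.ndarray) -> float:
    """Mean categorical cross-entropy of probabilities P vs one-hot Y."""
    return float(-(Y * np.log(np.clip(P, 1e-12, None))).sum(axis=1).mean())


def _as_X(crops_or_X) -> np.ndarray:
    arr = np.asarray(crops_or_X) if isinstance(crops_or_X, np.ndarray) else None
    if arr is not None and arr.ndim == 2 and arr.dtype != object:
        return arr.astype(np.float64)
    return feature_matrix(list(crops_or_X))


def train_classifier(
    crops_or_X,
    labels: Sequence[int],
    cfg: ClassifierConfig | None = None,
    channel_stats: ChannelStats | None = None,
    shuffle: bool = True,
) -> TrainedModel:
    """Fit the reference multinomial-logistic backend.

    Accepts either a sequence of crops (features extracted here) or a
    precomputed (n, 22) feature matrix.  Feature standardization statistics
    come from this training set only.  Deterministic under a fixed seed.
    """
    cfg = cfg or ClassifierConfig()
    X = _as_X(crops_or_X)
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("labels must align with crops")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes present")

    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 1e-9, sd, 1.0)
    Xs = (X - mean) / sd
    Xb = np.hstack([Xs, np.ones((Xs.shape[0], 1))])

    k = len(classes)
    class_pos = {c: i for i, c in enumerate(classes)}
    Y = np.zeros((len(y), k))
    Y[np.arange(len(y)), [class_pos[c] for c in y]] = 1.0

    rng = np.random.default_rng(cfg.seed)
    W = np.zeros((Xb.shape[1], k))
    n = Xb.shape[0]
    history = []
    for epoch in range(cfg.epochs):
        lr = cfg.lr_at(epoch)
        order = rng.permutation(n) if shuffle else np.arange(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            P = _softmax(Xb[idx] @ W)
            grad = Xb[idx].T @ (P - Y[idx]) / len(idx) + cfg.l2 * W
            W -= lr * grad
        history.append(cross_entropy(_softmax(Xb @ W), Y))

    return TrainedModel(
        weights=W, feat_mean=mean, feat_sd=sd, classes=classes, config=cfg,
        channel_stats=channel_stats, loss_history=history,
    )


def _proba_from_X(m: TrainedModel, X: np.ndarray) -> np.ndarray:
    if X.shape[1] != m.weights.shape[0] - 1:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model "
            f"({m.weights.shape[0] - 1}); channel-role or feature mismatch")
    Xs = (X - m.feat_mean) / m.feat_sd
    Xb = np.hstack([Xs, np.ones((Xs.shape[0], 1))])
    return _softmax(Xb @ m.weights)


def predict_proba(m: TrainedModel, c) -> np.ndarray:
    """Class probability vector(s); rows sum to 1.

    ``c`` may be one crop, a sequence of crops, one feature vector, or a
    feature matrix.  For a single input a 1-D probability vector is
    returned, otherwise an (n, k) matrix.
    """
    if isinstance(c, CropImage):
        return _proba_from_X(m, extract_features(c)[None, :])[0]
    arr = np.asarray(c) if isinstance(c, np.ndarray) else None
    if arr is not None and arr.ndim == 1:
        return _proba_from_X(m, arr[None, :])[0]
    if arr is not None and arr.ndim == 2:
        return _proba_from_X(m, arr)
    return _proba_from_X(m, feature_matrix(list(c)))


def predict_class(m: TrainedModel, c):
    """argmax class label(s) under :func:`predict_proba`."""
    p = predict_proba(m, c)
    if p.ndim == 1:
        return m.classes[int(np.argmax(p))]
    return m.classes[np.argmax(p, axis=1)]


def predict_binary(m: TrainedModel, c, positive: int = 1) -> int | np.ndarray:
    """Binary screening verdict: 1 = control-like, 0 = LPS-like.

    Requires a 2-class model trained with label 1 for control crops and
    label 0 for (mild) LPS crops.
    """
    if m.n_classes != 2:
        raise ValueError("predict_binary requires a binary model")
    pred = predict_class(m, c)
    return (np.asarray(pred) == positive).astype(int) if np.ndim(pred) else int(pred == positive)
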