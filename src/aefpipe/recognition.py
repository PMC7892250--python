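"""Binary AEF-vs-noise classification of scalp topography images.

A compact scratch-trained convolutional network (the ``compact-scratch``
backbone) classifies 224 x 224 x 3 energy topomaps into ``aef`` vs ``noise``,
with the training configuration used for transfer-learning an
inception-style network: final dropout 0.6, learning rate 1e-4, 10 epochs,
80/20 stratified train/validation split. A ``pretrained-inception-style``
backbone name is reserved in the spec of the classifier; it requires
pretrained weights and a deep-learning runtime, neither of which this package
ships, so selecting it raises.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _convnet
from .topomap import TopoImage

BACKBONES = ("compact-scratch", "pretrained-inception-style")


@dataclass
class ClassifierSpec:
    """Training configuration for the AEF-vs-noise classifier."""

    backbone: str = "compact-scratch"
    dropout_prob: float = 0.6
    learning_rate: float = 1e-4
    epochs: int = 10
    val_fraction: float = 0.2
    batch_size: int = 16
    seed: int = 0
    class_labels: tuple[str, str] = ("aef", "noise")

    def __post_init__(self) -> None:
        if self.backbone not in BACKBONES:
            raise ValueError(f"backbone must be one of {BACKBONES}")
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must be in [0, 1)")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if len(self.class_labels) != 2:
            raise ValueError("binary classifier: exactly 2 class labels")


@dataclass
class LabeledImages:
    """An in-memory image dataset: (N, H, W, 3) pixels plus string labels."""

    images: np.ndarray
    labels: list[str]
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        if self.images.ndim != 4:
            raise ValueError("images must be (N, H, W, 3)")
        if len(self.labels) != self.images.shape[0]:
            raise ValueError("labels must align with images")
        if not self.ids:
            self.ids = [f"img{i:04d}" for i in range(len(self.labels))]

    def __len__(self) -> int:
        return self.images.shape[0]

    @staticmethod
    def from_topoimages(images: list[TopoImage], labels: list[str], ids=None) -> "LabeledImages":
        arr = np.stack([img.pixels for img in images]).astype(np.float32)
        return LabeledImages(images=arr, labels=list(labels), ids=list(ids) if ids else [])


@dataclass
class TrainedModel:
    """A fitted classifier: network parameters, spec and training history."""

    net: _convnet.ConvNet
    spec: ClassifierSpec
    training_history: list[dict] = field(default_factory=list)

    def save(self, path) -> None:
        state = self.net.state_dict()
        np.savez(
            path,
            **state,
            __spec=json.dumps(asdict(self.spec)),
            __history=json.dumps(self.training_history),
        )

    @staticmethod
    def load(path) -> "TrainedModel":
        with np.load(path, allow_pickle=False) as d:
            spec_d = json.loads(str(d["__spec"]))
            spec_d["class_labels"] = tuple(spec_d["class_labels"])
            history = json.loads(str(d["__history"]))
            net = _convnet.ConvNet.from_state_dict({k: d[k] for k in d.files if not k.startswith("__spec") and not k.startswith("__history")})
        return TrainedModel(net=net, spec=ClassifierSpec(**spec_d), training_history=history)


def split_dataset(
    dataset: LabeledImages, val_fraction: float = 0.2, seed: int = 0
) -> tuple[LabeledImages, LabeledImages]:
    """Stratified random train/validation split, deterministic given seed.

    Within each class, ``floor(n_class * val_fraction)`` items (at least one)
    go to validation; the rest to training. The two sides partition the
    dataset exactly.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if not 0 < val_fraction < 1:
        raise ValueError("val_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    labels = np.asarray(dataset.labels)
    train_idx: list[int] = []
    val_idx: list[int] = []
    for cls in sorted(set(dataset.labels)):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 items")
        idx = rng.permutation(idx)
        n_val = max(1, math.floor(idx.size * val_fraction))
        val_idx.extend(idx[:n_val].tolist())
        train_idx.extend(idx[n_val:].tolist())
    train_idx.sort()
    val_idx.sort()

    def subset(ix: list[int]) -> LabeledImages:
        return LabeledImages(
            images=dataset.images[ix],
            labels=[dataset.labels[i] for i in ix],
            ids=[dataset.ids[i] for i in ix],
        )

    return subset(train_idx), subset(val_idx)


def train_classifier(
    train_set: LabeledImages, val_set: LabeledImages, spec: ClassifierSpec
) -> TrainedModel:
    """Train the binary image classifier per the spec.

    With ``epochs=0`` the returned model is valid but untrained (random
    initialization) — useful as a chance-level baseline.
    """
    if spec.backbone == "pretrained-inception-style":
        raise NotImplementedError(
            "the pretrained-inception-style backbone requires pretrained weights "
            "and a deep-learning runtime; use backbone='compact-scratch'"
        )
    for s in (train_set, val_set):
        if s.images.shape[1] != s.images.shape[2]:
            raise ValueError("images must be square")
    if train_set.images.shape[1:] != val_set.images.shape[1:]:
        raise ValueError("train/validation image shapes differ")
    classes = list(spec.class_labels)
    for s, name in ((train_set, "train"), (val_set, "validation")):
        missing = set(classes) - set(s.labels)
        if missing:
            raise ValueError(f"{name} set lacks class(es) {sorted(missing)}")

    cls_to_idx = {c: i for i, c in enumerate(classes)}
    y_train = np.array([cls_to_idx[lb] for lb in train_set.labels])
    y_val = np.array([cls_to_idx[lb] for lb in val_set.labels])

    rng = np.random.default_rng(spec.seed)
    net = _convnet.ConvNet(
        input_size=train_set.images.shape[1], dropout=spec.dropout_prob, rng=rng
    )
    history = _convnet.train(
        net,
        train_set.images,
        y_train,
        val_set.images,
        y_val,
        epochs=spec.epochs,
        lr=spec.learning_rate,
        batch_size=spec.batch_size,
        seed=spec.seed,
    )
    return TrainedModel(net=net, spec=spec, training_history=history)


def classify(model: TrainedModel, image: TopoImage | np.ndarray) -> tuple[str, dict[str, float]]:
    """Classify one image; returns (label, {class: probability})."""
    pixels = image.pixels if isinstance(image, TopoImage) else np.asarray(image)
    if pixels.ndim != 3 or pixels.shape[0] != pixels.shape[1] or pixels.shape[2] != 3:
        raise ValueError("image must be (size, size, 3)")
    if pixels.shape[0] != model.net.input_size:
        raise ValueError(
            f"image size {pixels.shape[0]} != model input size {model.net.input_size}"
        )
    probs = model.net.predict_proba(pixels)
    classes = model.spec.class_labels
    label = classes[int(np.argmax(probs))]
    return label, {c: float(p) for c, p in zip(classes, probs)}


def evaluate(model: TrainedModel, dataset: LabeledImages) -> dict:
    """Accuracy and 2x2 confusion counts on a labeled set."""
    if len(dataset) == 0:
        raise ValueError("empty evaluation set")
    probs = model.net.predict_proba(dataset.images)
    classes = model.spec.class_labels
    pred = [classes[i] for i in probs.argmax(axis=1)]
    confusion = {t: {p: 0 for p in classes} for t in classes}
    correct = 0
    for truth, p in zip(dataset.labels, pred):
        confusion[truth][p] += 1
        correct += truth == p
    return {
        "accuracy": correct / len(dataset),
        "n": len(dataset),
        "confusion": confusion,
        "predictions": pred,
    }
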