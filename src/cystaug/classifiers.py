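"""Grayscale AlexNet and VGG16: layer plans, shape inference, training.

The two architectures are fixed, single-channel adaptations of the classic
networks with a four-class softmax head.  Shape inference over a plan is pure
arithmetic on the convolution output-size formula and is testable without
allocating any weights; building a network realizes the plan with trainable
parameters.  A "reduced" profile (28×28 input, narrow layers) is provided for
CPU-scale end-to-end runs and is never a stand-in for the full plans in
architecture checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

from . import nn
from .convmath import ConvSpec, conv_output_size
from .dataset import ImageDataset

__all__ = [
    "LayerSpec",
    "TrainSpec",
    "ShapeMismatchError",
    "alexnet_plan",
    "vgg16_plan",
    "infer_shapes",
    "build_alexnet",
    "build_vgg16",
    "train_classifier",
    "predict_scores",
    "Classifier",
]

logger = logging.getLogger(__name__)

SOLVER_NAMES = ("Adam", "RMSprop", "AdaDelta", "AdaMax", "AdaGrad")
BATCH_SIZES = (4, 8, 16, 32)


@dataclass(frozen=True)
class LayerSpec:
    """One row of an architecture table.

    kind : "conv" | "pool" | "fully_connected" | "softmax_output".
    repeat : number of identical conv layers stacked in this row.
    feature_maps / units : output width (channels, or neurons for FC rows).
    kernel, stride, padding : spatial parameters (conv/pool rows only).
    expected_size : declared spatial output size; checked by infer_shapes.
    """

    kind: str
    feature_maps: int = 0
    kernel: int = 0
    stride: int = 1
    padding: int | str = 0
    repeat: int = 1
    units: int = 0
    activation: str = "ReLU"
    expected_size: int | None = None


@dataclass(frozen=True)
class TrainSpec:
    """Hyperparameters for one grid point of classifier training."""

    solver: str = "Adam"
    batch_size: int = 16
    epochs: int = 5
    seed: int = 0
    learning_rate: float | None = None  # None -> solver default

    def __post_init__(self) -> None:
        if self.solver not in SOLVER_NAMES:
            raise ValueError(f"solver must be one of {SOLVER_NAMES}")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


class ShapeMismatchError(ValueError):
    """A plan's declared layer size disagrees with the size formula."""


def alexnet_plan() -> list[LayerSpec]:
    """The nine-layer grayscale AlexNet: 227×227×1 in, 4-class softmax out."""
    return [
        LayerSpec("conv", 96, 11, 4, 0, expected_size=55),
        LayerSpec("pool", 96, 3, 2, 0, expected_size=27),
        LayerSpec("conv", 256, 5, 1, 2, expected_size=27),
        LayerSpec("pool", 256, 3, 2, 0, expected_size=13),
        LayerSpec("conv", 384, 3, 1, 1, expected_size=13),
        LayerSpec("conv", 384, 3, 1, 1, expected_size=13),
        LayerSpec("conv", 256, 3, 1, 1, expected_size=13),
        LayerSpec("pool", 256, 3, 2, 0, expected_size=6),
        LayerSpec("fully_connected", units=4096),
        LayerSpec("fully_connected", units=4096),
        LayerSpec("softmax_output", units=4),
    ]


def vgg16_plan() -> list[LayerSpec]:
    """Grayscale VGG16 per its published table: 224×224×1 in, softmax-4 out.

    Block structure follows the size column of the table (2-2-2-3-3 convs of
    3×3, five 3×3 stride-2 pools), ending at 7×7×512, flatten width 25 088.
    """
    return [
        LayerSpec("conv", 64, 3, 1, 1, repeat=2, expected_size=224),
        LayerSpec("pool", 64, 3, 2, "same", expected_size=112),
        LayerSpec("conv", 128, 3, 1, 1, repeat=2, expected_size=112),
        LayerSpec("pool", 128, 3, 2, "same", expected_size=56),
        LayerSpec("conv", 256, 3, 1, 1, repeat=2, expected_size=56),
        LayerSpec("pool", 256, 3, 2, "same", expected_size=28),
        LayerSpec("conv", 512, 3, 1, 1, repeat=3, expected_size=28),
        LayerSpec("pool", 512, 3, 2, "same", expected_size=14),
        LayerSpec("conv", 512, 3, 1, 1, repeat=3, expected_size=14),
        LayerSpec("pool", 512, 3, 2, "same", expected_size=7),
        LayerSpec("fully_connected", units=4096),
        LayerSpec("fully_connected", units=4096),
        LayerSpec("softmax_output", units=4),
    ]


def _reduced_plan() -> list[LayerSpec]:
    """Narrow 28×28 profile for CPU-scale training; never used for the
    full-architecture shape checks."""
    return [
        LayerSpec("conv", 8, 3, 1, "same", expected_size=28),
        LayerSpec("pool", 8, 2, 2, 0, expected_size=14),
        LayerSpec("conv", 16, 3, 1, "same", expected_size=14),
        LayerSpec("pool", 16, 2, 2, 0, expected_size=7),
        LayerSpec("fully_connected", units=32),
        LayerSpec("softmax_output", units=4),
    ]


def infer_shapes(plan: Sequence[LayerSpec], input_size: int) -> list[tuple]:
    """Walk a plan, computing every layer's output shape from the size formula.

    Returns the chain of (size, size, channels) / (units,) shapes, starting at
    the input.  Raises :class:`ShapeMismatchError` naming the first layer whose
    declared ``expected_size`` disagrees with the arithmetic.
    """
    size, channels = input_size, 1
    chain: list[tuple] = [(size, size, channels)]
    flattened = False
    for idx, layer in enumerate(plan):
        if layer.kind in ("conv", "pool"):
            if flattened:
                raise ShapeMismatchError(f"layer {idx}: spatial layer after flatten")
            for _ in range(layer.repeat):
                size = conv_output_size(
                    ConvSpec(L=size, F=layer.kernel, S=layer.stride, P=layer.padding)
                )
            if layer.kind == "conv":
                channels = layer.feature_maps
            if layer.expected_size is not None and size != layer.expected_size:
                raise ShapeMismatchError(
                    f"layer {idx} ({layer.kind}): computed size {size} != declared "
                    f"{layer.expected_size}"
                )
            chain.append((size, size, channels))
        elif layer.kind in ("fully_connected", "softmax_output"):
            if not flattened:
                chain.append((size * size * channels,))
                flattened = True
            chain.append((layer.units,))
        else:
            raise ValueError(f"unknown layer kind {layer.kind!r}")
    return chain


def flatten_width(plan: Sequence[LayerSpec], input_size: int) -> int:
    """Element count entering the first fully connected layer."""
    chain = infer_shapes(plan, input_size)
    for shape in chain:
        if len(shape) == 1:
            return shape[0]
    raise ValueError("plan has no fully connected layer")


class Classifier:
    """Realized network for a plan, with softmax scoring."""

    def __init__(self, plan: Sequence[LayerSpec], input_size: int, seed: int = 0,
                 name: str = "cnn") -> None:
        self.plan = list(plan)
        self.input_size = input_size
        self.name = name
        self.shape_chain = infer_shapes(plan, input_size)
        rng = np.random.default_rng(seed)
        layers: list[nn.Layer] = []
        size, channels = input_size, 1
        flattened = False
        width = 0
        for layer in self.plan:
            if layer.kind == "conv":
                for _ in range(layer.repeat):
                    layers.append(
                        nn.Conv2D(channels, layer.feature_maps, layer.kernel,
                                  layer.stride, layer.padding, rng)
                    )
                    layers.append(nn.ReLU())
                    size = conv_output_size(
                        ConvSpec(L=size, F=layer.kernel, S=layer.stride, P=layer.padding)
                    )
                    channels = layer.feature_maps
            elif layer.kind == "pool":
                if layer.padding == "same":
                    # stride-2 'same' pooling == valid pooling after 1px pad
                    pad = max(layer.kernel - layer.stride, 0)
                    layers.append(_PadLayer(pad))
                    size_p = size + pad
                else:
                    size_p = size
                layers.append(nn.MaxPool2D(layer.kernel, layer.stride))
                size = conv_output_size(
                    ConvSpec(L=size, F=layer.kernel, S=layer.stride, P=layer.padding)
                )
            else:
                if not flattened:
                    layers.append(nn.Flatten())
                    width = size * size * channels
                    flattened = True
                layers.append(nn.Dense(width, layer.units, rng))
                if layer.kind == "fully_connected":
                    layers.append(nn.ReLU())
                width = layer.units
        self.net = nn.Sequential(layers)
        self.n_classes = self.plan[-1].units

    def logits(self, images: np.ndarray, training: bool = False) -> np.ndarray:
        x = images.astype(np.float32)
        if x.ndim == 3:
            x = x[:, :, :, None]
        return self.net.forward(x, training=training)

    def scores(self, images: np.ndarray) -> np.ndarray:
        return nn.softmax(self.logits(images))


class _PadLayer(nn.Layer):
    """Symmetric-end zero pad used to emulate 'same' pooling."""

    def __init__(self, pad: int) -> None:
        super().__init__()
        self.pad = pad

    def forward(self, x, training=False):
        p = self.pad
        return np.pad(x, ((0, 0), (0, p), (0, p), (0, 0)))

    def backward(self, dout):
        p = self.pad
        return dout[:, : dout.shape[1] - p, : dout.shape[2] - p, :]


def build_alexnet(reduced: bool = False, seed: int = 0) -> Classifier:
    """Grayscale AlexNet (227×227 input) or its reduced 28×28 profile."""
    if reduced:
        return Classifier(_reduced_plan(), 28, seed=seed, name="alexnet_reduced")
    return Classifier(alexnet_plan(), 227, seed=seed, name="alexnet")


def build_vgg16(reduced: bool = False, seed: int = 0) -> Classifier:
    """Grayscale VGG16 (224×224 input) or its reduced 28×28 profile."""
    if reduced:
        return Classifier(_reduced_plan(), 28, seed=seed, name="vgg16_reduced")
    return Classifier(vgg16_plan(), 224, seed=seed, name="vgg16")


def resize_images(images: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize of an (n, h, w) stack to (n, size, size)."""
    if images.shape[1] == size and images.shape[2] == size:
        return images
    out = np.empty((len(images), size, size), dtype=np.float32)
    for i, img in enumerate(images):
        out[i] = _sk_resize(img, (size, size), order=1, anti_aliasing=False,
                            preserve_range=True)
    return out


def train_classifier(model: Classifier, train: ImageDataset, spec: TrainSpec) -> Classifier:
    """Train ``model`` in place on ``train`` with the given hyperparameters.

    Images are bilinearly resized to the network input size; optimization is
    minibatch softmax cross-entropy with the named solver.  A class absent
    from the training data is logged as a warning but training proceeds.
    """
    if len(train) == 0:
        raise ValueError("training dataset is empty")
    present = set(np.unique(train.labels).tolist())
    for c in range(model.n_classes):
        if c not in present:
            logger.warning("class %d absent from training data", c)
    x = resize_images(train.images, model.input_size)
    y = train.labels
    opt = nn.make_optimizer(spec.solver, spec.learning_rate)
    rng = np.random.default_rng(spec.seed)
    model.history = []
    for epoch in range(1, spec.epochs + 1):
        order = rng.permutation(len(x))
        total, correct, batches = 0.0, 0, 0
        for start in range(0, len(x), spec.batch_size):
            idx = order[start : start + spec.batch_size]
            logits = model.logits(x[idx], training=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, y[idx])
            model.net.backward(dlogits)
            opt.step(model.net)
            total += loss
            correct += int((logits.argmax(axis=1) == y[idx]).sum())
            batches += 1
        model.history.append(
            {"epoch": epoch, "loss": total / batches, "accuracy": correct / len(x)}
        )
    return model


def predict_scores(model: Classifier, images: np.ndarray | ImageDataset) -> np.ndarray:
    """Per-image class probabilities (rows on the simplex), batched."""
    pixels = images.images if isinstance(images, ImageDataset) else np.asarray(images)
    if len(pixels) == 0:
        return np.zeros((0, model.n_classes), dtype=np.float32)
    x = resize_images(pixels, model.input_size)
    out = []
    for start in range(0, len(x), 256):
        out.append(model.scores(x[start : start + 256]))
    return np.concatenate(out)
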