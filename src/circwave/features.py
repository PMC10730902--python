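"""The sub-band feature-extraction CNN.

Four blocks of conv(3x3, zero-padded) -> batch-norm -> ReLU -> 2x2 max-pool
with 25/50/100/200 filters take a 64x64xC sub-band stack down the spatial
path 64 -> 32 -> 16 -> 8 -> 4; the final 4x4x200 block output is flattened
into a 3200-dimensional feature vector, independent of the input channel
count.  During training a temporary softmax head sits on the features; after
training the head is discarded and the frozen network serves as a feature
extractor for the downstream classifier heads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn

FEATURE_DIM = 3200  # 4 * 4 * 200
INPUT_SIDE = 64


@dataclass(frozen=True)
class CnnConfig:
    block_filters: tuple[int, int, int, int] = (25, 50, 100, 200)
    kernel: int = 3
    learning_rate: float = 1e-3
    batch_size: int = 8
    max_epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.block_filters) != 4:
            raise ValueError("exactly 4 conv blocks are required")
        if any(a >= b for a, b in zip(self.block_filters, self.block_filters[1:])):
            raise ValueError("block filters must be strictly increasing")
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("learning_rate must be > 0 and batch_size >= 1")


@dataclass
class FeatureMatrix:
    """N x D CNN features with row-aligned labels and subject IDs."""

    values: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.values) == len(self.labels) == len(self.subjects)):
            raise ValueError("values, labels and subjects must be row-aligned")


class FeatureCnn:
    """The 4-block CNN with a temporary softmax classification head."""

    def __init__(self, network: nn.Network, input_channels: int, n_classes: int,
                 config: CnnConfig):
        self.network = network
        self.input_channels = input_channels
        self.n_classes = n_classes
        self.config = config
        self.trained = False
        self.history: dict | None = None

    def _check_input(self, stacks: np.ndarray) -> np.ndarray:
        stacks = np.asarray(stacks, dtype=np.float32)
        if stacks.ndim != 4 or stacks.shape[1:3] != (INPUT_SIDE, INPUT_SIDE):
            raise ValueError(f"expected N x {INPUT_SIDE} x {INPUT_SIDE} x C input, "
                             f"got {stacks.shape}")
        if stacks.shape[3] != self.input_channels:
            raise ValueError(f"expected {self.input_channels} channels, "
                             f"got {stacks.shape[3]}")
        return stacks

    def features(self, stacks: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Flattened final-block output (the classification head is skipped)."""
        stacks = self._check_input(stacks)
        if not self.trained:
            warnings.warn("extracting features from an untrained CNN", stacklevel=2)
        out = [self.network.forward(stacks[i:i + batch_size], train=False,
                                    upto="flatten")
               for i in range(0, len(stacks), batch_size)]
        return np.concatenate(out, axis=0)

    def predict_proba(self, stacks: np.ndarray) -> np.ndarray:
        return self.network.predict_proba(self._check_input(stacks))


def build_feature_cnn(input_channels: int, n_classes: int = 3,
                      config: CnnConfig | None = None,
                      dtype=np.float32) -> FeatureCnn:
    """Assemble the CNN; input spatial size is fixed at 64x64 so the feature
    dimension contract (3200) holds."""
    config = config or CnnConfig()
    if input_channels < 1:
        raise ValueError("input_channels must be >= 1")
    rng = np.random.default_rng(config.seed)
    layers: list[nn.Layer] = []
    c_prev = input_channels
    for b, c_out in enumerate(config.block_filters, start=1):
        layers += [
            nn.Conv2D(c_prev, c_out, kernel=config.kernel, name=f"conv{b}",
                      rng=rng, dtype=dtype),
            nn.BatchNorm(c_out, name=f"bn{b}", dtype=dtype),
            nn.ReLU(name=f"relu{b}"),
            nn.MaxPool2x2(name=f"pool{b}"),
        ]
        c_prev = c_out
    layers.append(nn.Flatten(name="flatten"))
    layers.append(nn.Dense(FEATURE_DIM, n_classes, name="head", rng=rng,
                           dtype=dtype))
    return FeatureCnn(nn.Network(layers), input_channels, n_classes, config)


def _check_subject_disjoint(train_subjects, val_subjects) -> None:
    overlap = set(np.asarray(train_subjects)) & set(np.asarray(val_subjects))
    if overlap:
        raise ValueError(f"subject leakage between train and validation: "
                         f"{sorted(overlap)}")


def one_hot(labels, classes) -> np.ndarray:
    classes = list(classes)
    idx = np.array([classes.index(l) for l in labels])
    out = np.zeros((len(idx), len(classes)), dtype=np.float32)
    out[np.arange(len(idx)), idx] = 1.0
    return out


def train_cnn(model: FeatureCnn, train_stacks, train_labels, val_stacks,
              val_labels, classes, *, train_subjects=None, val_subjects=None,
              config: CnnConfig | None = None) -> dict:
    """Train the CNN end-to-end with its softmax head.

    If subject vectors are provided they are checked for train/validation
    disjointness before any training happens.  The weights with the best
    validation accuracy within ``max_epochs`` are retained.
    """
    config = config or model.config
    if train_subjects is not None and val_subjects is not None:
        _check_subject_disjoint(train_subjects, val_subjects)
    x_train = model._check_input(train_stacks)
    x_val = model._check_input(val_stacks)
    y_train = one_hot(train_labels, classes)
    y_val = one_hot(val_labels, classes)
    if y_train.sum(axis=0).min() == 0 or len(classes) < 2:
        raise ValueError("training set must contain every class (>= 2 classes)")
    history = nn.fit_network(model.network, x_train, y_train, x_val, y_val,
                             lr=config.learning_rate,
                             batch_size=config.batch_size,
                             max_epochs=config.max_epochs, seed=config.seed)
    model.trained = True
    model.history = history
    return history


def extract_features(model: FeatureCnn, stacks, labels=None,
                     subjects=None) -> FeatureMatrix:
    """Extract the 3200-dimensional features for a batch of stacks."""
    n = len(stacks)
    values = model.features(stacks)
    return FeatureMatrix(
        values=values,
        labels=np.asarray(labels if labels is not None else [""] * n),
        subjects=np.asarray(subjects if subjects is not None else [""] * n),
    )


def count_trainable_params(*networks) -> int:
    """Exact count of trainable weights/biases/BN scale-shift parameters."""
    total = 0
    for net in networks:
        raw = net.network if isinstance(net, FeatureCnn) else net
        total += raw.n_params() if isinstance(raw, nn.Network) else int(raw)
    return total
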