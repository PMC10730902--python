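"""Classifier heads on extracted CNN features.

Two heads are provided: the MLP (three FC-BN-ReLU-dropout hidden layers of
1000/100/10 units with 70/60/60% dropout and a 3-unit softmax output) and a
one-vs-one multi-class SVM whose kernel hyper-parameters are chosen by grid
search over subject-wise inner validation folds.  Features are z-scored
per dimension (statistics fit on the training side only) before the SVM to
avoid kernel scale pathologies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import nn
from .features import FEATURE_DIM, FeatureMatrix, one_hot

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "linear": {"C": [0.1, 1.0, 10.0, 100.0]},
    "rbf": {"C": [0.1, 1.0, 10.0, 100.0],
            "gamma": [1e-4, 1e-3, 1e-2, 1e-1, "scale"]},
    "poly": {"C": [0.1, 1.0, 10.0, 100.0], "degree": [2, 3],
             "gamma": ["scale"], "coef0": [0.0, 1.0]},
    "sigmoid": {"C": [0.1, 1.0, 10.0, 100.0], "gamma": [1e-3, 1e-2, "scale"],
                "coef0": [0.0, 1.0]},
}


@dataclass(frozen=True)
class MlpConfig:
    hidden: tuple[int, int, int] = (1000, 100, 10)
    dropout: tuple[float, float, float] = (0.70, 0.60, 0.60)
    n_classes: int = 3
    learning_rate: float = 1e-3
    batch_size: int = 8
    max_epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden) != len(self.dropout):
            raise ValueError("hidden and dropout must have equal lengths")
        if any(not 0.0 <= d < 1.0 for d in self.dropout):
            raise ValueError("dropout rates must lie in [0, 1)")


@dataclass(frozen=True)
class SvmConfig:
    kernel: str = "rbf"
    grid: dict | None = None
    seed: int = 0

    def resolved_grid(self) -> dict[str, list]:
        if self.kernel not in DEFAULT_GRIDS:
            raise ValueError(f"unknown kernel {self.kernel!r}")
        grid = dict(self.grid) if self.grid else dict(DEFAULT_GRIDS[self.kernel])
        if not grid or any(len(v) == 0 for v in grid.values()):
            raise ValueError("degenerate grid: every hyper-parameter needs values")
        return grid


def build_mlp_head(config: MlpConfig | None = None, input_dim: int = FEATURE_DIM,
                   dtype=np.float32) -> nn.Network:
    """The MLP head as a bare network (used both standalone and for the
    whole-model parameter count)."""
    config = config or MlpConfig()
    rng = np.random.default_rng(config.seed)
    layers: list[nn.Layer] = []
    d_prev = input_dim
    for i, (units, rate) in enumerate(zip(config.hidden, config.dropout), start=1):
        layers += [nn.Dense(d_prev, units, name=f"fc{i}", rng=rng, dtype=dtype),
                   nn.BatchNorm(units, name=f"bn{i}", dtype=dtype),
                   nn.ReLU(name=f"relu{i}"),
                   nn.Dropout(rate, name=f"drop{i}")]
        d_prev = units
    layers.append(nn.Dense(d_prev, config.n_classes, name="out", rng=rng,
                           dtype=dtype))
    return nn.Network(layers)


class MlpClassifier:
    def __init__(self, network: nn.Network, classes, config: MlpConfig):
        self.network = network
        self.classes = list(classes)
        self.config = config
        self.history: dict | None = None

    @property
    def hidden_sizes(self) -> tuple[int, ...]:
        return tuple(lyr.params["W"].shape[1] for lyr in self.network.layers
                     if isinstance(lyr, nn.Dense))[:-1]

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        return self.network.predict_proba(np.asarray(features, dtype=np.float32))

    def predict(self, features: np.ndarray) -> np.ndarray:
        return np.asarray(self.classes)[self.predict_proba(features).argmax(1)]


def train_mlp(features: FeatureMatrix | np.ndarray, labels=None,
              config: MlpConfig | None = None, val_features=None,
              val_labels=None, classes=None) -> MlpClassifier:
    """Train the MLP head on feature vectors.

    Without an explicit validation set the training set itself selects the
    best-epoch checkpoint (plain empirical fit).
    """
    config = config or MlpConfig()
    if isinstance(features, FeatureMatrix):
        x, labels = features.values, features.labels
    else:
        x = np.asarray(features)
    labels = np.asarray(labels)
    classes = list(classes) if classes is not None else sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("training set contains a single class")
    net = build_mlp_head(config, input_dim=x.shape[1])
    y = one_hot(labels, classes)
    if val_features is None:
        xv, yv = x, y
    else:
        xv, yv = np.asarray(val_features), one_hot(val_labels, classes)
    history = nn.fit_network(net, x.astype(np.float32), y,
                             xv.astype(np.float32), yv,
                             lr=config.learning_rate, batch_size=config.batch_size,
                             max_epochs=config.max_epochs, seed=config.seed)
    clf = MlpClassifier(net, classes, config)
    clf.history = history
    return clf


class MsvmClassifier:
    """One-vs-one multi-class SVM with vote-based prediction.

    Scores are vote counts plus a bounded aggregate-margin term (< 0.5 vote),
    so ranking is monotone in confidence and ties resolve by margin sum, then
    lowest class index.
    """

    def __init__(self, scaler: StandardScaler, svc: SVC, classes,
                 best_params: dict, grid_results: list):
        self.scaler = scaler
        self.svc = svc
        self.classes = list(classes)
        self.best_params = best_params
        self.grid_results = grid_results

    @property
    def n_machines(self) -> int:
        k = len(self.classes)
        return k * (k - 1) // 2

    def _votes_and_margins(self, features):
        x = self.scaler.transform(np.asarray(features, dtype=float))
        pairwise = self.svc.decision_function(x)
        if pairwise.ndim == 1:
            # sklearn's binary decision function is positive for classes_[1];
            # the OVO pair convention is positive for the first class
            pairwise = -pairwise[:, None]
        k = len(self.classes)
        votes = np.zeros((len(x), k))
        margins = np.zeros((len(x), k))
        pair = 0
        for i in range(k):
            for j in range(i + 1, k):
                d = pairwise[:, pair]
                votes[:, i] += (d > 0)
                votes[:, j] += (d <= 0)
                margins[:, i] += d
                margins[:, j] -= d
                pair += 1
        return votes, margins

    def predict_scores(self, features) -> np.ndarray:
        votes, margins = self._votes_and_margins(features)
        norm = 1.0 + np.abs(margins).max(axis=1, keepdims=True)
        return votes + margins / (2.0 * norm)

    def predict(self, features) -> np.ndarray:
        return np.asarray(self.classes)[self.predict_scores(features).argmax(1)]


def _grid_points(grid: dict[str, list]):
    keys = sorted(grid)
    for combo in product(*(grid[k] for k in keys)):
        yield dict(zip(keys, combo))


def _fit_svc(x, y, kernel: str, params: dict, seed: int) -> SVC:
    return SVC(kernel=kernel, decision_function_shape="ovo",
               random_state=seed, **params).fit(x, y)


def msvm_fit(features, labels, subjects, config: SvmConfig | None = None,
             inner_folds=None) -> MsvmClassifier:
    """Grid-search and fit the OVO multi-class SVM.

    ``inner_folds`` is a list of (train_subjects, val_subjects) pairs; the
    candidate maximizing mean inner-validation accuracy (ties: first in
    deterministic grid order) is refit on the full training set.  Without
    inner folds the grid must be a single point.
    """
    config = config or SvmConfig()
    grid = config.resolved_grid()
    if isinstance(features, FeatureMatrix):
        subjects = features.subjects
        labels = features.labels
        features = features.values
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    subjects = np.asarray(subjects)
    candidates = list(_grid_points(grid))
    results = []
    if inner_folds:
        for train_s, val_s in inner_folds:
            overlap = set(train_s) & set(val_s)
            if overlap:
                raise ValueError(f"subject leakage in inner folds: {sorted(overlap)}")
        for params in candidates:
            accs = []
            for train_s, val_s in inner_folds:
                tr = np.isin(subjects, list(train_s))
                va = np.isin(subjects, list(val_s))
                scaler = StandardScaler().fit(x[tr])
                svc = _fit_svc(scaler.transform(x[tr]), y[tr], config.kernel,
                               params, config.seed)
                accs.append(float((svc.predict(scaler.transform(x[va]))
                                   == y[va]).mean()))
            results.append((params, float(np.mean(accs))))
        best_params = max(results, key=lambda r: r[1])[0]
    else:
        if len(candidates) != 1:
            raise ValueError("grid search needs inner folds; provide them or "
                             "reduce the grid to a single point")
        best_params = candidates[0]
    scaler = StandardScaler().fit(x)
    svc = _fit_svc(scaler.transform(x), y, config.kernel, best_params, config.seed)
    classes = list(svc.classes_)
    return MsvmClassifier(scaler, svc, classes, best_params, results)


def circwavenet_param_count(input_channels: int = 14) -> int:
    """Exact trainable-parameter count of the assembled network: the 4-block
    feature CNN (without its temporary training head) plus the MLP head."""
    from .features import build_feature_cnn

    cnn = build_feature_cnn(input_channels)
    conv_blocks = sum(lyr.n_params() for lyr in cnn.network.layers
                      if lyr.name != "head")
    return conv_blocks + build_mlp_head().n_params()


def predict_scores(classifier, features) -> np.ndarray:
    """Per-class score matrix for either head (row-aligned with the input)."""
    if isinstance(features, FeatureMatrix):
        features = features.values
    if isinstance(classifier, MlpClassifier):
        return classifier.predict_proba(features)
    if isinstance(classifier, MsvmClassifier):
        return classifier.predict_scores(features)
    raise TypeError(f"unsupported classifier type {type(classifier).__name__}")
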