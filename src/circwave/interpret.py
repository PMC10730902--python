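"""Interpretability: Grad-CAM, lesion-mask concentration, PCA + t-SNE embedding.

Grad-CAM weights the final conv-block activations by the spatial mean of the
target-class logit gradient and keeps the positive part of the weighted sum;
the map is bilinearly upsampled to the input size and min-max normalized.
The mask-concentration statistic (fraction of total heat falling inside a
ground-truth lesion mask) turns the qualitative "the heat map concentrates on
the appearing circles" observation into a number that can be compared across
input representations (original vs sub-band-reconstructed B-scans).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .features import FeatureCnn
from .nn import softmax


@dataclass
class HeatMap:
    values: np.ndarray          # 2-D in [0, 1], input spatial size
    target_class: int
    source: str = "original"


@dataclass
class Embedding2D:
    points: np.ndarray          # N x 2
    labels: np.ndarray
    pca_dims: int
    seed: int
    silhouette: float = float("nan")


def grad_cam(model: FeatureCnn, stack: np.ndarray, target_class: int,
             layer: str = "relu4", source: str = "original") -> HeatMap:
    """Class-activation map of ``target_class`` for one sub-band stack."""
    stack = np.asarray(stack, dtype=np.float32)
    if stack.ndim == 3:
        stack = stack[None]
    if stack.shape[0] != 1:
        raise ValueError("grad_cam maps one stack at a time")
    if not 0 <= target_class < model.n_classes:
        raise ValueError(f"unknown class index {target_class}")
    net = model.network
    logits = net.forward(stack, train=False)
    dlogits = np.zeros_like(logits)
    dlogits[0, target_class] = 1.0
    grad = net.backward(dlogits, downto=layer)          # d logit / d activation
    activation = net.forward(stack, train=False, upto=layer)
    weights = grad.mean(axis=(1, 2))                     # 1 x C channel weights
    cam = np.maximum((activation * weights[:, None, None, :]).sum(axis=-1), 0.0)[0]
    side = stack.shape[1]
    if cam.max() <= 0:
        return HeatMap(np.zeros((side, side)), target_class, source)
    cam = _sk_resize(cam, (side, side), order=1, anti_aliasing=False,
                     mode="reflect")
    cam = np.maximum(cam, 0.0)
    cam = (cam - cam.min()) / (cam.max() - cam.min())
    return HeatMap(cam, target_class, source)


def mask_concentration(heat: HeatMap | np.ndarray, mask: np.ndarray) -> float:
    """Fraction of total heat inside the binary mask (in [0, 1])."""
    values = heat.values if isinstance(heat, HeatMap) else np.asarray(heat)
    mask = np.asarray(mask, dtype=bool)
    if values.shape != mask.shape:
        raise ValueError("heat map and mask shapes must match")
    if not mask.any():
        warnings.warn("mask_concentration on an empty mask is undefined",
                      stacklevel=2)
        return float("nan")
    total = float(values.sum())
    if total == 0:
        return 0.0
    return float(values[mask].sum()) / total


def embed_features(features: np.ndarray, labels, seed: int = 0,
                   pca_dims: int = 50, perplexity: float = 30.0) -> Embedding2D:
    """PCA to 50 dimensions followed by t-SNE to 2, with a silhouette score
    of the labels on the embedded points."""
    from sklearn.decomposition import PCA
    from sklearn.manifold import TSNE
    from sklearn.metrics import silhouette_score

    x = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 samples to embed")
    dims = min(pca_dims, n - 1, x.shape[1])
    if dims < pca_dims:
        warnings.warn(f"reducing pca_dims to {dims} for {n} samples", stacklevel=2)
    reduced = PCA(n_components=dims, random_state=seed).fit_transform(x)
    perp = min(perplexity, max((n - 2) / 3.0, 2.0))
    points = TSNE(n_components=2, perplexity=perp, random_state=seed,
                  init="pca", max_iter=1000).fit_transform(reduced)
    sil = float("nan")
    if len(set(labels.tolist())) > 1:
        sil = float(silhouette_score(points, labels))
    return Embedding2D(points=points, labels=labels, pca_dims=dims, seed=seed,
                       silhouette=sil)


def save_heatmap_overlay(image: np.ndarray, heat: HeatMap, path) -> None:
    """Write a PNG of the B-scan with the Grad-CAM heat overlaid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(image, cmap="gray", interpolation="nearest")
    ax.imshow(heat.values, cmap="jet", alpha=0.4, interpolation="bilinear")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)
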