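"""Tissue-type clustering used to guide the classification loss.

Patch images are embedded by a feature extractor, standardized feature-wise
(z-score), projected onto the principal components explaining 95% of the
fit-set variance, and grouped by k-means with k = 10.  The fitted pipeline
is frozen: the same mean/std/components/centroids are applied verbatim at
training time, so assignments reproduce bitwise.

The default extractor is a seeded random-projection CNN built from the
package's own layers: convolutions with fixed random weights followed by a
fixed random projection to 512 dimensions.  Random convolutional features
are a classical, surprisingly strong embedding for texture-like imagery and
require no pretrained weights; an ImageNet-style backbone can be registered
as an alternative extractor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from . import _nn as nn
from .errors import ConfigError, GeometryError, SampleSizeError

__all__ = [
    "FeatureMatrix",
    "ClusterModel",
    "extract_features",
    "fit_cluster_model",
    "assign_clusters",
    "register_extractor",
    "save_cluster_model",
    "load_cluster_model",
    "collect_features",
]

DEFAULT_EXTRACTOR = "random_cnn_512"
_EXTRACTOR_SEED = 0x5EED


@dataclass
class FeatureMatrix:
    values: np.ndarray  # n x d
    extractor_id: str


@dataclass
class ClusterModel:
    mean: np.ndarray            # d
    std: np.ndarray             # d, zero-variance features replaced by 1
    components: np.ndarray      # d x m, orthonormal columns
    explained_ratio: np.ndarray  # m
    centroids: np.ndarray       # k x m
    k: int
    extractor_id: str


class _RandomCnn:
    """Fixed-weight conv embedding: 3 conv/pool stages + random projection."""

    def __init__(self, d_out: int = 512, seed: int = _EXTRACTOR_SEED):
        rng = np.random.default_rng(seed)
        self.stem = nn.AvgPoolN(8)  # 256 -> 32
        self.convs = nn.Sequential([
            nn.Conv2d(3, 16, rng=rng), nn.ReLU(), nn.MaxPool2(),
            nn.Conv2d(16, 32, rng=rng), nn.ReLU(), nn.MaxPool2(),
        ])  # -> 8 x 8 x 32
        self.proj = (rng.standard_normal((8 * 8 * 32, d_out)) /
                     np.sqrt(8 * 8 * 32)).astype(np.float32)

    def __call__(self, images: np.ndarray) -> np.ndarray:
        x = self.stem.forward(images.astype(np.float32))
        x = self.convs.forward(x)
        return x.reshape(x.shape[0], -1) @ self.proj


_extractors = {}


def register_extractor(extractor_id: str, fn) -> None:
    """Register ``fn(images) -> n x d array`` under an id."""
    _extractors[extractor_id] = fn


register_extractor(DEFAULT_EXTRACTOR, _RandomCnn())


def extract_features(images: np.ndarray, extractor: str = DEFAULT_EXTRACTOR
                     ) -> FeatureMatrix:
    """Embed a batch of patches (B x S x S x 3, values in [0, 1])."""
    if extractor not in _extractors:
        raise ConfigError(f"unknown feature extractor {extractor!r}")
    values = np.asarray(_extractors[extractor](images), dtype=np.float64)
    return FeatureMatrix(values=values, extractor_id=extractor)


def collect_features(tree, rng, reader, n_batches: int = 100,
                     batch_size: int = 32,
                     extractor: str = DEFAULT_EXTRACTOR) -> FeatureMatrix:
    """Gather a clustering fit set from the hierarchical sampler."""
    from .sampler import generate_batch

    rows = []
    for _ in range(n_batches):
        batch = generate_batch(tree, rng, reader, batch_size)
        rows.append(extract_features(batch.images, extractor).values)
    return FeatureMatrix(values=np.vstack(rows), extractor_id=extractor)


def fit_cluster_model(features: FeatureMatrix, k: int = 10,
                      var_target: float = 0.95, seed: int = 0) -> ClusterModel:
    """Fit z-score -> PCA (minimal components reaching ``var_target``) ->
    k-means (k-means++ init, 10 restarts, 300-iteration cap)."""
    x = features.values
    n, d = x.shape
    if n <= k:
        raise SampleSizeError(f"need more than k={k} samples, got {n}")
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std = np.where(std > 0, std, 1.0)  # constant features become all-zero
    z = (x - mean) / std

    pca = PCA(n_components=min(n, d), svd_solver="full", random_state=seed)
    pca.fit(z)
    ratios = pca.explained_variance_ratio_
    cum = np.cumsum(ratios)
    m = int(np.searchsorted(cum, var_target - 1e-12) + 1)
    m = min(m, len(ratios))
    components = pca.components_[:m].T  # d x m
    proj = z @ components

    km = KMeans(n_clusters=k, init="k-means++", n_init=10, max_iter=300,
                random_state=seed)
    km.fit(proj)
    return ClusterModel(
        mean=mean,
        std=std,
        components=components,
        explained_ratio=ratios[:m].copy(),
        centroids=km.cluster_centers_.astype(np.float64),
        k=k,
        extractor_id=features.extractor_id,
    )


def assign_clusters(features: FeatureMatrix, model: ClusterModel) -> np.ndarray:
    """Frozen-transform assignment: nearest centroid in squared Euclidean
    distance; ties resolve to the lowest centroid index."""
    x = features.values
    if x.shape[1] != model.mean.shape[0]:
        raise GeometryError(
            f"feature dim {x.shape[1]} != model dim {model.mean.shape[0]}"
        )
    z = (x - model.mean) / model.std
    proj = z @ model.components
    d2 = ((proj[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def save_cluster_model(model: ClusterModel, path) -> None:
    np.savez(
        path,
        mean=model.mean, std=model.std, components=model.components,
        explained_ratio=model.explained_ratio, centroids=model.centroids,
        k=np.array(model.k), extractor_id=np.array(model.extractor_id),
    )


def load_cluster_model(path) -> ClusterModel:
    with np.load(path, allow_pickle=False) as z:
        return ClusterModel(
            mean=z["mean"], std=z["std"], components=z["components"],
            explained_ratio=z["explained_ratio"], centroids=z["centroids"],
            k=int(z["k"]), extractor_id=str(z["extractor_id"]),
        )
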