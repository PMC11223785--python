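"""Learned metric index over embedding collections.

The collection is partitioned by k-means; a small fully connected network
(softmax router) is then trained to map a query embedding to a relevance
distribution over the K partitions. At query time only the ``n_probe``
top-scoring buckets are scanned, trading exactness for a large reduction of
the candidate set — the "learned index" pattern for metric data. With
``n_probe = K`` the index degenerates to an exhaustive scan, which the test
suite uses as the brute-force oracle.

Training uses scikit-learn (KMeans, MLPClassifier); after training the
network weights are frozen into a plain NumPy forward pass so predictions
are bit-reproducible and trivially serializable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
from sklearn.cluster import KMeans
from sklearn.neural_network import MLPClassifier

from .embedding import Embedding, stack_vectors

_FORMAT_ATTR = "foldsearch-lmi"
_FORMAT_VERSION = 1

# adam step size for router training; the sklearn default (1e-3) leaves the
# router clearly underfit within the fixed 50-epoch budget
_LEARNING_RATE = 0.01


@dataclass(frozen=True)
class IndexConfig:
    """Build-time knobs of the index.

    n_clusters : number of k-means partitions K (desk-scale default 64)
    n_probe : buckets scanned per query (default 10)
    classifier_hidden : hidden-layer widths of the router network
    epochs : training epochs for the router
    seed : master seed for clustering and network initialization
    """

    n_clusters: int = 64
    n_probe: int = 10
    classifier_hidden: tuple[int, ...] = (128,)
    epochs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "classifier_hidden", tuple(self.classifier_hidden))
        if not (1 <= self.n_probe <= self.n_clusters):
            raise ValueError("need 1 <= n_probe <= n_clusters")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    def to_json(self) -> str:
        return json.dumps({
            "n_clusters": self.n_clusters,
            "n_probe": self.n_probe,
            "classifier_hidden": list(self.classifier_hidden),
            "epochs": self.epochs,
            "seed": self.seed,
        })

    @staticmethod
    def from_json(text: str) -> "IndexConfig":
        return IndexConfig(**json.loads(text))


class SoftmaxRouter:
    """Frozen fully connected network: ReLU hidden layers, K-way softmax.

    A plain-NumPy forward pass over weights extracted from a trained
    MLPClassifier (or loaded from disk); its output is always a proper
    probability vector over all K clusters, including clusters that were
    empty at training time (those receive probability exactly 0). Inputs
    are standardized by the feature mean/scale seen at training time (raw
    embedding entries are angstrom distances spanning orders of magnitude,
    which gradient training handles poorly).
    """

    def __init__(self, weights, biases, classes: np.ndarray, n_clusters: int,
                 feature_mean: np.ndarray | None = None,
                 feature_scale: np.ndarray | None = None):
        self.weights = [np.asarray(w, dtype=np.float64) for w in weights]
        self.biases = [np.asarray(b, dtype=np.float64) for b in biases]
        self.classes = np.asarray(classes, dtype=int)
        self.n_clusters = int(n_clusters)
        self.input_dim = self.weights[0].shape[0]
        self.feature_mean = (np.zeros(self.input_dim) if feature_mean is None
                             else np.asarray(feature_mean, dtype=np.float64))
        self.feature_scale = (np.ones(self.input_dim) if feature_scale is None
                              else np.asarray(feature_scale, dtype=np.float64))

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        squeeze = x.ndim == 1
        h = np.atleast_2d(x)
        if h.shape[1] != self.input_dim:
            raise ValueError(
                f"embedding dimension {h.shape[1]} != router input {self.input_dim}"
            )
        h = (h - self.feature_mean) / self.feature_scale
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ w + b, 0.0)
        logits = h @ self.weights[-1] + self.biases[-1]
        if logits.shape[1] == 1:
            # binary MLPClassifier emits a single logistic unit
            p1 = 1.0 / (1.0 + np.exp(-logits[:, 0]))
            probs = np.column_stack([1.0 - p1, p1])
        else:
            logits -= logits.max(axis=1, keepdims=True)
            exp = np.exp(logits)
            probs = exp / exp.sum(axis=1, keepdims=True)
        full = np.zeros((probs.shape[0], self.n_clusters))
        full[:, self.classes] = probs
        return full[0] if squeeze else full


@dataclass
class LearnedIndex:
    """Centroids, bucket contents and the trained router."""

    centroids: np.ndarray
    buckets: dict[int, list[tuple[str, Embedding]]]
    classifier: SoftmaxRouter
    config: IndexConfig
    labels: np.ndarray = field(repr=False, default=None)

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]

    @property
    def size(self) -> int:
        return sum(len(b) for b in self.buckets.values())


def fit_clusters(
    embeddings: list[Embedding], K: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """k-means partitioning with k-means++ init and a fixed seed.

    Returns (centroids, labels); labels are recomputed as the argmin
    distance to the final centroids, so every embedding is guaranteed to sit
    in the bucket of its nearest centroid (ties -> lowest cluster id).
    """
    X = stack_vectors(embeddings)
    if K < 1:
        raise ValueError("K must be >= 1")
    if len(embeddings) < K:
        raise ValueError(f"cannot fit {K} clusters to {len(embeddings)} embeddings")
    km = KMeans(n_clusters=K, init="k-means++", n_init=10, random_state=seed)
    km.fit(X)
    centroids = km.cluster_centers_
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1)
    return centroids, labels


def train_classifier(
    embeddings: list[Embedding], labels: np.ndarray, config: IndexConfig
) -> SoftmaxRouter:
    """Train the softmax router on (embedding, cluster-label) pairs.

    Fully connected network with ReLU hidden layers and cross-entropy loss,
    seeded initialization, fixed epoch budget, no early stopping — the same
    config and seed always yield identical predictions.
    """
    X = stack_vectors(embeddings)
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 0 or labels.max() >= config.n_clusters:
        raise ValueError("label outside [0, n_clusters)")
    if len(np.unique(labels)) == 1:
        # K=1 or degenerate data: a constant router that puts all mass on
        # the single populated cluster
        return _constant_router(X.shape[1], int(labels[0]), config.n_clusters)
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    mlp = MLPClassifier(
        hidden_layer_sizes=config.classifier_hidden,
        activation="relu",
        solver="adam",
        learning_rate_init=_LEARNING_RATE,
        max_iter=config.epochs,
        random_state=config.seed,
        early_stopping=False,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        mlp.fit((X - mean) / scale, labels)
    return SoftmaxRouter(mlp.coefs_, mlp.intercepts_, mlp.classes_,
                         config.n_clusters, feature_mean=mean, feature_scale=scale)


def _constant_router(dim: int, cls: int, n_clusters: int) -> SoftmaxRouter:
    # two-logit softmax with a huge bias on `cls`; the other logit is
    # attached to an arbitrary distinct class index
    other = 0 if cls != 0 else min(1, n_clusters - 1)
    w = np.zeros((dim, 2))
    b = np.array([-50.0, 50.0])
    return SoftmaxRouter([w], [b], np.array([other, cls]), n_clusters)


def build_index(embeddings: list[Embedding], config: IndexConfig) -> LearnedIndex:
    """fit_clusters + train_classifier + bucket fill."""
    centroids, labels = fit_clusters(embeddings, config.n_clusters, config.seed)
    router = train_classifier(embeddings, labels, config)
    buckets: dict[int, list[tuple[str, Embedding]]] = {
        k: [] for k in range(config.n_clusters)
    }
    for emb, lab in zip(embeddings, labels):
        buckets[int(lab)].append((emb.source_id, emb))
    return LearnedIndex(centroids, buckets, router, config, labels=labels)


def probe(index: LearnedIndex, query: Embedding, n_probe: int | None = None) -> list[int]:
    """Ids of the ``n_probe`` clusters the router scores highest for the
    query, in descending score order; ties broken by ascending cluster id."""
    if n_probe is None:
        n_probe = index.config.n_probe
    if not (1 <= n_probe <= index.n_clusters):
        raise ValueError("need 1 <= n_probe <= K")
    scores = index.classifier(query.vector)
    # sort by (-score, id): stable, reproducible tie-break
    order = np.lexsort((np.arange(len(scores)), -scores))
    return [int(c) for c in order[:n_probe]]


def gather_candidates(
    index: LearnedIndex, cluster_ids: list[int]
) -> list[tuple[str, Embedding]]:
    """Concatenate the named buckets (order follows ``cluster_ids``)."""
    out: list[tuple[str, Embedding]] = []
    for cid in cluster_ids:
        if cid not in index.buckets:
            raise ValueError(f"unknown cluster id {cid}")
        out.extend(index.buckets[cid])
    return out


# ---------------------------------------------------------------------------
# Persistence


def save_index(index: LearnedIndex, path) -> None:
    """Persist the whole index in one HDF5 container (versioned header)."""
    ids, vecs, labels = [], [], []
    for cid in sorted(index.buckets):
        for sid, emb in index.buckets[cid]:
            ids.append(sid)
            vecs.append(emb.vector)
            labels.append(cid)
    with h5py.File(path, "w") as f:
        f.attrs["format"] = _FORMAT_ATTR
        f.attrs["version"] = _FORMAT_VERSION
        f.attrs["config"] = index.config.to_json()
        f.create_dataset("centroids", data=index.centroids)
        f.create_dataset("ids", data=np.array(ids, dtype=h5py.string_dtype()))
        f.create_dataset("vectors", data=np.asarray(vecs))
        f.create_dataset("labels", data=np.asarray(labels, dtype=np.int32))
        f.create_dataset("router/classes", data=index.classifier.classes)
        f.create_dataset("router/feature_mean", data=index.classifier.feature_mean)
        f.create_dataset("router/feature_scale", data=index.classifier.feature_scale)
        f.attrs["router_layers"] = len(index.classifier.weights)
        for i, (w, b) in enumerate(zip(index.classifier.weights, index.classifier.biases)):
            f.create_dataset(f"router/w{i}", data=w)
            f.create_dataset(f"router/b{i}", data=b)


def load_index(path) -> LearnedIndex:
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != _FORMAT_ATTR:
            raise ValueError(f"{path}: not a learned-index container")
        if int(f.attrs.get("version", -1)) != _FORMAT_VERSION:
            raise ValueError(f"{path}: unsupported index version")
        config = IndexConfig.from_json(f.attrs["config"])
        centroids = f["centroids"][...]
        ids = [s.decode() if isinstance(s, bytes) else s for s in f["ids"][...]]
        vecs = f["vectors"][...]
        labels = f["labels"][...]
        n_layers = int(f.attrs["router_layers"])
        weights = [f[f"router/w{i}"][...] for i in range(n_layers)]
        biases = [f[f"router/b{i}"][...] for i in range(n_layers)]
        classes = f["router/classes"][...]
        feature_mean = f["router/feature_mean"][...]
        feature_scale = f["router/feature_scale"][...]
    router = SoftmaxRouter(weights, biases, classes, centroids.shape[0],
                           feature_mean=feature_mean, feature_scale=feature_scale)
    buckets: dict[int, list[tuple[str, Embedding]]] = {
        k: [] for k in range(centroids.shape[0])
    }
    for sid, vec, lab in zip(ids, vecs, labels):
        buckets[int(lab)].append((sid, Embedding(vec, source_id=sid)))
    return LearnedIndex(centroids, buckets, router, config, labels=np.asarray(labels))
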