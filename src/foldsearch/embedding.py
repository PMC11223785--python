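"""Compact distance-matrix embeddings of protein chains.

A chain's tertiary structure is summarized by its C-alpha pairwise distance
matrix — invariant under rotation, translation and mirror reflection and
blind to primary/secondary structure. The matrix is down-sampled to a fixed
m x m grid by corner-anchored bilinear interpolation and flattened to its
strict upper triangle, giving a fixed-length vector (d = m(m-1)/2, 28 for
the default m = 8) in which arbitrarily sized proteins can be compared by
plain Euclidean distance. At 28 float32 entries a protein costs ~100 bytes,
which is what makes scanning hundreds of millions of structures feasible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from scipy.spatial.distance import squareform, pdist

from .structure_io import ProteinChain, MIN_CHAIN_LENGTH

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EmbeddingConfig:
    """Knobs of the compression step.

    grid_size : target grid m (embedding dimension is m(m-1)/2)
    include_diagonal : keep the (near-zero) resized diagonal entries
    scale : divisor applied to the final vector; 1.0 keeps raw angstroms
    """

    grid_size: int = 8
    include_diagonal: bool = False
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def dimension(self) -> int:
        m = self.grid_size
        return m * (m + 1) // 2 if self.include_diagonal else m * (m - 1) // 2


@dataclass(frozen=True)
class Embedding:
    """Fixed-length vector summary of one chain."""

    vector: np.ndarray = field(repr=False)
    source_id: str = ""

    def __post_init__(self) -> None:
        vec = np.asarray(self.vector, dtype=float)
        object.__setattr__(self, "vector", vec)
        if vec.ndim != 1:
            raise ValueError("embedding vector must be 1-D")
        if not np.isfinite(vec).all():
            raise ValueError("non-finite embedding entry")


def distance_matrix(chain: ProteinChain) -> np.ndarray:
    """Pairwise C-alpha Euclidean distance matrix (n x n, angstrom)."""
    if len(chain) < MIN_CHAIN_LENGTH:
        raise ValueError(f"chain must have >= {MIN_CHAIN_LENGTH} residues")
    return squareform(pdist(chain.ca_coords))


def resize_matrix(D: np.ndarray, m: int) -> np.ndarray:
    """Bilinearly resample an n x n matrix onto an m x m grid.

    The sample grid is corner-anchored: output corners coincide with input
    corners, interior samples sit at fractional index i*(n-1)/(m-1).
    Symmetric input yields symmetric output. Up-sampling (m > n) is allowed
    but logged, as it adds no information.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[1] != n:
        raise ValueError("D must be square")
    if n < 2 or m < 2:
        raise ValueError("need n >= 2 and m >= 2")
    if m > n:
        logger.info("up-sampling %dx%d matrix to %dx%d", n, n, m, m)
    if m == n:
        return D.copy()
    ticks = np.linspace(0.0, n - 1.0, m)
    rows, cols = np.meshgrid(ticks, ticks, indexing="ij")
    return map_coordinates(D, [rows, cols], order=1, mode="nearest")


def embed(chain: ProteinChain, config: EmbeddingConfig = EmbeddingConfig()) -> Embedding:
    """Embed one chain: distance matrix -> bilinear resize -> triangle flatten.

    The output is the row-major upper triangle (strict unless
    ``include_diagonal``) of the resized matrix, divided by ``scale``.
    Deterministic, and invariant under any rigid motion of the chain.
    """
    small = resize_matrix(distance_matrix(chain), config.grid_size)
    k = 0 if config.include_diagonal else 1
    iu = np.triu_indices(config.grid_size, k=k)
    return Embedding(small[iu] / config.scale, source_id=chain.id)


def embed_batch(
    chains: list[ProteinChain], config: EmbeddingConfig = EmbeddingConfig()
) -> list[Embedding]:
    """Embed a list of chains, preserving order.

    A chain that fails to embed (e.g. too short after upstream filtering)
    is skipped with a warning rather than aborting the batch.
    """
    out: list[Embedding] = []
    for chain in chains:
        try:
            out.append(embed(chain, config))
        except ValueError as exc:
            logger.warning("skipping chain %s: %s", getattr(chain, "id", "?"), exc)
    return out


def stack_vectors(embeddings: list[Embedding]) -> np.ndarray:
    """(N, d) float matrix of embedding vectors in list order."""
    if not embeddings:
        return np.empty((0, 0))
    return np.stack([e.vector for e in embeddings])


# ---------------------------------------------------------------------------
# Persistence: one binary container (HDF5), float32 storage; CSV for debugging

_FORMAT_ATTR = "foldsearch-embeddings"
_FORMAT_VERSION = 1


def save_embeddings(embeddings: list[Embedding], path) -> None:
    ids = [e.source_id for e in embeddings]
    mat = stack_vectors(embeddings).astype(np.float32)
    with h5py.File(path, "w") as f:
        f.attrs["format"] = _FORMAT_ATTR
        f.attrs["version"] = _FORMAT_VERSION
        f.create_dataset("embeddings", data=mat)
        f.create_dataset("ids", data=np.array(ids, dtype=h5py.string_dtype()))


def load_embeddings(path) -> list[Embedding]:
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != _FORMAT_ATTR:
            raise ValueError(f"{path}: not an embedding container")
        mat = f["embeddings"][...]
        ids = [s.decode() if isinstance(s, bytes) else s for s in f["ids"][...]]
    return [Embedding(vec, source_id=i) for vec, i in zip(mat, ids)]


def export_embeddings_csv(embeddings: list[Embedding], path) -> None:
    mat = stack_vectors(embeddings)
    df = pd.DataFrame(mat, columns=[f"e{i}" for i in range(mat.shape[1])])
    df.insert(0, "id", [e.source_id for e in embeddings])
    df.to_csv(path, index=False)
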