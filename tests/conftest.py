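"""Shared fixtures: a desk-scale synthetic benchmark database and a built
learned index, constructed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from foldsearch.embedding import embed_batch
from foldsearch.learned_index import IndexConfig, build_index
from foldsearch.search_engine import SearchEngine
from foldsearch.structure_io import generate_benchmark_db

BENCH_SEED = 42
INDEX_SEED = 7


@pytest.fixture(scope="session")
def benchmark_db():
    """20 structural families x 50 members (1000 chains) with labels."""
    chains, labels = generate_benchmark_db(
        n_families=20, members_per_family=50,
        length_range=(50, 200), sigma=1.0, seed=BENCH_SEED,
    )
    return chains, labels


@pytest.fixture(scope="session")
def benchmark_embeddings(benchmark_db):
    chains, _ = benchmark_db
    return embed_batch(chains)


@pytest.fixture(scope="session")
def benchmark_index(benchmark_embeddings):
    """K=64 learned index over the benchmark embeddings."""
    return build_index(
        benchmark_embeddings, IndexConfig(n_clusters=64, seed=INDEX_SEED)
    )


@pytest.fixture(scope="session")
def benchmark_matrix(benchmark_embeddings):
    mat = np.stack([e.vector for e in benchmark_embeddings])
    ids = np.array([e.source_id for e in benchmark_embeddings])
    return mat, ids


@pytest.fixture()
def engine(benchmark_db, benchmark_index):
    chains, _ = benchmark_db
    return SearchEngine(benchmark_index, {c.id: c for c in chains})


def brute_force_ranking(mat: np.ndarray, ids: np.ndarray, query_vec: np.ndarray,
                        k: int) -> list[str]:
    """Exhaustive Euclidean ranking oracle (ties by ascending id)."""
    dists = np.linalg.norm(mat - query_vec, axis=1)
    order = np.lexsort((ids, dists))
    return [str(i) for i in ids[order[:k]]]
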