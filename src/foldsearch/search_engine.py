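"""Query workflow: identifier resolution, probe, ranking, scoring, export.

Mirrors the staged search pipeline of a structure-similarity web service,
run entirely offline: a query token (UniProt accession, PDB id or gene
symbol) is resolved to a canonical accession using local mapping tables,
the query chain's embedding is routed through the learned index, the
gathered candidates are ranked by Euclidean embedding distance and truncated
to a fixed cap (default 1000), and structural-alignment metrics (TM-score,
RMSD, aligned residues, sequence identity) are computed for the top of the
ranking — 50 hits initially, expandable in increments of 50/100/200/300.
Scored sessions are cached so a repeated query does no alignment work.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .alignment_metrics import AlignmentResult, TMParams, align_chains
from .embedding import Embedding, EmbeddingConfig, embed
from .learned_index import LearnedIndex, gather_candidates, probe
from .structure_io import ProteinChain

logger = logging.getLogger(__name__)

# official UniProt accession pattern
UNIPROT_RE = re.compile(
    r"^([OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9]([A-Z][A-Z0-9]{2}[0-9]){1,2})$"
)
PDB_RE = re.compile(r"^[0-9][A-Z0-9]{3}$")


class IdentifierNotFoundError(KeyError):
    """No mapping found for a query token in any identifier category."""


class ChainNotIndexedError(KeyError):
    """The token resolved, but its structure is not in the chain store."""


@dataclass(frozen=True)
class SearchConfig:
    """Workflow constants of the staged search."""

    candidate_cap: int = 1000
    first_page: int = 50
    expansion_steps: frozenset[int] = frozenset({50, 100, 200, 300})
    n_probe: int = 10

    def __post_init__(self) -> None:
        object.__setattr__(self, "expansion_steps", frozenset(self.expansion_steps))
        if self.first_page > self.candidate_cap:
            raise ValueError("first_page must not exceed candidate_cap")
        if any(s <= 0 for s in self.expansion_steps):
            raise ValueError("expansion steps must be positive")


class IDMappingTable:
    """Offline identifier mapping: PDB id -> UniProt and gene -> UniProt.

    Built from two-column tab-separated files; all keys and accessions are
    upper-cased. One-to-many mappings are kept; resolution picks the
    lexicographically smallest accession and logs the alternatives.
    """

    def __init__(
        self,
        pdb_to_uniprot: dict[str, set[str]] | None = None,
        gene_to_uniprot: dict[str, set[str]] | None = None,
    ):
        self.pdb_to_uniprot = self._normalize(pdb_to_uniprot or {})
        self.gene_to_uniprot = self._normalize(gene_to_uniprot or {})

    @staticmethod
    def _normalize(mapping: dict[str, set[str]]) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for key, vals in mapping.items():
            vals = {vals} if isinstance(vals, str) else set(vals)
            out.setdefault(key.upper(), set()).update(v.upper() for v in vals)
        return out

    @classmethod
    def from_files(cls, pdb_path=None, gene_path=None) -> "IDMappingTable":
        """Load from tab-separated two-column files (key<TAB>accession)."""
        def read(path) -> dict[str, set[str]]:
            if path is None:
                return {}
            df = pd.read_csv(path, sep="\t", header=None, names=["key", "acc"],
                             dtype=str, comment="#")
            out: dict[str, set[str]] = {}
            for key, acc in zip(df["key"], df["acc"]):
                out.setdefault(str(key).upper(), set()).add(str(acc).upper())
            return out

        return cls(read(pdb_path), read(gene_path))


def resolve_identifier(token: str, table: IDMappingTable) -> str:
    """Translate a query token to a canonical UniProt-style accession.

    Classification order: UniProt accession pattern (returned as-is after
    upper-casing), then 4-character PDB id (table lookup), then gene symbol
    (table lookup). One-to-many lookups return the lexicographically
    smallest accession.
    """
    token = token.strip()
    if not token:
        raise ValueError("empty query token")
    upper = token.upper()
    if UNIPROT_RE.match(upper):
        return upper
    attempted = ["UniProt accession"]
    if PDB_RE.match(upper):
        attempted.append("PDB id")
        hits = table.pdb_to_uniprot.get(upper)
        if hits:
            return _pick_accession(upper, hits)
    attempted.append("gene symbol")
    hits = table.gene_to_uniprot.get(upper)
    if hits:
        return _pick_accession(upper, hits)
    raise IdentifierNotFoundError(
        f"{token!r} not found (tried: {', '.join(attempted)})"
    )


def _pick_accession(key: str, hits: set[str]) -> str:
    ordered = sorted(hits)
    if len(ordered) > 1:
        logger.info("%s maps to %d accessions %s; using %s",
                    key, len(ordered), ordered, ordered[0])
    return ordered[0]


@dataclass
class SearchHit:
    """One ranked result: id, embedding-space distance and, once the hit
    has been scored, its structural-alignment metrics."""

    id: str
    embedding_distance: float
    metrics: AlignmentResult | None = None
    organism: str | None = None


@dataclass
class SearchSession:
    """State of one query: the capped ranking and how much of it is scored.

    Scored hits are always a prefix of the ranking; expanding a session
    scores the next block and never touches already-scored hits.
    """

    query_id: str
    hits: list[SearchHit]
    scored_count: int = 0

    @property
    def scored_hits(self) -> list[SearchHit]:
        return self.hits[: self.scored_count]


def rank_candidates(
    query: Embedding, candidates: list[tuple[str, Embedding]], cap: int
) -> list[SearchHit]:
    """Sort candidates by ascending Euclidean embedding distance (ties by
    ascending id) and truncate to ``cap``."""
    if not candidates:
        return []
    mat = np.stack([emb.vector for _, emb in candidates])
    if mat.shape[1] != query.vector.shape[0]:
        raise ValueError(
            f"candidate dimension {mat.shape[1]} != query {query.vector.shape[0]}"
        )
    dists = np.linalg.norm(mat - query.vector, axis=1)
    ids = [cid for cid, _ in candidates]
    order = sorted(range(len(ids)), key=lambda i: (dists[i], ids[i]))
    return [SearchHit(ids[i], float(dists[i])) for i in order[:cap]]


class SearchEngine:
    """Ties the index, chain store and mapping tables into one query API.

    ``chain_store`` maps accession -> ProteinChain; ``organisms`` optionally
    maps accession -> organism name (from a local metadata table). Computed
    alignment metrics are cached across searches keyed by
    (query id, result id, scorer-config digest); whole sessions are cached
    by query id so repeating a search does no ranking or alignment work.
    """

    def __init__(
        self,
        index: LearnedIndex,
        chain_store: dict[str, ProteinChain],
        table: IDMappingTable | None = None,
        organisms: dict[str, str] | None = None,
        config: SearchConfig = SearchConfig(),
        embedding_config: EmbeddingConfig = EmbeddingConfig(),
        tm_params: TMParams = TMParams(),
    ):
        self.index = index
        self.chain_store = chain_store
        self.table = table or IDMappingTable()
        self.organisms = organisms or {}
        self.config = config
        self.embedding_config = embedding_config
        self.tm_params = tm_params
        self._metric_cache: dict[tuple, AlignmentResult] = {}
        self._session_cache: dict[str, SearchSession] = {}
        self.alignment_calls = 0  # instrumentation: cache-miss counter

    # -- pipeline stages -----------------------------------------------

    def _scorer_digest(self) -> tuple:
        p = self.tm_params
        return (p.d0, p.gap_penalty, p.max_iterations, p.convergence_tol,
                p.normalization_length)

    def _score_hit(self, query_chain: ProteinChain, hit: SearchHit) -> None:
        key = (query_chain.id, hit.id, self._scorer_digest())
        result = self._metric_cache.get(key)
        if result is None:
            target = self.chain_store[hit.id]
            self.alignment_calls += 1
            result = align_chains(query_chain, target, self.tm_params)
            self._metric_cache[key] = result
        hit.metrics = result
        hit.organism = self.organisms.get(hit.id)

    def search(self, query_token: str, n_probe: int | None = None) -> SearchSession:
        """Run the full staged query workflow and return the session."""
        accession = resolve_identifier(query_token, self.table)
        cached = self._session_cache.get(accession)
        if cached is not None:
            logger.info("serving %s from session cache", accession)
            return cached
        chain = self.chain_store.get(accession)
        if chain is None:
            raise ChainNotIndexedError(
                f"{accession} resolved but is not in the indexed chain store"
            )
        query_emb = embed(chain, self.embedding_config)
        clusters = probe(self.index, query_emb, n_probe or self.config.n_probe)
        logger.info("%s: probing %d clusters", accession, len(clusters))
        candidates = gather_candidates(self.index, clusters)
        logger.info("%s: %d candidates gathered", accession, len(candidates))
        hits = rank_candidates(query_emb, candidates, self.config.candidate_cap)
        session = SearchSession(query_id=accession, hits=hits)
        n_score = min(self.config.first_page, len(hits))
        for hit in hits[:n_score]:
            self._score_hit(chain, hit)
        session.scored_count = n_score
        logger.info("%s: scored first %d of %d hits", accession, n_score, len(hits))
        self._session_cache[accession] = session
        return session

    def expand(self, session: SearchSession, increment: int) -> SearchSession:
        """Score the next ``increment`` ranked hits (one of the allowed
        expansion steps), clamped to the candidate count."""
        if increment not in self.config.expansion_steps:
            allowed = sorted(self.config.expansion_steps)
            raise ValueError(f"increment {increment} not in allowed steps {allowed}")
        chain = self.chain_store[session.query_id]
        new_count = min(session.scored_count + increment, len(session.hits))
        for hit in session.hits[session.scored_count:new_count]:
            self._score_hit(chain, hit)
        session.scored_count = new_count
        return session


CSV_HEADER = [
    "query_id", "result_id", "embedding_distance", "tm_score", "rmsd",
    "aligned_residues", "sequence_identity", "organism",
]


def export_csv(session: SearchSession, path) -> None:
    """Write all scored hits, in rank order, as CSV (fixed schema)."""
    if session.scored_count < 1:
        raise ValueError("session has no scored hits to export")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for hit in session.scored_hits:
            m = hit.metrics
            writer.writerow([
                session.query_id,
                hit.id,
                f"{hit.embedding_distance:.6f}",
                f"{m.tm_score:.4f}" if m else "",
                f"{m.rmsd:.4f}" if m else "",
                m.aligned_count if m else "",
                f"{m.seq_identity:.4f}" if m else "",
                hit.organism or "",
            ])


def group_by_organism(session: SearchSession) -> dict[str, list[SearchHit]]:
    """Partition scored hits by organism (missing -> "unknown"), preserving
    rank order within groups; groups ordered by their best member's
    distance."""
    groups: dict[str, list[SearchHit]] = {}
    for hit in session.scored_hits:
        groups.setdefault(hit.organism or "unknown", []).append(hit)
    return dict(
        sorted(groups.items(), key=lambda kv: kv[1][0].embedding_distance)
    )


# ---------------------------------------------------------------------------
# Chain store persistence (one HDF5 container; used by the CLI build step)

_STORE_FORMAT = "foldsearch-chains"


def save_chain_store(chains: dict[str, ProteinChain] | list[ProteinChain], path) -> None:
    if isinstance(chains, dict):
        chains = list(chains.values())
    ids = [c.id for c in chains]
    seqs = [c.sequence for c in chains]
    lengths = np.array([len(c) for c in chains], dtype=np.int64)
    coords = (np.concatenate([c.ca_coords for c in chains])
              if chains else np.empty((0, 3)))
    with h5py.File(path, "w") as f:
        f.attrs["format"] = _STORE_FORMAT
        f.attrs["version"] = 1
        str_t = h5py.string_dtype()
        f.create_dataset("ids", data=np.array(ids, dtype=str_t))
        f.create_dataset("sequences", data=np.array(seqs, dtype=str_t))
        f.create_dataset("lengths", data=lengths)
        f.create_dataset("coords", data=coords)


def load_chain_store(path) -> dict[str, ProteinChain]:
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != _STORE_FORMAT:
            raise ValueError(f"{path}: not a chain-store container")
        ids = [s.decode() for s in f["ids"][...]]
        seqs = [s.decode() for s in f["sequences"][...]]
        lengths = f["lengths"][...]
        coords = f["coords"][...]
    store: dict[str, ProteinChain] = {}
    offset = 0
    for cid, seq, n in zip(ids, seqs, lengths):
        store[cid] = ProteinChain(cid, seq, coords[offset:offset + n])
        offset += n
    return store


def load_organism_table(path) -> dict[str, str]:
    """Two-column tab-separated metadata table: accession<TAB>organism."""
    df = pd.read_csv(path, sep="\t", header=None, names=["acc", "organism"],
                     dtype=str, comment="#")
    return {str(a).upper(): str(o) for a, o in zip(df["acc"], df["organism"])}
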