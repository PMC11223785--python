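"""Identifier resolution, ranking, the staged search workflow and export."""

import numpy as np
import pytest

from foldsearch.embedding import Embedding, embed
from foldsearch.search_engine import (
    ChainNotIndexedError, IDMappingTable, IdentifierNotFoundError,
    SearchConfig, SearchEngine, export_csv, group_by_organism,
    rank_candidates, resolve_identifier,
)
from conftest import brute_force_ranking


@pytest.fixture()
def table():
    return IDMappingTable(
        pdb_to_uniprot={"1ABC": {"Q00001"}, "2XYZ": {"Q00009", "Q00002"}},
        gene_to_uniprot={"HBA1": {"P69905"}, "MULTI": {"P00003", "P00002"}},
    )


class TestResolveIdentifier:
    def test_accession_passthrough(self, table):
        assert resolve_identifier("P69905", table) == "P69905"
        assert resolve_identifier("p69905", table) == "P69905"  # case-normalized
        assert resolve_identifier("A0A2G9QLR9", table) == "A0A2G9QLR9"

    def test_pdb_id_lookup(self, table):
        assert resolve_identifier("1abc", table) == "Q00001"

    def test_gene_symbol_lookup(self, table):
        assert resolve_identifier("hba1", table) == "P69905"

    def test_one_to_many_picks_smallest(self, table):
        assert resolve_identifier("2XYZ", table) == "Q00002"
        assert resolve_identifier("MULTI", table) == "P00002"

    def test_not_found_names_categories(self, table):
        with pytest.raises(IdentifierNotFoundError, match="gene symbol"):
            resolve_identifier("NOPE99", table)
        with pytest.raises(ValueError):
            resolve_identifier("   ", table)

    def test_table_from_files(self, tmp_path):
        pdb = tmp_path / "pdb.tsv"
        pdb.write_text("1abc\tq00001\n1abc\tQ00000\n")
        gene = tmp_path / "gene.tsv"
        gene.write_text("HBA1\tP69905\n")
        t = IDMappingTable.from_files(pdb, gene)
        assert resolve_identifier("1ABC", t) == "Q00000"
        assert resolve_identifier("HBA1", t) == "P69905"


class TestRankCandidates:
    def test_analytic_ordering(self):
        query = Embedding(np.array([0.0, 0.0]), "q")
        cands = [
            ("c", Embedding(np.array([3.0, 0.0]), "c")),
            ("a", Embedding(np.array([1.0, 0.0]), "a")),
            ("b", Embedding(np.array([0.0, 2.0]), "b")),
        ]
        hits = rank_candidates(query, cands, cap=10)
        assert [h.id for h in hits] == ["a", "b", "c"]
        assert [h.embedding_distance for h in hits] == [1.0, 2.0, 3.0]

    def test_cap_truncates_to_1000(self):
        rng = np.random.default_rng(0)
        cands = [(f"C{i:05d}", Embedding(rng.uniform(size=4), f"C{i:05d}"))
                 for i in range(5000)]
        query = Embedding(np.full(4, 0.5), "q")
        hits = rank_candidates(query, cands, cap=SearchConfig().candidate_cap)
        assert len(hits) == 1000
        dists = [h.embedding_distance for h in hits]
        assert dists == sorted(dists)

    def test_exact_match_first(self):
        vecs = np.eye(3)
        cands = [(f"x{i}", Embedding(vecs[i], f"x{i}")) for i in range(3)]
        hits = rank_candidates(Embedding(vecs[1], "q"), cands, cap=3)
        assert hits[0].id == "x1"
        assert hits[0].embedding_distance == 0.0

    def test_tie_break_by_id(self):
        v = np.array([1.0, 0.0])
        cands = [("zz", Embedding(v, "zz")), ("aa", Embedding(v, "aa"))]
        hits = rank_candidates(Embedding(np.zeros(2), "q"), cands, cap=2)
        assert [h.id for h in hits] == ["aa", "zz"]

    def test_dimension_mismatch(self):
        cands = [("a", Embedding(np.zeros(3), "a"))]
        with pytest.raises(ValueError):
            rank_candidates(Embedding(np.zeros(2), "q"), cands, cap=1)


class TestSearch:
    def test_self_retrieval(self, engine):
        session = engine.search("P00000")
        assert session.hits[0].id == "P00000"
        assert session.hits[0].embedding_distance == 0.0
        assert session.hits[0].metrics.tm_score == pytest.approx(1.0, abs=1e-9)

    def test_first_page_scored_count(self, engine):
        session = engine.search("P00010")
        assert session.scored_count == 50
        assert all(h.metrics is not None for h in session.scored_hits)
        assert all(h.metrics is None for h in session.hits[50:])

    def test_ranking_is_sorted(self, engine):
        session = engine.search("P00020")
        dists = [h.embedding_distance for h in session.hits]
        assert dists == sorted(dists)
        assert len(session.hits) <= engine.config.candidate_cap

    def test_unknown_token(self, engine):
        with pytest.raises(IdentifierNotFoundError):
            engine.search("UNKNOWN_GENE")

    def test_resolvable_but_not_indexed(self, benchmark_db, benchmark_index):
        chains, _ = benchmark_db
        engine = SearchEngine(benchmark_index, {c.id: c for c in chains})
        with pytest.raises(ChainNotIndexedError):
            engine.search("P99999")  # accession-shaped, not in the store

    def test_repeat_search_served_from_cache(self, engine):
        engine.search("P00030")
        calls_after_first = engine.alignment_calls
        session2 = engine.search("P00030")
        assert engine.alignment_calls == calls_after_first  # zero new alignments
        assert session2.scored_count == 50

    def test_oracle_equivalence_exhaustive_probe(
        self, benchmark_db, benchmark_index, benchmark_matrix
    ):
        """With n_probe = K the approximate pipeline must reproduce
        brute-force exhaustive ranking exactly (ids and order)."""
        chains, _ = benchmark_db
        engine = SearchEngine(
            benchmark_index, {c.id: c for c in chains},
            config=SearchConfig(n_probe=64, first_page=5),
        )
        mat, ids = benchmark_matrix
        for token in ("P00001", "P00500", "P00999"):
            session = engine.search(token)
            query_vec = embed(engine.chain_store[token]).vector
            oracle = brute_force_ranking(mat, ids, query_vec, 50)
            assert [h.id for h in session.hits[:50]] == oracle


class TestExpand:
    def test_expand_increments(self, engine):
        session = engine.search("P00040", n_probe=64)
        assert session.scored_count == 50
        engine.expand(session, 50)
        assert session.scored_count == 100
        assert all(h.metrics is not None for h in session.scored_hits)

    def test_expand_clamps_to_candidates(self, benchmark_db, benchmark_index):
        chains, _ = benchmark_db
        engine = SearchEngine(
            benchmark_index, {c.id: c for c in chains},
            config=SearchConfig(n_probe=1, first_page=5),
        )
        session = engine.search("P00050")
        n = len(session.hits)
        engine.expand(session, 300)
        engine.expand(session, 300)
        engine.expand(session, 300)
        engine.expand(session, 300)
        assert session.scored_count == min(n, 5 + 4 * 300)

    def test_invalid_increment_rejected(self, engine):
        session = engine.search("P00060")
        with pytest.raises(ValueError, match="allowed"):
            engine.expand(session, 37)

    def test_expansion_order_irrelevant(self, benchmark_db, benchmark_index):
        """Expanding 50 then 100 scores the same hit set as 100 then 50."""
        chains, _ = benchmark_db
        store = {c.id: c for c in chains}
        config = SearchConfig(n_probe=64, first_page=5)
        e1 = SearchEngine(benchmark_index, store, config=config)
        e2 = SearchEngine(benchmark_index, store, config=config)
        s1 = e1.search("P00070")
        e1.expand(s1, 50)
        e1.expand(s1, 100)
        s2 = e2.search("P00070")
        e2.expand(s2, 100)
        e2.expand(s2, 50)
        assert [h.id for h in s1.scored_hits] == [h.id for h in s2.scored_hits]
        assert s1.scored_count == s2.scored_count == 155


class TestExportAndGrouping:
    @pytest.fixture()
    def scored_session(self, benchmark_db, benchmark_index):
        chains, _ = benchmark_db
        organisms = {c.id: ("Homo sapiens" if int(c.id[1:]) % 2 else "Mus musculus")
                     for c in chains[:500]}
        engine = SearchEngine(
            benchmark_index, {c.id: c for c in chains}, organisms=organisms,
            config=SearchConfig(n_probe=10, first_page=50),
        )
        return engine.search("P00001")

    def test_csv_row_count_and_roundtrip(self, scored_session, tmp_path):
        import pandas as pd
        path = tmp_path / "out.csv"
        export_csv(scored_session, path)
        lines = path.read_text().splitlines()
        assert len(lines) == scored_session.scored_count + 1
        assert lines[0] == ("query_id,result_id,embedding_distance,tm_score,"
                            "rmsd,aligned_residues,sequence_identity,organism")
        df = pd.read_csv(path)
        for row, hit in zip(df.itertuples(), scored_session.scored_hits):
            assert row.tm_score == pytest.approx(hit.metrics.tm_score, abs=5e-5)
            assert row.result_id == hit.id

    def test_export_requires_scored_hits(self, benchmark_db, benchmark_index, tmp_path):
        from foldsearch.search_engine import SearchSession
        with pytest.raises(ValueError):
            export_csv(SearchSession("q", hits=[]), tmp_path / "x.csv")

    def test_missing_organism_is_empty_field(self, scored_session, tmp_path):
        path = tmp_path / "out.csv"
        export_csv(scored_session, path)
        text = path.read_text()
        assert "unknown" not in text  # absent metadata is just empty

    def test_group_by_organism(self, scored_session):
        groups = group_by_organism(scored_session)
        sizes = sum(len(v) for v in groups.values())
        assert sizes == scored_session.scored_count
        # flattening groups and re-sorting by distance reproduces the ranking
        flat = [h for hits in groups.values() for h in hits]
        resorted = sorted(flat, key=lambda h: (h.embedding_distance, h.id))
        assert [h.id for h in resorted] == [h.id for h in scored_session.scored_hits]
        # groups ordered by best member distance
        bests = [hits[0].embedding_distance for hits in groups.values()]
        assert bests == sorted(bests)

    def test_all_missing_single_unknown_group(self, benchmark_db, benchmark_index):
        chains, _ = benchmark_db
        engine = SearchEngine(benchmark_index, {c.id: c for c in chains})
        session = engine.search("P00002")
        groups = group_by_organism(session)
        assert list(groups) == ["unknown"]


class TestChainStorePersistence:
    def test_roundtrip(self, tmp_path):
        from foldsearch.search_engine import load_chain_store, save_chain_store
        from foldsearch.structure_io import make_coil, make_helix
        chains = [make_helix(20, id="P00001"), make_coil(35, seed=1, id="P00002")]
        path = tmp_path / "chains.h5"
        save_chain_store(chains, path)
        back = load_chain_store(path)
        assert set(back) == {"P00001", "P00002"}
        np.testing.assert_allclose(back["P00002"].ca_coords, chains[1].ca_coords)
        assert back["P00001"].sequence == chains[0].sequence
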