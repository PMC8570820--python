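from __future__ import annotations

import numpy as np
import pytest

import pzsearch as pz
from pzsearch.errors import ConsistencyError, LimitError
from pzsearch.seqio import hits_table_text


class TestSearchBasics:
    def test_self_hit_ranks_first_at_full_identity(self, query300, small_reference):
        ref = small_reference.all_sequences() + [
            pz.AminoAcidSequence("S9999|copy", query300.residues, sample_id="S9999")
        ]
        result = pz.search([query300], [ref], pz.SearchConfig())
        hits = result.per_query[query300.id].hits
        assert hits, "expected at least the self-hit"
        top = hits[0]
        assert top.subject_id == "S9999|copy"
        assert top.percent_identity == 100.00
        assert top.evalue <= 1e-8
        assert (top.q_start, top.q_end) == (1, 300)

    def test_no_shared_kword_means_no_hits(self):
        q = pz.AminoAcidSequence("q", "ACDEFGHIKLMNPQRSTVWY" * 3)
        ref = [pz.AminoAcidSequence("r", "W" * 100)]
        result = pz.search([q], [ref], pz.SearchConfig())
        assert result.per_query["q"].hits == []

    def test_empty_reference_warns_and_returns_empty(self, query300, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="pzsearch.search"):
            result = pz.search([query300], [[]], pz.SearchConfig())
        assert result.per_query[query300.id].hits == []
        assert "empty" in caplog.text

    def test_query_limit_enforced(self, query300):
        queries = [
            pz.AminoAcidSequence(f"q{i}", query300.residues) for i in range(3)
        ]
        cfg = pz.SearchConfig(max_queries=2)
        with pytest.raises(LimitError):
            pz.search(queries, [[]], cfg)

    def test_every_reported_evalue_below_threshold(self, query300, small_reference):
        cfg = pz.SearchConfig()
        result = pz.search([query300], small_reference.chunks, cfg)
        assert all(
            h.evalue <= cfg.evalue_max for h in result.per_query[query300.id].hits
        )

    def test_hits_sorted_by_evalue_then_bits_then_subject(self, query300, small_reference):
        result = pz.search([query300], small_reference.chunks, pz.SearchConfig())
        hits = result.per_query[query300.id].hits
        keys = [(h.evalue, -h.bit_score, h.subject_id) for h in hits]
        assert keys == sorted(keys)


class TestSearchAgainstExhaustivePairOracle:
    def test_hit_set_equals_all_pairs_extension(self, query300, small_reference):
        """The streamed seed-index search finds exactly the pairs that running
        the extension machinery on every (query, subject) pair finds."""
        cfg = pz.SearchConfig()
        matrix = cfg.matrix()
        params = cfg.params()
        refs = small_reference.all_sequences()
        total_n = sum(len(s) for s in refs)
        expected = set()
        for subject in refs:
            hsps = pz.extend_pair(query300, subject, cfg, matrix)
            if not hsps:
                continue
            best = hsps[0]
            e = pz.evalue(best.raw_score, len(query300), total_n, params)
            if e <= cfg.evalue_max:
                expected.add((query300.id, subject.id))
        result = pz.search([query300], [refs], cfg)
        got = {h.pair for h in result.per_query[query300.id].hits}
        assert got == expected
        assert expected, "fixture should contain recoverable planted homologs"


class TestThresholdAndTruncation:
    def test_raising_max_hits_never_removes_hits(self, query300, small_reference):
        lo = pz.search(
            [query300], small_reference.chunks, pz.SearchConfig(max_hits_per_query=3)
        )
        hi = pz.search(
            [query300], small_reference.chunks, pz.SearchConfig(max_hits_per_query=100)
        )
        lo_ids = [h.subject_id for h in lo.per_query[query300.id].hits]
        hi_ids = [h.subject_id for h in hi.per_query[query300.id].hits]
        assert hi_ids[: len(lo_ids)] == lo_ids
        assert lo.per_query[query300.id].truncated

    def test_lowering_evalue_max_yields_subset(self, query300, small_reference):
        loose = pz.search(
            [query300], small_reference.chunks, pz.SearchConfig(evalue_max=1e-5)
        )
        strict = pz.search(
            [query300], small_reference.chunks, pz.SearchConfig(evalue_max=1e-20)
        )
        loose_pairs = {h.pair for h in loose.per_query[query300.id].hits}
        strict_pairs = {h.pair for h in strict.per_query[query300.id].hits}
        assert strict_pairs <= loose_pairs


class TestMergeInvariance:
    def test_single_chunk_merge_is_identity(self, query300, small_reference):
        cfg = pz.SearchConfig()
        refs = small_reference.all_sequences()
        total_n = sum(len(s) for s in refs)
        partial = pz.search_chunk([query300], refs, cfg, total_n)
        merged = pz.merge_chunk_results([partial], cfg)
        single = pz.search([query300], [refs], cfg)
        assert hits_table_text(merged.all_hits()) == hits_table_text(single.all_hits())

    def test_four_chunks_vs_single_pass_bit_identical(self, query300, planted_reference):
        cfg = pz.SearchConfig()
        refs = planted_reference.all_sequences()
        single = pz.search([query300], [refs], cfg)
        quarters = [refs[i::4] for i in range(4)]
        chunked = pz.search([query300], quarters, cfg)
        assert hits_table_text(chunked.all_hits()) == hits_table_text(single.all_hits())

    def test_equal_scoring_subjects_ordered_by_id_across_chunks(self, query300):
        copy_a = pz.AminoAcidSequence("SA|dup", query300.residues)
        copy_b = pz.AminoAcidSequence("SB|dup", query300.residues)
        cfg = pz.SearchConfig()
        forward = pz.search([query300], [[copy_a], [copy_b]], cfg)
        backward = pz.search([query300], [[copy_b], [copy_a]], cfg)
        ids_f = [h.subject_id for h in forward.per_query[query300.id].hits]
        ids_b = [h.subject_id for h in backward.per_query[query300.id].hits]
        assert ids_f == ids_b == ["SA|dup", "SB|dup"]

    def test_mismatched_configs_rejected(self, query300):
        refs = [pz.AminoAcidSequence("S1|a", query300.residues)]
        cfg1 = pz.SearchConfig()
        cfg2 = pz.SearchConfig(evalue_max=1e-5)
        p1 = pz.search_chunk([query300], refs, cfg1, len(query300))
        with pytest.raises(ConsistencyError):
            pz.merge_chunk_results([p1], cfg2)

    def test_duplicate_subject_ids_across_chunks_detected(self, query300):
        refs = [pz.AminoAcidSequence("S1|a", query300.residues)]
        cfg = pz.SearchConfig()
        p1 = pz.search_chunk([query300], refs, cfg, 600)
        p2 = pz.search_chunk([query300], refs, cfg, 600)
        with pytest.raises(ConsistencyError, match="duplicate subject"):
            pz.merge_chunk_results([p1, p2], cfg)

    def test_evalues_use_grand_total_not_per_chunk(self, query300):
        copy = pz.AminoAcidSequence("S1|copy", query300.residues)
        decoy = pz.AminoAcidSequence(
            "S2|decoy", pz.random_protein(500, np.random.default_rng(1))
        )
        both = pz.search([query300], [[copy], [decoy]], pz.SearchConfig())
        alone = pz.search([query300], [[copy]], pz.SearchConfig())
        e_both = both.per_query[query300.id].hits[0].evalue
        e_alone = alone.per_query[query300.id].hits[0].evalue
        # larger total reference -> proportionally larger E for the same hit
        assert e_both == pytest.approx(e_alone * (800 / 300), rel=1e-12)
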