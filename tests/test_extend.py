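from __future__ import annotations

import numpy as np
import pytest

import pzsearch as pz
from pzsearch.extend import smith_waterman_score

from _reference import brute_force_local_score
from conftest import random_protein_pair


def make_seed(q, s, q_pos, s_pos):
    return pz.SeedMatch(0, q_pos, s_pos)


class TestUngappedExtend:
    def run(self, blosum62, q, s, q_pos, s_pos, k=4, x_drop=20):
        return pz.ungapped_extend(
            make_seed(q, s, q_pos, s_pos),
            blosum62.encode(q),
            blosum62.encode(s),
            blosum62.array,
            k,
            x_drop,
            q,
            s,
        )

    def test_identical_sequences_extend_full_length(self, blosum62):
        q = "ACDEFGHIK"
        for pos in range(0, 6):
            hsp = self.run(blosum62, q, q, pos, pos)
            assert (hsp.q_start, hsp.q_end) == (0, 9)
            assert hsp.raw_score == 53  # sum of BLOSUM62 diagonal for A..K
            assert hsp.identities == 9

    def test_stop_walls_confine_extension(self, blosum62):
        q = "AAAA" + "ACDEFGHIK" + "AAAA"
        s = "****" + "ACDEFGHIK" + "****"
        hsp = self.run(blosum62, q, s, 6, 6)
        assert hsp.q_start >= 4 and hsp.q_end <= 13
        assert hsp.raw_score == 53

    def test_extension_never_scores_below_bare_seed(self, blosum62):
        rng = np.random.default_rng(3)
        for _ in range(50):
            q, s = random_protein_pair(rng, max_len=80, homolog=True)
            idx = pz.build_index([pz.AminoAcidSequence("q", q)], k=4)
            for sm in pz.scan_reference(idx, pz.AminoAcidSequence("s", s))[:5]:
                seed_score = sum(
                    blosum62.score(q[sm.q_pos + t], s[sm.s_pos + t]) for t in range(4)
                )
                hsp = self.run(blosum62, q, s, sm.q_pos, sm.s_pos)
                assert hsp.raw_score >= seed_score
                assert hsp.gap_opens == 0
                assert set(hsp.path) <= {"M"}


class TestGappedExtend:
    def test_identical_sequences_gapped_equals_ungapped(self, blosum62, query300):
        q = query300.residues
        hsp0 = pz.ungapped_extend(
            make_seed(q, q, 100, 100),
            blosum62.encode(q), blosum62.encode(q), blosum62.array, 4, 20, q, q,
        )
        hsp = pz.gapped_extend(
            hsp0, blosum62.encode(q), blosum62.encode(q), blosum62.array,
            11, 1, 38, 64, q, q,
        )
        assert hsp.raw_score == hsp0.raw_score
        assert hsp.gap_opens == 0

    def test_single_deletion_recovers_optimal_gap_placement(self, blosum62):
        """Subject = query minus one residue: one gap open, score matches the
        full-DP optimum computed by an independent implementation."""
        rng = np.random.default_rng(8)
        q = pz.random_protein(100, rng)
        s = q[:60] + q[61:]
        hsps = pz.extend_pair(
            pz.AminoAcidSequence("q", q), pz.AminoAcidSequence("s", s),
            pz.SearchConfig(), blosum62,
        )
        expected = brute_force_local_score(q, s, blosum62.score, 11, 1)
        assert hsps[0].raw_score == expected
        assert hsps[0].gap_opens == 1

    def test_widening_band_never_decreases_score(self, blosum62):
        rng = np.random.default_rng(9)
        q = pz.random_protein(120, rng)
        s, _ = pz.mutate_homolog(q, 0.7, 0.05, rng)
        qe, se = blosum62.encode(q), blosum62.encode(s)
        hsp0 = pz.ungapped_extend(make_seed(q, s, 0, 0), qe, se, blosum62.array, 4, 20, q, s)
        scores = [
            pz.gapped_extend(hsp0, qe, se, blosum62.array, 11, 1, 38, bw, q, s).raw_score
            for bw in (8, 16, 32, 64, 128)
        ]
        assert scores == sorted(scores)


class TestSmithWaterman:
    def test_short_self_alignment_hand_score(self, blosum62):
        hsp = pz.smith_waterman("ACDE", "ACDE", blosum62, 11, 1)
        assert hsp.raw_score == 24  # 4+9+6+5, no gapped alternative can beat it
        assert hsp.path == "MMMM"

    def test_score_symmetric_in_arguments(self, blosum62):
        rng = np.random.default_rng(21)
        for _ in range(10):
            q, s = random_protein_pair(rng, max_len=60, homolog=True)
            a = pz.smith_waterman(q, s, blosum62, 11, 1).raw_score
            b = pz.smith_waterman(s, q, blosum62, 11, 1).raw_score
            assert a == b

    def test_matches_independent_brute_force_dp(self, blosum62):
        rng = np.random.default_rng(33)
        for _ in range(40):
            q, s = random_protein_pair(rng, max_len=30, homolog=bool(rng.integers(2)))
            got = pz.smith_waterman(q, s, blosum62, 11, 1).raw_score
            want = brute_force_local_score(q, s, blosum62.score, 11, 1)
            assert got == want

    def test_matches_biopython_aligner(self, blosum62):
        """Cross-validation against an entirely external local aligner."""
        from Bio import Align
        from Bio.Align import substitution_matrices

        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
        rng = np.random.default_rng(55)
        for _ in range(20):
            q, s = random_protein_pair(rng, max_len=120, homolog=bool(rng.integers(2)))
            got = pz.smith_waterman(q, s, blosum62, 11, 1).raw_score
            assert got == int(aligner.score(q, s))

    def test_score_only_kernel_agrees_with_traceback_kernel(self, blosum62):
        rng = np.random.default_rng(77)
        for _ in range(30):
            q, s = random_protein_pair(rng, max_len=150, homolog=bool(rng.integers(2)))
            full = pz.smith_waterman(q, s, blosum62, 11, 1).raw_score
            fast = smith_waterman_score(
                blosum62.encode(q), blosum62.encode(s), blosum62.array, 11, 1
            )
            assert full == fast

    def test_empty_sequence_rejected(self, blosum62):
        with pytest.raises(ValueError):
            pz.smith_waterman("", "ACDE", blosum62)


class TestPathReplay:
    def test_replay_reproduces_scores_on_random_hsps(self, blosum62):
        rng = np.random.default_rng(99)
        cfg = pz.SearchConfig()
        for _ in range(30):
            q, s = random_protein_pair(rng, max_len=150, homolog=True)
            for hsp in pz.extend_pair(
                pz.AminoAcidSequence("q", q), pz.AminoAcidSequence("s", s), cfg, blosum62
            ):
                score, identities, gap_opens = pz.replay_score(
                    hsp.path, hsp.q_start, hsp.s_start, q, s, blosum62, 11, 1
                )
                assert score == hsp.raw_score
                assert identities == hsp.identities
                assert gap_opens == hsp.gap_opens
                # column counts consistent with coordinates
                assert hsp.path.count("M") + hsp.path.count("I") == hsp.q_end - hsp.q_start
                assert hsp.path.count("M") + hsp.path.count("D") == hsp.s_end - hsp.s_start

    def test_heuristic_never_beats_oracle(self, blosum62):
        rng = np.random.default_rng(123)
        cfg = pz.SearchConfig()
        for _ in range(30):
            q, s = random_protein_pair(rng, max_len=150, homolog=bool(rng.integers(2)))
            oracle = smith_waterman_score(
                blosum62.encode(q), blosum62.encode(s), blosum62.array, 11, 1
            )
            for hsp in pz.extend_pair(
                pz.AminoAcidSequence("q", q), pz.AminoAcidSequence("s", s), cfg, blosum62
            ):
                assert hsp.raw_score <= oracle

    def test_exact_copy_recovers_oracle_score(self, blosum62, query300):
        q = query300
        copy = pz.AminoAcidSequence("copy", q.residues)
        hsps = pz.extend_pair(q, copy, pz.SearchConfig(), blosum62)
        oracle = smith_waterman_score(
            blosum62.encode(q.residues), blosum62.encode(q.residues), blosum62.array, 11, 1
        )
        assert hsps[0].raw_score == oracle
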