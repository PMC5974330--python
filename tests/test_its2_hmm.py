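from __future__ import annotations

import json

import numpy as np
import pytest

from herbauth import simulate
from herbauth.its2_hmm import (
    ProfileHMM,
    annotate_its2,
    build_profile,
    calibrate_threshold,
    dinucleotide_shuffle,
    load_packaged_seeds,
    trim_batch,
    viterbi_locate,
    _scan_one_strand,
)

from conftest import random_dna
from _oracles import oracle_viterbi


class TestBuildProfile:
    def test_identical_ungapped_sequences(self):
        hmm = build_profile(["ACGTACGTACGTACGTACGT"] * 4, pseudocount=1.0)
        assert hmm.L == 20
        # each match row puts (n + pc) / (n + 4 pc) = 5/8 on the observed base
        for j, ch in enumerate("ACGTACGTACGTACGTACGT", start=1):
            row = hmm.match_emissions[j]
            assert row["ACGT".index(ch)] == pytest.approx(5 / 8)
            assert row.sum() == pytest.approx(1.0)

    def test_half_a_half_c_column(self):
        # column 0: 50% A / 50% C over n=4, pseudocount 1 -> (3/8, 3/8, 1/8, 1/8)
        seqs = ["AGGG", "AGGG", "CGGG", "CGGG"]
        hmm = build_profile(seqs, pseudocount=1.0)
        assert hmm.match_emissions[1] == pytest.approx([3 / 8, 3 / 8, 1 / 8, 1 / 8])

    def test_empty_alignment_errors(self):
        with pytest.raises(ValueError, match="empty"):
            build_profile([])

    def test_invalid_characters_error(self):
        with pytest.raises(ValueError, match="invalid"):
            build_profile(["ACGU"])

    def test_gap_majority_column_is_insert(self):
        seqs = ["A-GT", "A-GT", "ACGT", "A-GT"]
        hmm = build_profile(seqs)
        assert hmm.L == 3  # column 1 has 25% residues -> insert column

    def test_emission_rows_normalized(self):
        hmm = build_profile(["ACGTAC", "AC-TAC", "ACGTTC"], pseudocount=0.5)
        assert np.allclose(hmm.match_emissions[1:].sum(axis=1), 1.0)

    def test_json_roundtrip(self, tmp_path):
        hmm = build_profile(["ACGTACGT", "ACTTACGT", "ACGTACCT"], name="rt")
        hmm.score_threshold = 3.25
        p = tmp_path / "hmm.json"
        hmm.to_json(p)
        back = ProfileHMM.from_json(p)
        assert back.name == "rt" and back.L == hmm.L
        assert np.allclose(back.match_emissions, hmm.match_emissions)
        assert np.allclose(back.transitions, hmm.transitions)
        assert back.score_threshold == 3.25


@pytest.fixture(scope="module")
def small_hmm():
    seed_l, _ = load_packaged_seeds()
    return build_profile(seed_l, name="left")


class TestViterbiLocate:
    def test_consensus_at_offset(self, small_hmm, rng):
        motif = small_hmm.consensus()
        seq = random_dna(rng, 37) + motif + random_dna(rng, 60)
        hit = viterbi_locate(small_hmm, seq, threshold=0.0)
        assert (hit.start, hit.end) == (37, 37 + small_hmm.L)
        assert hit.strand == "+"

    def test_consensus_at_position_zero(self, small_hmm, rng):
        seq = small_hmm.consensus() + random_dna(rng, 50)
        hit = viterbi_locate(small_hmm, seq, threshold=0.0)
        assert hit.start == 0 and hit.end == small_hmm.L

    def test_reverse_strand_mapped_back(self, small_hmm, rng):
        from herbauth._dp import revcomp

        seq = random_dna(rng, 40) + small_hmm.consensus() + random_dna(rng, 40)
        hit = viterbi_locate(small_hmm, revcomp(seq), threshold=0.0)
        n = len(seq)
        assert hit.strand == "-"
        assert (hit.start, hit.end) == (n - (40 + small_hmm.L), n - 40)

    def test_empty_sequence_errors(self, small_hmm):
        with pytest.raises(ValueError):
            viterbi_locate(small_hmm, "")

    def test_oracle_equivalence_small_sequences(self, small_hmm, rng):
        for _ in range(10):
            n = int(rng.integers(30, 120))
            if rng.random() < 0.5:
                seq = random_dna(rng, n)
            else:  # embed a noisy motif so high-scoring paths are exercised
                motif = list(small_hmm.consensus())
                for p in rng.choice(len(motif), 5, replace=False):
                    motif[p] = str(rng.choice(list("ACGT")))
                pad = random_dna(rng, max(0, n - len(motif)))
                seq = pad[: n // 3] + "".join(motif) + pad[n // 3 :]
            got = _scan_one_strand(small_hmm, seq)
            want = oracle_viterbi(small_hmm, seq)
            assert got[0] == pytest.approx(want[0], abs=1e-9)
            assert (got[1], got[2]) == (want[1], want[2])

    def test_score_context_invariance(self, small_hmm, rng):
        motif = small_hmm.consensus()
        scores = set()
        for _ in range(5):
            seq = random_dna(rng, 80) + motif + random_dna(rng, 80)
            hit = viterbi_locate(small_hmm, seq, threshold=0.0)
            scores.add(round(hit.score, 9))
        assert len(scores) == 1  # glocal score independent of flanking context

    def test_shuffled_null_mostly_below_threshold(self, flank_hmms):
        hmm, _ = flank_hmms
        rng = np.random.default_rng(123)
        consensus = hmm.consensus()
        none_count = 0
        for _ in range(100):
            null = dinucleotide_shuffle(consensus + random_dna(rng, 440), rng)
            if viterbi_locate(hmm, null, both_strands=False) is None:
                none_count += 1
        assert none_count >= 95

    def test_true_motif_scores_far_above_threshold(self, flank_hmms, rng):
        for hmm, motif in zip(flank_hmms, (simulate.FLANK_5P8S, simulate.FLANK_28S)):
            seq = random_dna(rng, 100) + motif + random_dna(rng, 100)
            hit = viterbi_locate(hmm, seq)
            assert hit is not None and hit.score > hmm.score_threshold + 20


class TestDinucleotideShuffle:
    def test_preserves_dinucleotide_counts(self, rng):
        from collections import Counter

        seq = random_dna(rng, 300)
        shuf = dinucleotide_shuffle(seq, rng)
        assert len(shuf) == len(seq)
        assert Counter(zip(seq, seq[1:])) == Counter(zip(shuf, shuf[1:]))

    def test_deterministic_under_seed(self):
        seq = "ACGTACGGTTACGATCGATCGGGATC" * 5
        a = dinucleotide_shuffle(seq, np.random.default_rng(7))
        b = dinucleotide_shuffle(seq, np.random.default_rng(7))
        assert a == b


class TestCalibrateThreshold:
    def test_threshold_set_and_returned(self, small_hmm):
        t = calibrate_threshold(small_hmm, n_shuffles=50, seed=1)
        assert t == small_hmm.score_threshold
        assert np.isfinite(t)


class TestAnnotateITS2:
    def test_flanked_fixture_exact_coordinates(self, flank_hmms, rng):
        hmm_l, hmm_r = flank_hmms
        its2 = random_dna(rng, 250)
        seq = simulate.FLANK_5P8S + its2 + simulate.FLANK_28S
        ann = annotate_its2(seq, hmm_l, hmm_r)
        assert ann.status == "both_flanks"
        assert (ann.its2_start, ann.its2_end) == (60, 310)
        assert seq[ann.its2_start : ann.its2_end] == its2

    def test_bare_its2_untouched(self, flank_hmms, rng):
        hmm_l, hmm_r = flank_hmms
        seq = random_dna(rng, 250)
        ann = annotate_its2(seq, hmm_l, hmm_r)
        assert ann.status == "none"
        assert (ann.its2_start, ann.its2_end) == (0, 250)

    def test_trim_is_idempotent(self, flank_hmms, rng):
        hmm_l, hmm_r = flank_hmms
        seq = simulate.FLANK_5P8S + random_dna(rng, 250) + simulate.FLANK_28S
        ann = annotate_its2(seq, hmm_l, hmm_r)
        trimmed = seq[ann.its2_start : ann.its2_end]
        ann2 = annotate_its2(trimmed, hmm_l, hmm_r)
        assert ann2.status == "none"

    def test_left_only(self, flank_hmms, rng):
        hmm_l, hmm_r = flank_hmms
        seq = simulate.FLANK_5P8S + random_dna(rng, 250)
        ann = annotate_its2(seq, hmm_l, hmm_r)
        assert ann.status == "left_only" and ann.its2_start == 60

    def test_conservation_of_length(self, flank_hmms, rng):
        hmm_l, hmm_r = flank_hmms
        for _ in range(5):
            its2 = random_dna(rng, int(rng.integers(150, 350)))
            seq = simulate.FLANK_5P8S + its2 + simulate.FLANK_28S
            ann = annotate_its2(seq, hmm_l, hmm_r)
            left = ann.its2_start
            right = len(seq) - ann.its2_end
            assert left + len(seq[ann.its2_start : ann.its2_end]) + right == len(seq)

    def test_windowed_scan_matches_full(self, flank_hmms, rng):
        hmm_l, hmm_r = flank_hmms
        seq = simulate.FLANK_5P8S + random_dna(rng, 250) + simulate.FLANK_28S
        full = annotate_its2(seq, hmm_l, hmm_r)
        win = annotate_its2(seq, hmm_l, hmm_r, window=150)
        assert (full.its2_start, full.its2_end) == (win.its2_start, win.its2_end)


class TestTrimBatch:
    def test_five_flanked_fixtures(self, flank_hmms, rng):
        hmm_l, hmm_r = flank_hmms
        records = [
            (f"rec{i}", simulate.FLANK_5P8S + random_dna(rng, 200 + 10 * i) + simulate.FLANK_28S)
            for i in range(5)
        ]
        trimmed, report = trim_batch(records, hmm_l, hmm_r)
        assert len(trimmed) == 5
        assert all(row["status"] == "both_flanks" for row in report)

    def test_short_trim_dropped(self, flank_hmms, rng):
        hmm_l, hmm_r = flank_hmms
        records = [("tiny", simulate.FLANK_5P8S + random_dna(rng, 40) + simulate.FLANK_28S)]
        trimmed, report = trim_batch(records, hmm_l, hmm_r)
        assert trimmed == []
        assert report[0]["kept"] is False

    def test_empty_input(self, flank_hmms):
        assert trim_batch([], *flank_hmms) == ([], [])
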