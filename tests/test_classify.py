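from __future__ import annotations

import pytest

from herbauth import simulate
from herbauth._dp import revcomp
from herbauth.classify import (
    AbundanceTable,
    AlignmentHit,
    Assignment,
    ClassifyParams,
    align_read,
    assign_read,
    candidate_refs,
    classify_reads,
    make_alignment_locator,
    multimapped_reads,
    screen_prescription,
    tabulate,
)
from herbauth.refdb import ReferenceDB, ReferenceRecord, curate

from conftest import random_dna
from _oracles import oracle_overlap_identity


def _hit(species, identity, score, coverage=100.0, rid="r"):
    return AlignmentHit(
        read_id=rid,
        record_id=species,
        species=species,
        identity=identity,
        query_coverage=coverage,
        score=score,
        strand="+",
    )


class TestAlignRead:
    def test_identical_sequences(self, rng):
        seq = random_dna(rng, 300)
        hit = align_read(seq, seq)
        assert hit.identity == 100.0 and hit.query_coverage == 100.0
        assert hit.strand == "+" and hit.score == 300.0

    def test_single_substitution(self, rng):
        ref = random_dna(rng, 100)
        q = list(ref)
        q[50] = {"A": "C", "C": "A", "G": "T", "T": "G"}[q[50]]
        hit = align_read("".join(q), ref)
        assert hit.identity == pytest.approx(99.0)

    def test_reverse_complement_minus_strand(self, rng):
        ref = random_dna(rng, 200)
        hit = align_read(revcomp(ref), ref)
        assert hit.identity == 100.0 and hit.strand == "-"

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            align_read("", "ACGT")

    def test_oracle_equivalence_random_pairs(self, rng):
        for _ in range(40):
            q = random_dna(rng, int(rng.integers(20, 150)))
            r = random_dna(rng, int(rng.integers(20, 150)))
            hit = align_read(q, r, strand="+")
            score, identity, coverage = oracle_overlap_identity(q, r)
            assert hit.score == pytest.approx(score)
            assert hit.identity == pytest.approx(identity)
            assert hit.query_coverage == pytest.approx(coverage)

    def test_banded_matches_full_on_near_identical(self, rng):
        for _ in range(20):
            ref = random_dna(rng, int(rng.integers(100, 350)))
            q = list(ref)
            for p in rng.choice(len(q), size=3, replace=False):
                q[p] = str(rng.choice(list("ACGT")))
            q = "".join(q)
            full = align_read(q, ref, strand="+")
            banded = align_read(q, ref, strand="+", band=48)
            assert (full.score, full.identity) == (banded.score, banded.identity)

    def test_partial_overlap_reduces_coverage(self, rng):
        ref = random_dna(rng, 100)
        q = ref[:60] + random_dna(rng, 0)
        tail = random_dna(rng, 60)
        hit = align_read(ref[:60] + tail, ref)
        assert hit.query_coverage < 100.0


@pytest.fixture(scope="module")
def curated_db(flank_hmms, refset3):
    db, _ = curate(refset3.records(), *flank_hmms)
    return db


class TestCandidateRefs:
    def test_identical_read_is_candidate(self, curated_db):
        rec = curated_db.records[0]
        assert rec.id in candidate_refs(rec.sequence, curated_db)

    def test_random_read_yields_no_candidates(self, rng, curated_db):
        # null model: ~143 distinct 8-mers/read x ~320 per ref / 4^8 ≈ 0.7
        # expected shared k-mers per (ref, strand); P(>= 5) is negligible
        for _ in range(10):
            assert candidate_refs(random_dna(rng, 150), curated_db) == []

    def test_superset_of_qualifying_alignments(self, rng, curated_db):
        params = ClassifyParams()
        for rec in curated_db.records:
            noisy = list(rec.sequence)
            for p in rng.choice(len(noisy), size=5, replace=False):
                noisy[p] = str(rng.choice(list("ACGT")))
            read = "".join(noisy)
            cands = set(candidate_refs(read, curated_db, params))
            qualifying = {
                other.id
                for other in curated_db.records
                if align_read(read, other).identity >= params.min_identity
                and align_read(read, other).query_coverage >= params.min_query_coverage
            }
            assert qualifying <= cands


class TestAssignRead:
    def test_single_good_hit_assigned(self):
        a = assign_read([_hit("Panax ginseng", 98.0, 290)])
        assert a.label == "Panax ginseng"

    def test_below_identity_threshold_unassigned(self):
        a = assign_read([_hit("Panax ginseng", 96.5, 280)])
        assert a.is_unassigned

    def test_below_coverage_unassigned(self):
        a = assign_read([_hit("Panax ginseng", 99.0, 280, coverage=60.0)])
        assert a.is_unassigned

    def test_congeneric_tie_collapses_to_genus(self):
        hits = [_hit("Arisaema amurense", 99.0, 300), _hit("Arisaema erubescens", 99.0, 300)]
        a = assign_read(hits)
        assert a.label == "AMBIGUOUS(Arisaema)"

    def test_cross_genus_tie_lists_species(self):
        hits = [_hit("Arisaema amurense", 99.0, 300), _hit("Pinellia pedatisecta", 99.0, 300)]
        a = assign_read(hits)
        assert a.label == "AMBIGUOUS(Arisaema amurense|Pinellia pedatisecta)"

    def test_unique_best_score_wins_over_higher_identity(self):
        hits = [_hit("A a", 100.0, 200, coverage=80.0), _hit("B b", 97.5, 290)]
        a = assign_read(hits)
        assert a.label == "B b"

    def test_no_hits_unassigned(self):
        assert assign_read([]).is_unassigned

    def test_monotonicity_in_identity_threshold(self, rng):
        hits = [
            _hit(f"S{i} sp", float(rng.uniform(90, 100)), float(rng.uniform(100, 300)))
            for i in range(30)
        ]
        assigned_counts = []
        for thr in (90.0, 95.0, 97.0, 99.0, 100.0):
            n = sum(
                not assign_read([h], ClassifyParams(min_identity=thr)).is_unassigned
                for h in hits
            )
            assigned_counts.append(n)
        assert assigned_counts == sorted(assigned_counts, reverse=True)


class TestTabulate:
    def test_counting_and_order(self):
        assignments = (
            [Assignment("r", "A a")] * 7 + [Assignment("r", "B b")] * 2 + [Assignment("r", "UNASSIGNED")]
        )
        table = tabulate(assignments)
        assert table.rows[0][::2] == ("A a", 7)
        assert table.rows[1][::2] == ("B b", 2)
        assert table.unassigned == 1 and table.total == 10

    def test_empty_input(self):
        table = tabulate([])
        assert table.rows == () and table.total == 0

    def test_all_ambiguous(self):
        assignments = [Assignment("r", "AMBIGUOUS(X)")] * 4
        table = tabulate(assignments)
        assert table.rows == () and table.ambiguous == table.total == 4

    def test_conservation(self, rng):
        labels = ["A a", "B b", "AMBIGUOUS(C)", "UNASSIGNED"]
        assignments = [Assignment("r", labels[int(rng.integers(4))]) for _ in range(57)]
        assert tabulate(assignments).total == 57


class TestScreenPrescription:
    def _table(self, counts):
        rows = tuple((sp, sp, c) for sp, c in counts.items())
        return AbundanceTable(rows=rows, ambiguous=0, unassigned=0)

    def test_partition(self):
        report = screen_prescription(self._table({"A a": 100, "X x": 5}), ["A a", "B b"])
        assert report.present == ("A a",)
        assert report.absent == ("B b",)
        assert report.extra == ("X x",)

    def test_detection_threshold_boundary(self):
        report = screen_prescription(self._table({"A a": 100, "X x": 1}), ["A a"])
        assert report.extra == ()
        report2 = screen_prescription(self._table({"A a": 100, "X x": 2}), ["A a"])
        assert report2.extra == ("X x",)

    def test_clean_report(self):
        report = screen_prescription(self._table({"A a": 10, "B b": 20}), ["A a", "B b"])
        assert report.clean


class TestEndToEnd:
    def test_error_free_reads_fully_correct(self, curated_db, refset3):
        # species are >= 3% diverged; error-free ITS2 reads must all be correct
        reads = [seq for seq in refset3.its2.values()]
        species = list(refset3.its2.keys())
        assignments = classify_reads(reads, curated_db)
        assert [a.label for a in assignments] == species

    def test_conservation_every_run(self, curated_db, refset3, rng):
        reads = [random_dna(rng, 300) for _ in range(5)] + list(refset3.its2.values())
        assignments = classify_reads(reads, curated_db)
        table = tabulate(assignments)
        assert table.total == len(reads)

    def test_multimapped_report(self):
        assignments = [Assignment("r1", "AMBIGUOUS(X)"), Assignment("r2", "A a")]
        assert [a.read_id for a in multimapped_reads(assignments)] == ["r1"]

    def test_alignment_locator_for_run_qc(self, curated_db, refset3):
        locate = make_alignment_locator(curated_db)
        rec = curated_db.records[0]
        from herbauth.io_qc import SequenceRead

        read = SequenceRead(id="q", bases=rec.sequence, quals=(30,) * len(rec.sequence))
        rid, start, end = locate(read)
        assert rid == rec.id and (start, end) == (0, len(rec.sequence))
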