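"""Identity-threshold best-hit species assignment and abundance tabulation.

Each QC-passed read is aligned (overlap alignment, free terminal gaps on
both sequences; match +1, mismatch -1, gap open -2, gap extend -1) against
candidate references selected by a shared-k-mer prefilter. A hit qualifies
when percent identity >= 97 and query coverage >= 80 (defaults). The unique
best-scoring species wins the read; a best-score tie across >= 2 species is
reported as AMBIGUOUS (collapsed to a genus label when all tied species
share one genus); no qualifying hit leaves the read UNASSIGNED.

Identity is percent of matching aligned columns (BLAST-style), distinct from
query coverage (percent of query bases inside the aligned region).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from ._dp import encode_seq, overlap_align, overlap_align_banded, revcomp
from .io_qc import SequenceRead
from .refdb import ReferenceDB, kmers

UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class ClassifyParams:
    min_identity: float = 97.0
    min_query_coverage: float = 80.0
    k: int = 8
    min_shared_kmers: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 100):
            raise ValueError("min_identity must be in (0, 100]")
        if not (0 < self.min_query_coverage <= 100):
            raise ValueError("min_query_coverage must be in (0, 100]")


@dataclass(frozen=True)
class AlignmentHit:
    read_id: str
    record_id: str
    species: str
    identity: float
    query_coverage: float
    score: float
    strand: str
    ref_start: int = 0
    ref_end: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.identity <= 100 and 0 <= self.query_coverage <= 100):
            raise ValueError("identity and coverage must be percentages")


@dataclass(frozen=True)
class Assignment:
    read_id: str
    label: str  # species, "AMBIGUOUS(...)" or "UNASSIGNED"
    best_hits: tuple[AlignmentHit, ...] = ()

    @property
    def is_ambiguous(self) -> bool:
        return self.label.startswith("AMBIGUOUS")

    @property
    def is_unassigned(self) -> bool:
        return self.label == UNASSIGNED


@dataclass(frozen=True)
class AbundanceTable:
    rows: tuple[tuple[str, str, int], ...]  # (species, latin name, count), descending
    ambiguous: int
    unassigned: int

    @property
    def total(self) -> int:
        return sum(c for _, _, c in self.rows) + self.ambiguous + self.unassigned

    def species_counts(self) -> dict[str, int]:
        return {species: count for species, _, count in self.rows}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["species", "latin_name", "count"])

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        extra = pd.DataFrame(
            [("AMBIGUOUS", "", self.ambiguous), (UNASSIGNED, "", self.unassigned)],
            columns=df.columns,
        )
        pd.concat([df, extra], ignore_index=True).to_csv(path, sep="\t", index=False)


def _shared_kmers_by_strand(seq: str, db: ReferenceDB, k: int) -> dict[str, tuple[int, int]]:
    out: dict[str, tuple[int, int]] = {}
    for si, strand_seq in enumerate((seq, revcomp(seq))):
        strand_counts: Counter[str] = Counter()
        for kmer in kmers(strand_seq, k):
            for rid in db.kmer_index.get(kmer, ()):
                strand_counts[rid] += 1
        for rid, c in strand_counts.items():
            fwd, rev = out.get(rid, (0, 0))
            out[rid] = (max(fwd, c), rev) if si == 0 else (fwd, max(rev, c))
    return out


def candidate_refs(read: SequenceRead | str, db: ReferenceDB, params: ClassifyParams | None = None) -> list[str]:
    """Records sharing >= min_shared_kmers distinct k-mers with the read.

    Both strands are considered. This is a BLAST-seeding stand-in; on small
    instances it is a superset of the records with qualifying alignments
    (tested against exhaustive alignment).
    """
    params = params or ClassifyParams()
    seq = read if isinstance(read, str) else read.bases
    shared = _shared_kmers_by_strand(seq, db, params.k)
    return sorted(
        rid for rid, (f, r) in shared.items() if max(f, r) >= params.min_shared_kmers
    )


def _align_one_strand(query: str, reference: str, band: int = 0):
    q = encode_seq(query)
    r = encode_seq(reference)
    if band > 0:
        res = overlap_align_banded(q, r, band + abs(len(query) - len(reference)))
    else:
        res = overlap_align(q, r)
    score, matches, cols, qbases, _qs, rs, _qe, re_ = res
    identity = 100.0 * matches / cols if cols else 0.0
    coverage = 100.0 * qbases / len(query) if query else 0.0
    return score, identity, coverage, rs, re_


def align_read(
    read: SequenceRead | str, record, read_id: str = "", species: str = "", strand: str = "both",
    band: int = 0,
) -> AlignmentHit:
    """Best-strand overlap alignment of a read against one reference record.

    ``record`` is a ReferenceRecord or a plain sequence string. Identity =
    matches / aligned columns x 100; query coverage = query bases inside the
    aligned region / query length x 100. Plus strand wins ties; ``strand``
    can restrict the search to "+" or "-".
    """
    query = read if isinstance(read, str) else read.bases
    rid = read_id or (getattr(read, "id", "") if not isinstance(read, str) else "")
    ref_seq = record if isinstance(record, str) else record.sequence
    record_id = getattr(record, "id", "")
    species = species or getattr(record, "species", "")
    if not query or not ref_seq:
        raise ValueError("align_read requires non-empty sequences")

    fwd = _align_one_strand(query, ref_seq, band) if strand in ("both", "+") else None
    rev = _align_one_strand(revcomp(query), ref_seq, band) if strand in ("both", "-") else None
    if fwd is None or (rev is not None and rev[0] > fwd[0]):
        score, identity, coverage, rs, re_ = rev
        strand = "-"
    else:
        score, identity, coverage, rs, re_ = fwd
        strand = "+"
    return AlignmentHit(
        read_id=rid,
        record_id=record_id,
        species=species,
        identity=identity,
        query_coverage=coverage,
        score=score,
        strand=strand,
        ref_start=rs,
        ref_end=re_,
    )


def assign_read(
    hits: list[AlignmentHit],
    params: ClassifyParams | None = None,
    genus_of=None,
    read_id: str = "",
) -> Assignment:
    """Resolve a read's hits into a species / AMBIGUOUS / UNASSIGNED label.

    genus_of maps species -> genus for the ambiguity collapse; by default the
    first token of the binomial is used.
    """
    params = params or ClassifyParams()
    if genus_of is None:
        genus_of = lambda sp: sp.split()[0]  # noqa: E731
    rid = read_id or (hits[0].read_id if hits else "")
    qualifying = [
        h
        for h in hits
        if h.identity >= params.min_identity and h.query_coverage >= params.min_query_coverage
    ]
    if not qualifying:
        return Assignment(rid, UNASSIGNED)
    best_score = max(h.score for h in qualifying)
    best = [h for h in qualifying if h.score == best_score]
    species = sorted({h.species for h in best})
    if len(species) == 1:
        return Assignment(rid, species[0], tuple(best))
    genera = {genus_of(sp) for sp in species}
    if len(genera) == 1:
        label = f"AMBIGUOUS({genera.pop()})"
    else:
        label = f"AMBIGUOUS({'|'.join(species)})"
    return Assignment(rid, label, tuple(best))


def classify_read(
    read: SequenceRead | str,
    db: ReferenceDB,
    params: ClassifyParams | None = None,
    read_id: str = "",
    band: int = 0,
) -> Assignment:
    """Prefilter, align and resolve a single read.

    The k-mer prefilter also decides which strand to align: only when the
    forward and reverse shared-k-mer counts are close is the slower
    both-strand alignment used.
    """
    params = params or ClassifyParams()
    rid = read_id or getattr(read, "id", "")
    seq = read if isinstance(read, str) else read.bases
    shared = _shared_kmers_by_strand(seq, db, params.k)
    hits = []
    for record_id in sorted(shared):
        f, r = shared[record_id]
        if max(f, r) < params.min_shared_kmers:
            continue
        if f >= 2 * r and f > r + 5:
            strand = "+"
        elif r >= 2 * f and r > f + 5:
            strand = "-"
        else:
            strand = "both"
        hits.append(align_read(read, db.get(record_id), read_id=rid, strand=strand, band=band))
    return assign_read(hits, params, genus_of=db.genus_of, read_id=rid)


def classify_reads(
    reads, db: ReferenceDB, params: ClassifyParams | None = None, band: int = 0
) -> list[Assignment]:
    """Classify a batch of reads.

    ``band`` > 0 switches to banded alignment (exact when query and
    reference are near-identical and similar in length -- the curated-db
    case); 0 runs the full quadratic DP.
    """
    params = params or ClassifyParams()
    return [classify_read(read, db, params, band=band) for read in reads]


def tabulate(assignments, db: ReferenceDB | None = None, latin_names: dict[str, str] | None = None) -> AbundanceTable:
    """Per-species read counts sorted descending; zero-count species omitted."""
    counts: Counter[str] = Counter()
    ambiguous = 0
    unassigned = 0
    for a in assignments:
        if a.is_unassigned:
            unassigned += 1
        elif a.is_ambiguous:
            ambiguous += 1
        else:
            counts[a.label] += 1
    latin_names = latin_names or {}
    rows = tuple(
        (species, latin_names.get(species, species), count)
        for species, count in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    )
    return AbundanceTable(rows=rows, ambiguous=ambiguous, unassigned=unassigned)


@dataclass(frozen=True)
class ScreeningReport:
    present: tuple[str, ...]
    absent: tuple[str, ...]
    extra: tuple[str, ...]  # detected but not prescribed: putative adulterants
    detection_min: int

    @property
    def clean(self) -> bool:
        return not self.absent and not self.extra

    def to_dict(self) -> dict:
        return {
            "prescribed_present": list(self.present),
            "prescribed_absent": list(self.absent),
            "non_prescribed_detected": list(self.extra),
            "detection_min": self.detection_min,
            "clean": self.clean,
        }


def screen_prescription(table: AbundanceTable, prescription, detection_min: int = 2) -> ScreeningReport:
    """Partition detected species into prescribed-present / absent / extra.

    A species counts as detected when its read count >= detection_min
    (default 2, guarding against singleton noise).
    """
    prescription = set(prescription)
    detected = {sp for sp, _, c in table.rows if c >= detection_min}
    return ScreeningReport(
        present=tuple(sorted(prescription & detected)),
        absent=tuple(sorted(prescription - detected)),
        extra=tuple(sorted(detected - prescription)),
        detection_min=detection_min,
    )


def make_alignment_locator(db: ReferenceDB, params: ClassifyParams | None = None):
    """A run_qc hook mapping a read to its best reference span."""
    params = params or ClassifyParams()

    def locate(read: SequenceRead):
        best = None
        for record_id in candidate_refs(read, db, params):
            hit = align_read(read, db.get(record_id))
            if best is None or hit.score > best.score:
                best = hit
        if best is None:
            return None
        return best.record_id, best.ref_start, best.ref_end

    return locate


def hits_to_tsv(hits, path: str | Path) -> None:
    """BLAST outfmt-6-like hit table."""
    pd.DataFrame(
        [
            {
                "qseqid": h.read_id,
                "sseqid": h.record_id,
                "species": h.species,
                "pident": round(h.identity, 3),
                "qcov": round(h.query_coverage, 3),
                "score": h.score,
                "strand": h.strand,
                "sstart": h.ref_start,
                "send": h.ref_end,
            }
            for h in hits
        ]
    ).to_csv(path, sep="\t", index=False)


def multimapped_reads(assignments) -> list[Assignment]:
    """Reads whose best qualifying score is attained by >= 2 species."""
    return [a for a in assignments if a.is_ambiguous]
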