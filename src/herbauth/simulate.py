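"""Synthetic references, flanked amplicons and error-bearing reads.

Everything the other modules need is generated here with known ground truth,
so the whole pipeline is testable without downloading anything. Amplicon
reads have the layout

    forward primer + 5.8S tail + ITS2 + 28S head + rc(reverse primer)

with an Ion-Torrent-like error model: per-base substitutions, +/-1
homopolymer-length indels on runs >= 3 nt, and a fraction of reads truncated
below the length filter. Quality strings are flat: Q30 for ordinary reads,
Q15 for reads marked low-quality, which makes the Q20 mean-quality filter's
behaviour exactly predictable in tests. All generators are deterministic
under a fixed seed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._dp import revcomp
from .io_qc import QCParams, SequenceRead, filter_reads, mask_primers
from .its2_hmm import annotate_its2, build_flank_hmms
from .qpcr import PrimerPair
from .refdb import ReferenceDB, ReferenceRecord, curate

# Universal ITS2 amplification primers (pharmacopoeia-style assay fixture).
FWD_PRIMER = "ATGCGATACTTGGTGTGAAT"
REV_PRIMER = "GACGCTTCTCCAGACTACAAT"

# Conserved rRNA flank fixtures; the packaged seed alignments in
# herbauth/data are substitution variants of these motifs.
FLANK_5P8S = "TGTCTTGGCGTCTTGTTCGGAATCGCTACATACTGGCGAGTAGTACCTACCAAGTCTGTT"
FLANK_28S = "ACGATGGCTTGAATCCACAGCTTATCGAATTCGGTCGTCACCTTAAATTGTCGTACTACC"

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    species: tuple[str, ...]
    proportions: tuple[float, ...]
    n_reads: int = 1000
    read_length_mode: int = 488
    substitution_rate: float = 0.005
    homopolymer_indel_rate: float = 0.01
    truncation_fraction: float = 0.05
    low_quality_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.species) != len(self.proportions):
            raise ValueError("species and proportions must have equal length")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        for rate in (
            self.substitution_rate,
            self.homopolymer_indel_rate,
            self.truncation_fraction,
            self.low_quality_fraction,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    per_read: dict[str, str]  # read id -> true species
    counts: dict[str, int]  # realized per-species read counts

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != len(self.per_read):
            raise ValueError("ground-truth counts must sum to n_reads")


@dataclass(frozen=True)
class ReferenceSet:
    """Synthetic reference panel: flanked records plus amplicon templates."""

    species: tuple[str, ...]
    taxonomy: tuple[tuple[str, str, str], ...]  # (id, species, genus)
    its2: dict[str, str]  # species -> ITS2 proper
    flanked: dict[str, str]  # species -> 5.8S tail + ITS2 + 28S head
    templates: dict[str, str]  # species -> full amplicon template

    def records(self, trimmed: bool = False) -> list[ReferenceRecord]:
        seqs = self.its2 if trimmed else self.flanked
        return [
            ReferenceRecord(id=rid, species=sp, genus=genus, sequence=seqs[sp], source="sim")
            for rid, sp, genus in self.taxonomy
        ]

    def write(self, fasta_path: str | Path, taxonomy_path: str | Path) -> None:
        with open(fasta_path, "w") as fa:
            for rid, sp, _ in self.taxonomy:
                fa.write(f">{rid}\n{self.flanked[sp]}\n")
        with open(taxonomy_path, "w") as tsv:
            tsv.write("id\tspecies\tgenus\n")
            for rid, sp, genus in self.taxonomy:
                tsv.write(f"{rid}\t{sp}\t{genus}\n")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate(seq: str, positions, rng: np.random.Generator) -> str:
    out = list(seq)
    for p in positions:
        out[p] = str(rng.choice([b for b in "ACGT" if b != out[p]]))
    return "".join(out)


def make_reference_set(
    n_species: int,
    its2_length: int = 327,
    divergence: float = 5.0,
    shared_flanks: bool = False,
    seed: int = 0,
) -> ReferenceSet:
    """n_species ITS2 sequences with pairwise divergence >= ``divergence`` %.

    Species descend from a common ancestor; each one is mutated at a disjoint
    block of positions large enough that any pair differs at >= divergence%
    of sites. When ``shared_flanks`` is true every record carries identical
    5.8S-tail/28S-head motifs (the conserved-flank interference scenario);
    otherwise each species' flanks get two private substitutions.
    """
    if n_species < 1:
        raise ValueError("need at least one species")
    rng = np.random.default_rng(seed)
    ancestor = _random_seq(rng, its2_length)
    per_species_muts = int(np.ceil(divergence / 100.0 * its2_length / 2.0)) + 1
    if n_species > 1 and n_species * per_species_muts > its2_length:
        raise ValueError("its2_length too short for requested divergence and n_species")
    shuffled = rng.permutation(its2_length)

    species_names = tuple(f"Herba{i} simulata" for i in range(n_species))
    taxonomy = tuple(
        (f"ref{i:03d}", species_names[i], f"Herba{i}") for i in range(n_species)
    )
    its2: dict[str, str] = {}
    flanked: dict[str, str] = {}
    templates: dict[str, str] = {}
    for i, sp in enumerate(species_names):
        if n_species == 1:
            core = ancestor
        else:
            block = shuffled[i * per_species_muts : (i + 1) * per_species_muts]
            core = _mutate(ancestor, block, rng)
        if shared_flanks:
            left, right = FLANK_5P8S, FLANK_28S
        else:
            left = _mutate(FLANK_5P8S, rng.choice(len(FLANK_5P8S), 2, replace=False), rng)
            right = _mutate(FLANK_28S, rng.choice(len(FLANK_28S), 2, replace=False), rng)
        its2[sp] = core
        flanked[sp] = left + core + right
        templates[sp] = FWD_PRIMER + flanked[sp] + revcomp(REV_PRIMER)
    return ReferenceSet(species_names, taxonomy, its2, flanked, templates)


def _homopolymer_runs(seq: str, min_len: int = 3) -> list[tuple[int, int]]:
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j))
        i = j
    return runs


def _apply_errors(seq: str, config: SimConfig, rng: np.random.Generator) -> str:
    chars = list(seq)
    if config.substitution_rate > 0:
        hit = np.nonzero(rng.random(len(chars)) < config.substitution_rate)[0]
        for p in hit:
            chars[p] = str(rng.choice([b for b in "ACGT" if b != chars[p]]))
    seq = "".join(chars)
    if config.homopolymer_indel_rate > 0:
        edits = []
        for start, end in _homopolymer_runs(seq):
            if rng.random() < config.homopolymer_indel_rate:
                edits.append((start, +1 if rng.random() < 0.5 else -1))
        for start, delta in sorted(edits, reverse=True):
            if delta > 0:
                seq = seq[: start + 1] + seq[start] + seq[start + 1 :]
            else:
                seq = seq[:start] + seq[start + 1 :]
    return seq


def sample_reads(
    config: SimConfig, templates: dict[str, str]
) -> tuple[list[SequenceRead], GroundTruth]:
    """Draw error-bearing amplicon reads from species templates.

    Species are drawn per read from ``config.proportions``; each read is a
    template copy with substitutions, homopolymer-length indels, and (for a
    ``truncation_fraction`` of reads) truncation to 50-299 bp. Ground truth
    records every read's true species.
    """
    if not templates:
        raise ValueError("empty template set")
    missing = [sp for sp in config.species if sp not in templates]
    if missing:
        raise ValueError(f"no template for species: {missing}")
    rng = np.random.default_rng(config.seed)
    species = list(config.species)
    props = np.asarray(config.proportions, dtype=float)
    draws = rng.choice(len(species), size=config.n_reads, p=props)

    reads: list[SequenceRead] = []
    per_read: dict[str, str] = {}
    counts: Counter[str] = Counter()
    for i, si in enumerate(draws):
        sp = species[si]
        seq = _apply_errors(templates[sp], config, rng)
        if config.truncation_fraction > 0 and rng.random() < config.truncation_fraction:
            cut = int(rng.integers(50, 300))
            if cut < len(seq):
                seq = seq[:cut]
        q = 15 if rng.random() < config.low_quality_fraction else 30
        rid = f"read{i:06d}"
        reads.append(SequenceRead(id=rid, bases=seq, quals=(q,) * len(seq)))
        per_read[rid] = sp
        counts[sp] += 1
    return reads, GroundTruth(per_read=per_read, counts=dict(counts))


def make_congener_templates(seed: int = 0):
    """Two near-identical templates plus the two primer pairs that tell them apart.

    The templates share an 800 nt backbone and differ only at the embedded
    primer binding sites; the two assays' forward primers share their 5'
    motif and diverge toward the 3' end, so the mismatch + 3'-window rule
    yields a diagonal specificity matrix. Returns
    (templates: dict name -> sequence, pairs: list[PrimerPair]).
    """
    pair_a = PrimerPair("assay_A", "TGGCCCACCATGCACGTCGA", "TGAGCATTGTCCACCACT")
    pair_b = PrimerPair("assay_B", "TGGCCCACCGTGCACTCACG", "ATGAGCGTCCTCCACC")
    rng = np.random.default_rng(seed)
    backbone = _random_seq(rng, 800)
    fwd_at, rev_at = 100, 460

    def embed(template: str, pos: int, insert: str) -> str:
        return template[:pos] + insert + template[pos + len(insert) :]

    t_a = embed(embed(backbone, fwd_at, pair_a.forward), rev_at, revcomp(pair_a.reverse))
    t_b = embed(embed(backbone, fwd_at, pair_b.forward), rev_at, revcomp(pair_b.reverse))
    return {"template_A": t_a, "template_B": t_b}, [pair_a, pair_b]


def preprocess_reads(
    reads,
    hmm_5p8s,
    hmm_28s,
    primers: PrimerPair | None = None,
    qc_params: QCParams | None = None,
    trim_reads: bool = True,
):
    """QC-filter, primer-mask and (optionally) HMM-trim reads for classification."""
    primers = primers or PrimerPair("ITS2", FWD_PRIMER, REV_PRIMER)
    qc_params = qc_params or QCParams()
    kept, rejected = filter_reads(reads, qc_params)
    out = []
    for read in kept:
        masked = mask_primers(read, primers, qc_params.primer_max_mismatch)
        if trim_reads and len(masked) > 0:
            # flanks sit at the read ends after primer masking; 160 nt windows
            # comfortably cover the 60 nt motifs plus indel slack
            ann = annotate_its2(
                masked.bases, hmm_5p8s, hmm_28s, source_id=masked.id, window=160
            )
            masked = SequenceRead(
                id=masked.id,
                bases=masked.bases[ann.its2_start : ann.its2_end],
                quals=masked.quals[ann.its2_start : ann.its2_end],
                unprimed=masked.unprimed,
            )
        if len(masked) > 0:
            out.append(masked)
    return out, rejected


def false_positive_experiment(seed: int = 0, n_reads: int = 200, divergence: float = 3.0) -> dict:
    """Conserved-flank interference, reproduced in silico.

    Reads come exclusively from species A. The raw database holds A as a
    clean ITS2-only record but B as an uncurated record that retains the
    shared 5.8S/28S flanks: untrimmed, B's record matches the full flanked
    read better than A's (A fails the query-coverage floor), so every read is
    spuriously assigned to B. Curating the database (and trimming reads)
    flips the spurious count to zero. Reads are error-free so the flip is
    deterministic.
    """
    from .classify import ClassifyParams, classify_reads, tabulate

    rs = make_reference_set(
        n_species=2, divergence=divergence, shared_flanks=True, seed=seed
    )
    species_a, species_b = rs.species
    config = SimConfig(
        species=(species_a,),
        proportions=(1.0,),
        n_reads=n_reads,
        substitution_rate=0.0,
        homopolymer_indel_rate=0.0,
        truncation_fraction=0.0,
        seed=seed,
    )
    reads, _ = sample_reads(config, rs.templates)
    hmm_l, hmm_r = build_flank_hmms(seed=seed)
    params = ClassifyParams()

    # raw route: A curated (ITS2 only), B with residual flanks; reads untrimmed
    raw_records = [
        ReferenceRecord("refA", species_a, "Herba0", rs.its2[species_a], "curated"),
        ReferenceRecord("refB", species_b, "Herba1", rs.flanked[species_b], "raw"),
    ]
    raw_db = ReferenceDB(records=raw_records)
    masked, _ = preprocess_reads(reads, hmm_l, hmm_r, trim_reads=False)
    untrimmed_table = tabulate(classify_reads(masked, raw_db, params))

    # curated route: trim both the database and the reads
    curated_db, _ = curate(raw_records, hmm_l, hmm_r)
    trimmed, _ = preprocess_reads(reads, hmm_l, hmm_r, trim_reads=True)
    trimmed_table = tabulate(classify_reads(trimmed, curated_db, params))

    return {
        "source_species": species_a,
        "decoy_species": species_b,
        "n_reads": n_reads,
        "untrimmed_counts": untrimmed_table.species_counts(),
        "trimmed_counts": trimmed_table.species_counts(),
        "spurious_untrimmed": untrimmed_table.species_counts().get(species_b, 0),
        "spurious_trimmed": trimmed_table.species_counts().get(species_b, 0),
    }


def mixture_recovery_experiment(
    seed: int,
    n_reads: int = 10_000,
    proportions: tuple[float, ...] = (0.5, 0.3, 0.2),
    divergence: float = 5.0,
    detection_min: int = 2,
) -> dict:
    """Simulate a known mixture and measure how well classification recovers it.

    Reads are drawn at the stated proportions with the default error model,
    QC-filtered, primer-masked, HMM-trimmed and classified against a curated
    database of the same species. Truncated reads are removed by the length
    filter independently of species, so surviving reads remain multinomial at
    the stated proportions: each species' classified count is compared to
    p * n_kept with the binomial standard error sqrt(n_kept * p * (1 - p)).
    """
    from .classify import classify_reads, tabulate

    rs = make_reference_set(len(proportions), divergence=divergence, seed=seed)
    hmm_l, hmm_r = build_flank_hmms(seed=seed)
    db, _ = curate(rs.records(), hmm_l, hmm_r)
    config = SimConfig(
        species=rs.species, proportions=tuple(proportions), n_reads=n_reads, seed=seed + 1
    )
    reads, truth = sample_reads(config, rs.templates)
    kept, _ = preprocess_reads(reads, hmm_l, hmm_r)
    table = tabulate(classify_reads(kept, db, band=48))
    counts = table.species_counts()
    n_kept = len(kept)
    per_species = []
    for sp, p in zip(rs.species, proportions):
        expected = p * n_kept
        se = float(np.sqrt(n_kept * p * (1 - p)))
        got = counts.get(sp, 0)
        per_species.append(
            {
                "species": sp,
                "proportion": p,
                "count": got,
                "expected": expected,
                "se": se,
                "z": (got - expected) / se if se else 0.0,
                "within_3se": abs(got - expected) <= 3 * se,
            }
        )
    extra = [
        sp for sp, c in counts.items() if sp not in rs.species and c >= detection_min
    ]
    return {
        "n_reads": n_reads,
        "n_kept": n_kept,
        "truth_counts": truth.counts,
        "per_species": per_species,
        "all_within_3se": all(row["within_3se"] for row in per_species),
        "extra_species_detected": extra,
        "ambiguous": table.ambiguous,
        "unassigned": table.unassigned,
    }
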