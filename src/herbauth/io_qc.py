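"""FASTQ I/O, read-level filters, primer masking and run-level QC gates.

Read-level filtering keeps a read iff its mean phred quality is >= the Q20
floor and its length lies in [300, 500] bp (defaults). Quality is checked
before length so that rejection accounting is deterministic. Run-level QC
requires at least 10,000 reads per sample and coverage of the targeted
reference positions of 99% at depth 1, 97% at depth 20 and 95% at depth 100.
"""

from __future__ import annotations

from collections.abc import Callable, Iterable, Sequence
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from ._dp import revcomp

PHRED_OFFSET = 33
MAX_PHRED = 93

_VALID_BASES = set("ACGTN")


class FastqFormatError(ValueError):
    """Raised on malformed FASTQ records; message names the offending line."""


@dataclass(frozen=True)
class SequenceRead:
    """One single-end amplicon read: bases plus per-base phred qualities."""

    id: str
    bases: str
    quals: tuple[int, ...]
    unprimed: bool = False

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.bases):
            raise ValueError(
                f"read {self.id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality values"
            )
        if any(q < 0 or q > MAX_PHRED for q in self.quals):
            raise ValueError(f"read {self.id!r}: phred values outside [0, {MAX_PHRED}]")
        bad = set(self.bases) - _VALID_BASES
        if bad:
            raise ValueError(f"read {self.id!r}: non-IUPAC characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def mean_quality(self) -> float:
        return float(np.mean(self.quals)) if self.quals else 0.0


@dataclass(frozen=True)
class QCParams:
    """Read-level filter thresholds."""

    min_quality: float = 20.0
    min_length: int = 300
    max_length: int = 500
    primer_max_mismatch: int = 2
    #: "window" checks every sliding window of `quality_window` bases instead
    #: of the whole-read mean.
    quality_mode: str = "mean"
    quality_window: int = 30

    def __post_init__(self) -> None:
        if not (0 < self.min_length <= self.max_length):
            raise ValueError("need 0 < min_length <= max_length")
        if self.min_quality < 0:
            raise ValueError("min_quality must be >= 0")
        if self.quality_mode not in ("mean", "window"):
            raise ValueError("quality_mode must be 'mean' or 'window'")


@dataclass(frozen=True)
class RunQCThresholds:
    min_reads: int = 10_000
    coverage_rules: tuple[tuple[float, int], ...] = ((0.99, 1), (0.97, 20), (0.95, 100))

    def __post_init__(self) -> None:
        depths = [d for _, d in self.coverage_rules]
        if any(not 0 <= f <= 1 for f, _ in self.coverage_rules):
            raise ValueError("coverage fractions must be in [0, 1]")
        if any(d <= 0 for d in depths) or depths != sorted(depths):
            raise ValueError("coverage depths must be positive and increasing")


@dataclass(frozen=True)
class CoverageRuleResult:
    min_fraction: float
    depth: int
    observed_fraction: float
    passed: bool


@dataclass(frozen=True)
class RunQCReport:
    n_reads: int
    pass_min_reads: bool
    coverage: tuple[CoverageRuleResult, ...]
    overall_pass: bool

    def __post_init__(self) -> None:
        expected = self.pass_min_reads and all(c.passed for c in self.coverage)
        if self.overall_pass != expected:
            raise ValueError("overall_pass inconsistent with individual flags")

    def to_dict(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "pass_min_reads": self.pass_min_reads,
            "coverage": [
                {
                    "min_fraction": c.min_fraction,
                    "depth": c.depth,
                    "observed_fraction": c.observed_fraction,
                    "passed": c.passed,
                }
                for c in self.coverage
            ],
            "overall_pass": self.overall_pass,
        }


def read_fastq(path: str | Path) -> list[SequenceRead]:
    """Parse a phred+33 FASTQ file.

    Raises FastqFormatError (naming the line number) on truncated records,
    missing ``@``/``+`` separators, seq/qual length mismatches, quality
    characters outside the printable phred+33 range, or a file that looks
    like phred+64.
    """
    reads: list[SequenceRead] = []
    min_q = MAX_PHRED
    max_q = 0
    with open(path) as handle:
        lineno = 0
        while True:
            header = handle.readline()
            if not header:
                break
            lineno += 1
            header = header.rstrip("\n")
            if not header.strip():
                continue
            if not header.startswith("@"):
                raise FastqFormatError(f"line {lineno}: expected '@' header, got {header[:20]!r}")
            seq = handle.readline().rstrip("\n")
            plus = handle.readline().rstrip("\n")
            qual = handle.readline().rstrip("\n")
            if not qual and not plus:
                raise FastqFormatError(f"line {lineno}: truncated record")
            lineno += 3
            if not plus.startswith("+"):
                raise FastqFormatError(f"line {lineno - 1}: expected '+' separator")
            if len(seq) != len(qual):
                raise FastqFormatError(
                    f"line {lineno}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            quals = []
            for ch in qual:
                q = ord(ch) - PHRED_OFFSET
                if q < 0 or q > MAX_PHRED:
                    raise FastqFormatError(
                        f"line {lineno}: quality character {ch!r} outside phred+33 range"
                    )
                quals.append(q)
            if quals:
                min_q = min(min_q, min(quals))
                max_q = max(max_q, max(quals))
            reads.append(
                SequenceRead(
                    id=header[1:].split()[0] if header[1:].split() else header[1:],
                    bases=seq.upper().replace("U", "T"),
                    quals=tuple(quals),
                )
            )
    # phred+64 files decode to implausibly high uniform scores under +33
    if reads and min_q >= 31 and max_q >= 66:
        raise FastqFormatError(
            "quality scores look like phred+64 encoding; only phred+33 is supported"
        )
    return reads


def write_fastq(reads: Iterable[SequenceRead], path: str | Path) -> None:
    with open(path, "w") as handle:
        for read in reads:
            qual = "".join(chr(q + PHRED_OFFSET) for q in read.quals)
            handle.write(f"@{read.id}\n{read.bases}\n+\n{qual}\n")


def _passes_quality(read: SequenceRead, params: QCParams) -> bool:
    if params.quality_mode == "mean":
        return read.mean_quality >= params.min_quality
    w = min(params.quality_window, len(read))
    if w == 0:
        return False
    q = np.asarray(read.quals, dtype=float)
    sums = np.convolve(q, np.ones(w), mode="valid")
    return bool(np.all(sums / w >= params.min_quality))


def filter_reads(
    reads: Sequence[SequenceRead], params: QCParams | None = None
) -> tuple[list[SequenceRead], dict[str, int]]:
    """Apply the quality filter then the length filter.

    Returns the kept reads (order preserved) and rejection counts keyed by
    the first failing rule ("quality" or "length"); kept + rejected
    partitions the input.
    """
    params = params or QCParams()
    kept: list[SequenceRead] = []
    rejected = {"quality": 0, "length": 0}
    for read in reads:
        if not _passes_quality(read, params):
            rejected["quality"] += 1
        elif not (params.min_length <= len(read) <= params.max_length):
            rejected["length"] += 1
        else:
            kept.append(read)
    return kept, rejected


def _hamming_scan(segment: str, primer: str) -> tuple[int, int]:
    """Best (position, mismatches) for primer in segment by sliding Hamming scan."""
    best_pos, best_mm = -1, len(primer) + 1
    for pos in range(len(segment) - len(primer) + 1):
        mm = sum(1 for a, b in zip(segment[pos : pos + len(primer)], primer) if a != b)
        if mm < best_mm:
            best_pos, best_mm = pos, mm
    return best_pos, best_mm


def mask_primers(read: SequenceRead, primers, max_mismatch: int = 2) -> SequenceRead:
    """Trim PCR primer sequences (and anything outside them) off a read.

    The forward primer is searched in the first ``len(primer) + 3`` bases and
    the reverse-complemented reverse primer in the last ``len(primer) + 3``
    bases, each at Hamming distance <= max_mismatch. If neither is found the
    read is returned unchanged with ``unprimed=True``.
    """
    fwd = primers.forward.upper()
    rev_rc = revcomp(primers.reverse.upper())
    seq = read.bases
    n = len(seq)

    start = 0
    end = n
    found = False
    head = seq[: min(n, len(fwd) + 3)]
    pos, mm = _hamming_scan(head, fwd)
    if pos >= 0 and mm <= max_mismatch:
        start = pos + len(fwd)
        found = True
    tail_window = min(n, len(rev_rc) + 3)
    tail = seq[n - tail_window :]
    pos, mm = _hamming_scan(tail, rev_rc)
    if pos >= 0 and mm <= max_mismatch:
        end = n - tail_window + pos
        found = True
    if not found:
        return replace(read, unprimed=True)
    if end < start:
        start, end = 0, 0
    return SequenceRead(
        id=read.id,
        bases=seq[start:end],
        quals=read.quals[start:end],
        unprimed=False,
    )


def run_qc(
    reads: Sequence[SequenceRead],
    references,
    thresholds: RunQCThresholds | None = None,
    locate: Callable[[SequenceRead], tuple[str, int, int] | None] | None = None,
) -> RunQCReport:
    """Run-level QC: read count gate plus pooled reference coverage rules.

    ``references`` is a mapping of reference id -> sequence (or any object
    with ``.records`` exposing ``id``/``sequence``). ``locate`` maps a read to
    the (reference id, start, end) span it covers, or None; the classify
    module provides :func:`herbauth.classify.make_alignment_locator`.
    """
    thresholds = thresholds or RunQCThresholds()
    if hasattr(references, "records"):
        ref_seqs = {rec.id: rec.sequence for rec in references.records}
    elif isinstance(references, dict):
        ref_seqs = dict(references)
    else:
        ref_seqs = {rec.id: rec.sequence for rec in references}
    if not ref_seqs:
        raise ValueError("run_qc requires a non-empty reference set")

    depth = {rid: np.zeros(len(seq), dtype=np.int64) for rid, seq in ref_seqs.items()}
    if locate is not None:
        for read in reads:
            hit = locate(read)
            if hit is None:
                continue
            rid, start, end = hit
            if rid in depth:
                depth[rid][max(0, start) : min(len(depth[rid]), end)] += 1
    pooled = np.concatenate(list(depth.values()))

    n_reads = len(reads)
    pass_min = n_reads >= thresholds.min_reads
    results = []
    for min_frac, d in thresholds.coverage_rules:
        frac = float(np.mean(pooled >= d)) if pooled.size else 0.0
        results.append(CoverageRuleResult(min_frac, d, frac, frac >= min_frac))
    overall = pass_min and all(r.passed for r in results)
    return RunQCReport(n_reads, pass_min, tuple(results), overall)


def filter_stats_tsv(rejected: dict[str, int], kept: int, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("rule\tcount\n")
        handle.write(f"kept\t{kept}\n")
        for rule, count in rejected.items():
            handle.write(f"{rule}\t{count}\n")
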