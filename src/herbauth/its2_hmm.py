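"""Profile HMMs for the conserved 5.8S-3' and 28S-5' rRNA flanks of ITS2.

Residual 5.8S/28S fragments in reference sequences cause cross-species false
positives, because those genes are nearly invariant across plants. The fix is
to model each flank with a small Plan7-like profile HMM (match/insert/delete
states, no internal entry/exit), locate the flanks by glocal Viterbi (full
model, local on the sequence), and trim everything outside the span between
them. The score threshold separating hits from noise is calibrated as the
95th percentile of best scores over dinucleotide-shuffled null sequences.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from ._dp import encode_seq, profile_viterbi, revcomp

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

# transition column layout used by the DP kernel
_T_COLS = ("MM", "MI", "MD", "IM", "II", "DM", "DD")


@dataclass
class ProfileHMM:
    name: str
    match_emissions: np.ndarray  # (L+1, 4), row 0 unused
    insert_emission: np.ndarray  # (4,)
    transitions: np.ndarray  # (L+1, 7) probabilities, columns _T_COLS
    background: np.ndarray  # (4,)
    score_threshold: float = 0.0

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emission = np.asarray(self.insert_emission, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.L < 1:
            raise ValueError("model needs at least one match state")
        rows = self.match_emissions[1:]
        if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("match emission rows must sum to 1")
        if not np.isclose(self.insert_emission.sum(), 1.0, atol=1e-9):
            raise ValueError("insert emission must sum to 1")
        self._validate_transitions()
        self._log_cache: tuple | None = None

    @property
    def L(self) -> int:
        return self.match_emissions.shape[0] - 1

    def _validate_transitions(self) -> None:
        t = self.transitions
        if not np.isclose(t[0, 0] + t[0, 2], 1.0, atol=1e-9):  # B -> {M1, D1}
            raise ValueError("begin-state transitions must sum to 1")
        for j in range(1, self.L):
            if not np.isclose(t[j, 0] + t[j, 1] + t[j, 2], 1.0, atol=1e-9):
                raise ValueError(f"M{j} transitions must sum to 1")
            if not np.isclose(t[j, 3] + t[j, 4], 1.0, atol=1e-9):
                raise ValueError(f"I{j} transitions must sum to 1")
            if not np.isclose(t[j, 5] + t[j, 6], 1.0, atol=1e-9):
                raise ValueError(f"D{j} transitions must sum to 1")

    def _log_tables(self):
        if self._log_cache is None:
            with np.errstate(divide="ignore"):
                lme = np.full_like(self.match_emissions, -np.inf)
                lme[1:] = np.log2(self.match_emissions[1:]) - np.log2(self.background)
                lie = np.log2(self.insert_emission) - np.log2(self.background)
                ltr = np.log2(self.transitions)
            # node L exits to E with probability 1
            ltr[self.L, :] = 0.0
            self._log_cache = (lme, lie, ltr)
        return self._log_cache

    def consensus(self) -> str:
        return "".join(_BASES[k] for k in np.argmax(self.match_emissions[1:], axis=1))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "match_emissions": self.match_emissions[1:].tolist(),
            "insert_emission": self.insert_emission.tolist(),
            "transitions": {
                col: self.transitions[:, k].tolist() for k, col in enumerate(_T_COLS)
            },
            "background": self.background.tolist(),
            "score_threshold": self.score_threshold,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "ProfileHMM":
        me = np.vstack([np.full((1, 4), 0.25), np.asarray(d["match_emissions"])])
        L = me.shape[0] - 1
        tr = np.zeros((L + 1, 7))
        for k, col in enumerate(_T_COLS):
            tr[:, k] = d["transitions"][col]
        return cls(
            name=d["name"],
            match_emissions=me,
            insert_emission=np.asarray(d["insert_emission"]),
            transitions=tr,
            background=np.asarray(d["background"]),
            score_threshold=d["score_threshold"],
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ProfileHMM":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class FlankHit:
    start: int
    end: int
    score: float
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValueError("need 0 <= start <= end")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class AnnotatedITS2:
    source_id: str
    its2_start: int
    its2_end: int
    status: str  # both_flanks | left_only | right_only | none
    left_hit: FlankHit | None = None
    right_hit: FlankHit | None = None


def build_profile(seed_alignment: list[str], pseudocount: float = 1.0, name: str = "profile") -> ProfileHMM:
    """Estimate a profile HMM from a gapped seed alignment.

    Columns with >= 50% residues become match states; the rest are insert
    columns. Emissions are (counts + pseudocount) / (total + 4*pseudocount);
    transitions are estimated from the observed state paths with the same
    pseudocount; the background is the overall residue frequency.
    """
    if not seed_alignment:
        raise ValueError("seed alignment is empty")
    width = len(seed_alignment[0])
    seqs = [s.upper() for s in seed_alignment]
    for s in seqs:
        if len(s) != width:
            raise ValueError("seed alignment rows must have equal length")
        bad = set(s) - set("ACGT-")
        if bad:
            raise ValueError(f"seed alignment contains invalid characters {sorted(bad)}")

    n = len(seqs)
    is_match_col = [
        sum(1 for s in seqs if s[c] != "-") >= 0.5 * n for c in range(width)
    ]
    L = sum(is_match_col)
    if L < 1:
        raise ValueError("alignment yields no match columns")

    match_counts = np.zeros((L + 1, 4))
    insert_counts = np.zeros(4)
    # transition counts per node, columns _T_COLS
    t_counts = np.zeros((L + 1, 7))
    bg_counts = np.zeros(4)

    for s in seqs:
        state, node = "M", 0  # treat begin as node-0 match state
        for c in range(width):
            ch = s[c]
            if ch != "-":
                bg_counts[_BASE_INDEX[ch]] += 1
            if is_match_col[c]:
                nxt = "M" if ch != "-" else "D"
                t_counts[node, _T_COLS.index(state + nxt)] += 1
                node += 1
                state = nxt
                if nxt == "M":
                    match_counts[node, _BASE_INDEX[ch]] += 1
            elif ch != "-":
                # insert residue attached to the current node (skip pre-model inserts)
                if node >= 1 and node < L:
                    t_counts[node, _T_COLS.index(state + "I")] += 1
                    state = "I"
                insert_counts[_BASE_INDEX[ch]] += 1
        # exit to E is implicit (node L transitions are forced to E)

    pc = pseudocount
    me = np.full((L + 1, 4), 0.25)
    me[1:] = (match_counts[1:] + pc) / (
        match_counts[1:].sum(axis=1, keepdims=True) + 4 * pc
    )
    ie = (insert_counts + pc) / (insert_counts.sum() + 4 * pc)
    bg = (bg_counts + pc) / (bg_counts.sum() + 4 * pc)

    tr = np.zeros((L + 1, 7))
    groups = {"M": ("MM", "MI", "MD"), "I": ("IM", "II"), "D": ("DM", "DD")}
    for j in range(L + 1):
        for state, cols in groups.items():
            if j == 0 and state != "M":
                continue
            idx = [_T_COLS.index(c) for c in cols]
            if j == 0:
                idx = [_T_COLS.index("MM"), _T_COLS.index("MD")]  # B -> {M1, D1}
            counts = t_counts[j, idx]
            probs = (counts + pc) / (counts.sum() + len(idx) * pc)
            tr[j, idx] = probs
    # node L: all paths exit to E; kernel ignores row L, keep it normalized
    tr[L, :] = 0.0
    tr[L, _T_COLS.index("MM")] = 1.0
    tr[L, _T_COLS.index("DM")] = 1.0
    tr[L, _T_COLS.index("IM")] = 1.0
    tr[L, _T_COLS.index("MD")] = 0.0

    return ProfileHMM(
        name=name,
        match_emissions=me,
        insert_emission=ie,
        transitions=tr,
        background=bg,
        score_threshold=0.0,
    )


def _scan_one_strand(hmm: ProfileHMM, seq: str) -> tuple[float, int, int]:
    lme, lie, ltr = hmm._log_tables()
    return profile_viterbi(encode_seq(seq), lme, lie, ltr)


def viterbi_locate(
    hmm: ProfileHMM, seq: str, both_strands: bool = True, threshold: float | None = None
) -> FlankHit | None:
    """Best glocal alignment of the full model to any substring of seq.

    Returns None when the best log-odds score falls below the model's
    calibrated ``score_threshold`` (overridable via ``threshold``). Both
    strands are scanned by default; minus-strand coordinates are mapped back
    to the input sequence. Plus strand wins ties.
    """
    if not seq:
        raise ValueError("sequence is empty")
    cutoff = hmm.score_threshold if threshold is None else threshold
    score_f, start_f, end_f = _scan_one_strand(hmm, seq.upper())
    best = FlankHit(start_f, end_f, score_f, "+")
    if both_strands:
        score_r, start_r, end_r = _scan_one_strand(hmm, revcomp(seq))
        if score_r > best.score:
            n = len(seq)
            best = FlankHit(n - end_r, n - start_r, score_r, "-")
    if best.score < cutoff:
        return None
    return best


def dinucleotide_shuffle(seq: str, rng: np.random.Generator, max_tries: int = 200) -> str:
    """Shuffle preserving dinucleotide counts (edge-shuffle with retry)."""
    if len(seq) < 3:
        return seq
    for _ in range(max_tries):
        edges: dict[str, list[str]] = {}
        for a, b in zip(seq, seq[1:]):
            edges.setdefault(a, []).append(b)
        for lst in edges.values():
            rng.shuffle(lst)
        out = [seq[0]]
        cursors = {k: 0 for k in edges}
        ok = True
        for _step in range(len(seq) - 1):
            cur = out[-1]
            lst = edges.get(cur)
            i = cursors.get(cur, 0)
            if lst is None or i >= len(lst):
                ok = False
                break
            out.append(lst[i])
            cursors[cur] = i + 1
        if ok:
            return "".join(out)
    # extremely unlikely for DNA; fall back to a plain permutation
    chars = list(seq)
    rng.shuffle(chars)
    return "".join(chars)


def calibrate_threshold(
    hmm: ProfileHMM,
    n_shuffles: int = 200,
    scan_length: int = 500,
    quantile: float = 0.95,
    seed: int = 0,
) -> float:
    """Set score_threshold from a shuffled-sequence null.

    Null sequences are dinucleotide shuffles of the model consensus embedded
    in random background of length ``scan_length``; the threshold is the
    ``quantile`` of the best Viterbi scores over this null. The threshold is
    stored on the model and returned.
    """
    rng = np.random.default_rng(seed)
    consensus = hmm.consensus()
    pad = max(0, scan_length - len(consensus))
    scores = []
    for _ in range(n_shuffles):
        background = "".join(rng.choice(list(_BASES), size=pad))
        null_seq = dinucleotide_shuffle(consensus + background, rng)
        score, _, _ = _scan_one_strand(hmm, null_seq)
        scores.append(score)
    hmm.score_threshold = float(np.quantile(scores, quantile))
    hmm._log_cache = None  # threshold changed; caches of scores stay valid but be safe
    return hmm.score_threshold


def annotate_its2(
    seq: str,
    hmm_5p8s: ProfileHMM,
    hmm_28s: ProfileHMM,
    source_id: str = "",
    window: int | None = None,
) -> AnnotatedITS2:
    """Locate ITS2 proper between the 5.8S-tail and 28S-head flank hits.

    its2_start = end of the best 5.8S hit (0 if absent); its2_end = start of
    the best 28S hit (len(seq) if absent). Crossed or overlapping hits give
    status "none" and no trim. Only plus-strand hits are used for trimming;
    reads should be oriented first (the classifier handles strand anyway).

    ``window`` restricts the scan to the first/last ``window`` bases (a
    speed-up for amplicon reads whose flanks sit at known ends); None scans
    the whole sequence.
    """
    if not seq:
        raise ValueError("sequence is empty")
    n = len(seq)
    if window is None or window >= n:
        left = viterbi_locate(hmm_5p8s, seq, both_strands=False)
        right = viterbi_locate(hmm_28s, seq, both_strands=False)
    else:
        left = viterbi_locate(hmm_5p8s, seq[:window], both_strands=False)
        right = viterbi_locate(hmm_28s, seq[n - window :], both_strands=False)
        if right is not None:
            off = n - window
            right = FlankHit(right.start + off, right.end + off, right.score, right.strand)
    n = len(seq)
    start = left.end if left else 0
    end = right.start if right else n
    if left and right:
        status = "both_flanks"
    elif left:
        status = "left_only"
    elif right:
        status = "right_only"
    else:
        status = "none"
    if start > end:
        return AnnotatedITS2(source_id, 0, n, "none", left, right)
    return AnnotatedITS2(source_id, start, end, status, left, right)


def trim_batch(
    records: list[tuple[str, str]],
    hmm_5p8s: ProfileHMM,
    hmm_28s: ProfileHMM,
    min_trimmed_length: int = 100,
) -> tuple[list[tuple[str, str]], list[dict]]:
    """Annotate and trim every (id, sequence) record.

    Returns trimmed records plus a per-record report; records whose trimmed
    span is shorter than ``min_trimmed_length`` are dropped and reported with
    kept=False.
    """
    trimmed: list[tuple[str, str]] = []
    report: list[dict] = []
    for rid, seq in records:
        ann = annotate_its2(seq, hmm_5p8s, hmm_28s, source_id=rid)
        span = seq[ann.its2_start : ann.its2_end]
        kept = len(span) >= min_trimmed_length
        report.append(
            {
                "id": rid,
                "status": ann.status,
                "its2_start": ann.its2_start,
                "its2_end": ann.its2_end,
                "left_score": ann.left_hit.score if ann.left_hit else float("nan"),
                "right_score": ann.right_hit.score if ann.right_hit else float("nan"),
                "kept": kept,
            }
        )
        if kept:
            trimmed.append((rid, span))
    return trimmed, report


def read_seed_alignment(path: str | Path) -> list[str]:
    """Read an aligned FASTA into a list of gapped strings."""
    seqs: list[str] = []
    current: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if current:
                seqs.append("".join(current))
                current = []
        elif line.strip():
            current.append(line.strip())
    if current:
        seqs.append("".join(current))
    return seqs


def load_packaged_seeds() -> tuple[list[str], list[str]]:
    """Packaged seed alignments for the two flank models (synthetic motifs)."""
    data = resources.files("herbauth") / "data"
    left = read_seed_alignment(str(data / "seed_5p8S.afa"))
    right = read_seed_alignment(str(data / "seed_28S.afa"))
    return left, right


def build_flank_hmms(
    seed_5p8s: list[str] | None = None,
    seed_28s: list[str] | None = None,
    pseudocount: float = 1.0,
    calibrate: bool = True,
    seed: int = 0,
) -> tuple[ProfileHMM, ProfileHMM]:
    """Build (and by default calibrate) the 5.8S-tail and 28S-head models."""
    if seed_5p8s is None or seed_28s is None:
        packaged_left, packaged_right = load_packaged_seeds()
        seed_5p8s = seed_5p8s or packaged_left
        seed_28s = seed_28s or packaged_right
    hmm_l = build_profile(seed_5p8s, pseudocount, name="5.8S_tail")
    hmm_r = build_profile(seed_28s, pseudocount, name="28S_head")
    if calibrate:
        calibrate_threshold(hmm_l, seed=seed)
        calibrate_threshold(hmm_r, seed=seed + 1)
    return hmm_l, hmm_r
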