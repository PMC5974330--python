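"""Dynamic-programming kernels shared by the aligner and the profile-HMM scanner.

Numba-jitted when numba is importable; otherwise the same functions run as
pure Python (slow but correct), so the package has no hard numba dependency.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def encode_seq(seq: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3; every other character (incl. N) as 4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT.get(c, "N") for c in reversed(seq.upper()))


NEG = -1e18

# Scoring constants for the read-vs-reference aligner: match +1, mismatch -1,
# gap of length k costs 2 + (k - 1) (open -2 on the first gap column, -1 per
# extension). N never matches, not even N vs N.
MATCH = 1.0
MISMATCH = -1.0
GAP_OPEN = -2.0
GAP_EXTEND = -1.0


@njit(cache=True)
def overlap_align(q, r):  # pragma: no cover - covered via align_read tests
    """Overlap (free-end-gap) affine alignment of query q against reference r.

    Both sequences' terminal gaps are free: the optimal path starts on the
    top/left boundary and ends on the bottom/right boundary of the DP matrix.
    Endpoints are restricted to match/mismatch (M) cells; trailing gap columns
    can never beat ending earlier on a boundary, so this loses nothing.

    Tie-breaking is deterministic: M-state predecessors are preferred in the
    order M > X > Y (X = gap in reference, Y = gap in query), gap opens beat
    extends, and among equal-scoring endpoints the leftmost cell of the last
    row wins, then the topmost cell of the last column.

    Returns (score, matches, aligned_cols, query_bases_in_alignment,
             q_start, r_start, q_end, r_end).
    """
    n = q.shape[0]
    m = r.shape[0]
    M = np.empty((n + 1, m + 1))
    X = np.empty((n + 1, m + 1))
    Y = np.empty((n + 1, m + 1))
    tbM = np.empty((n + 1, m + 1), dtype=np.int8)
    tbX = np.empty((n + 1, m + 1), dtype=np.int8)
    tbY = np.empty((n + 1, m + 1), dtype=np.int8)
    for j in range(m + 1):
        M[0, j] = 0.0
        X[0, j] = NEG
        Y[0, j] = NEG
    for i in range(n + 1):
        M[i, 0] = 0.0
        X[i, 0] = NEG
        Y[i, 0] = NEG
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if (q[i - 1] == r[j - 1] and q[i - 1] < 4) else MISMATCH
            best = M[i - 1, j - 1]
            t = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                t = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                t = 2
            M[i, j] = best + s
            tbM[i, j] = t
            a = M[i - 1, j] + GAP_OPEN
            b = X[i - 1, j] + GAP_EXTEND
            if a >= b:
                X[i, j] = a
                tbX[i, j] = 0
            else:
                X[i, j] = b
                tbX[i, j] = 1
            a = M[i, j - 1] + GAP_OPEN
            b = Y[i, j - 1] + GAP_EXTEND
            if a >= b:
                Y[i, j] = a
                tbY[i, j] = 0
            else:
                Y[i, j] = b
                tbY[i, j] = 1

    best = NEG
    bi = n
    bj = 0
    for j in range(m + 1):
        if M[n, j] > best:
            best = M[n, j]
            bi = n
            bj = j
    for i in range(n + 1):
        if M[i, m] > best:
            best = M[i, m]
            bi = i
            bj = m

    i = bi
    j = bj
    state = 0
    matches = 0
    cols = 0
    qbases = 0
    while i > 0 and j > 0:
        if state == 0:
            cols += 1
            qbases += 1
            if q[i - 1] == r[j - 1] and q[i - 1] < 4:
                matches += 1
            state = tbM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            cols += 1
            qbases += 1
            state = 0 if tbX[i, j] == 0 else 1
            i -= 1
        else:
            cols += 1
            state = 0 if tbY[i, j] == 0 else 2
            j -= 1
    return best, matches, cols, qbases, i, j, bi, bj


@njit(cache=True)
def overlap_align_banded(q, r, w):  # pragma: no cover - compared against overlap_align
    """Banded variant of :func:`overlap_align` restricted to |j - i| <= w.

    Exact for alignments whose path stays within the band (near-identical
    sequences of similar length, as in read-vs-reference classification);
    scores of paths leaving the band are underestimated, so use only where
    that cannot change the outcome. Uses rolling score rows plus one packed
    traceback matrix, so per-call memory is ~(n*m) bytes instead of 6x8 of it.
    """
    n = q.shape[0]
    m = r.shape[0]
    Mp = np.empty(m + 1)
    Xp = np.empty(m + 1)
    Yp = np.empty(m + 1)
    Mc = np.empty(m + 1)
    Xc = np.empty(m + 1)
    Yc = np.empty(m + 1)
    # tb packs the three per-state predecessors: tbM | tbX << 2 | tbY << 4
    tb = np.empty((n + 1, m + 1), dtype=np.int8)
    colM = np.full(n + 1, NEG)  # M[i, m] per row, for last-column endpoints

    top = min(m, w + 1)
    for j in range(top + 1):
        Mp[j] = 0.0
        Xp[j] = NEG
        Yp[j] = NEG
    colM[0] = Mp[m] if m <= top else NEG

    for i in range(1, n + 1):
        jlo = max(1, i - w)
        jhi = min(m, i + w)
        if jlo > jhi:  # band has left the matrix; nothing more to compute
            break
        if jlo == 1:
            Mc[0] = 0.0  # free start down the left boundary
            Xc[0] = NEG
            Yc[0] = NEG
        else:
            Mc[jlo - 1] = NEG
            Xc[jlo - 1] = NEG
            Yc[jlo - 1] = NEG
        qi = q[i - 1]
        for j in range(jlo, jhi + 1):
            s = MATCH if (qi == r[j - 1] and qi < 4) else MISMATCH
            best = Mp[j - 1]
            t = 0
            if Xp[j - 1] > best:
                best = Xp[j - 1]
                t = 1
            if Yp[j - 1] > best:
                best = Yp[j - 1]
                t = 2
            Mc[j] = best + s
            code = t
            a = Mp[j] + GAP_OPEN
            b = Xp[j] + GAP_EXTEND
            if a >= b:
                Xc[j] = a
            else:
                Xc[j] = b
                code |= 4
            a = Mc[j - 1] + GAP_OPEN
            b = Yc[j - 1] + GAP_EXTEND
            if a >= b:
                Yc[j] = a
            else:
                Yc[j] = b
                code |= 16
            tb[i, j] = code
        if jhi + 1 <= m:
            Mc[jhi + 1] = NEG  # next row's diagonal/up reads beyond the band
            Xc[jhi + 1] = NEG
            Yc[jhi + 1] = NEG
        if jhi == m:
            colM[i] = Mc[m]
        # swap rolling rows
        tmp = Mp
        Mp = Mc
        Mc = tmp
        tmp = Xp
        Xp = Xc
        Xc = tmp
        tmp = Yp
        Yp = Yc
        Yc = tmp

    best = NEG
    bi = n
    bj = 0
    if n - w <= m:  # last row intersects the band
        for j in range(max(0, n - w), min(m, n + w) + 1):
            if Mp[j] > best:
                best = Mp[j]
                bi = n
                bj = j
    for i in range(0, n + 1):
        if abs(m - i) <= w and colM[i] > best:
            best = colM[i]
            bi = i
            bj = m

    i = bi
    j = bj
    state = 0
    matches = 0
    cols = 0
    qbases = 0
    while i > 0 and j > 0:
        code = tb[i, j]
        if state == 0:
            cols += 1
            qbases += 1
            if q[i - 1] == r[j - 1] and q[i - 1] < 4:
                matches += 1
            state = code & 3
            i -= 1
            j -= 1
        elif state == 1:
            cols += 1
            qbases += 1
            state = 0 if (code & 4) == 0 else 1
            i -= 1
        else:
            cols += 1
            state = 0 if (code & 16) == 0 else 2
            j -= 1
    return best, matches, cols, qbases, i, j, bi, bj


@njit(cache=True)
def profile_viterbi(x, lme, lie, ltr):  # pragma: no cover - covered via tests
    """Glocal Viterbi: full profile model, local on the sequence.

    x        encoded sequence (0..3; 4 = N, emitted with worst-case odds)
    lme      (L+1, 4) log2-odds match emissions; row 0 unused
    lie      (4,) log2-odds insert emissions
    ltr      (L+1, 7) log2 transition probs, columns
             [M->M, M->I, M->D, I->M, I->I, D->M, D->D]; row j = out of
             node j; row 0 holds B->M1 (col 0) and B->D1 (col 2); node L
             exits to E with probability 1 (score 0), no I_L state.

    The model may enter at any sequence position (free flank) and exit at any
    position after traversing all L nodes (through M or D at node L).

    Tie-break: higher score, then smaller start, then smaller end;
    on full ties predecessors are preferred in the order M > I > D.

    Returns (score, start, end) with 0-based half-open coordinates; if the
    sequence is shorter than usable, score can be -inf.
    """
    n = x.shape[0]
    L = lme.shape[0] - 1
    VM = np.empty((L + 1, n + 1))
    VI = np.empty((L + 1, n + 1))
    VD = np.empty((L + 1, n + 1))
    SM = np.zeros((L + 1, n + 1), dtype=np.int64)
    SI = np.zeros((L + 1, n + 1), dtype=np.int64)
    SD = np.zeros((L + 1, n + 1), dtype=np.int64)
    for i in range(n + 1):
        VM[0, i] = NEG
        VI[0, i] = NEG
        VD[0, i] = NEG
    for j in range(1, L + 1):
        VM[j, 0] = NEG
        VI[j, 0] = NEG

    # i = number of sequence characters consumed so far (1-based position).
    for i in range(0, n + 1):
        for j in range(1, L + 1):
            if i >= 1:
                e = lie[x[i - 1]] if x[i - 1] < 4 else lie[0] - 10.0
                em = lme[j, x[i - 1]] if x[i - 1] < 4 else -10.0
                # match state
                if j == 1:
                    best = ltr[0, 0]  # B -> M1, begin at position i-1
                    st = i - 1
                else:
                    best = VM[j - 1, i - 1] + ltr[j - 1, 0]
                    st = SM[j - 1, i - 1]
                    c = VI[j - 1, i - 1] + ltr[j - 1, 3]
                    cs = SI[j - 1, i - 1]
                    if c > best or (c == best and cs < st):
                        best = c
                        st = cs
                    c = VD[j - 1, i - 1] + ltr[j - 1, 5]
                    cs = SD[j - 1, i - 1]
                    if c > best or (c == best and cs < st):
                        best = c
                        st = cs
                VM[j, i] = best + em
                SM[j, i] = st
                # insert state (no I_L)
                if j < L:
                    a = VM[j, i - 1] + ltr[j, 1]
                    sa = SM[j, i - 1]
                    b = VI[j, i - 1] + ltr[j, 4]
                    sb = SI[j, i - 1]
                    if a > b or (a == b and sa <= sb):
                        VI[j, i] = a + e
                        SI[j, i] = sa
                    else:
                        VI[j, i] = b + e
                        SI[j, i] = sb
            # delete state (consumes no sequence)
            if j == 1:
                VD[1, i] = ltr[0, 2]  # B -> D1, begin at position i
                SD[1, i] = i
            else:
                a = VM[j - 1, i] + ltr[j - 1, 2]
                sa = SM[j - 1, i]
                b = VD[j - 1, i] + ltr[j - 1, 6]
                sb = SD[j - 1, i]
                if a > b or (a == b and sa <= sb):
                    VD[j, i] = a
                    SD[j, i] = sa
                else:
                    VD[j, i] = b
                    SD[j, i] = sb

    best = NEG
    bstart = 0
    bend = 0
    for i in range(0, n + 1):
        c = VM[L, i]
        cs = SM[L, i]
        if c > best or (c == best and (cs < bstart or (cs == bstart and i < bend))):
            best = c
            bstart = cs
            bend = i
        c = VD[L, i]
        cs = SD[L, i]
        if c > best or (c == best and (cs < bstart or (cs == bstart and i < bend))):
            best = c
            bstart = cs
            bend = i
    return best, bstart, bend


def warm_up() -> None:
    """Trigger JIT compilation once so timing-sensitive callers pay it early."""
    q = encode_seq("ACGTACGT")
    overlap_align(q, q)
    lme = np.zeros((3, 4))
    lie = np.zeros(4)
    ltr = np.full((3, 7), -1.0)
    profile_viterbi(q, lme, lie, ltr)
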