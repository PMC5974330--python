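"""Independent reference implementations used as test oracles.

These are deliberately written as plain-Python, straightforward DP code,
structurally different from the production kernels, with the same documented
scoring scheme and tie-break rules.
"""

from __future__ import annotations

NEG = float("-inf")


def oracle_overlap_align(q: str, r: str):
    """Plain-Python affine overlap aligner.

    Match +1, mismatch -1, gap open -2, gap extend -1; free terminal gaps on
    both sequences; endpoints restricted to match/mismatch cells on the last
    row/column (last row scanned first, strict improvement only). Returns
    (score, matches, aligned_cols, query_bases).
    """
    n, m = len(q), len(r)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    tbM = [[0] * (m + 1) for _ in range(n + 1)]
    tbX = [[0] * (m + 1) for _ in range(n + 1)]
    tbY = [[0] * (m + 1) for _ in range(n + 1)]
    for j in range(m + 1):
        M[0][j] = 0.0
    for i in range(n + 1):
        M[i][0] = 0.0
    for i in range(1, n + 1):
        qc = q[i - 1]
        for j in range(1, m + 1):
            s = 1.0 if (qc == r[j - 1] and qc != "N") else -1.0
            cands = [(M[i - 1][j - 1], 0), (X[i - 1][j - 1], 1), (Y[i - 1][j - 1], 2)]
            best, t = cands[0]
            for v, k in cands[1:]:
                if v > best:
                    best, t = v, k
            M[i][j] = best + s
            tbM[i][j] = t
            open_, ext = M[i - 1][j] - 2.0, X[i - 1][j] - 1.0
            X[i][j], tbX[i][j] = (open_, 0) if open_ >= ext else (ext, 1)
            open_, ext = M[i][j - 1] - 2.0, Y[i][j - 1] - 1.0
            Y[i][j], tbY[i][j] = (open_, 0) if open_ >= ext else (ext, 1)

    best, bi, bj = NEG, n, 0
    for j in range(m + 1):
        if M[n][j] > best:
            best, bi, bj = M[n][j], n, j
    for i in range(n + 1):
        if M[i][m] > best:
            best, bi, bj = M[i][m], i, m

    i, j, state = bi, bj, 0
    matches = cols = qbases = 0
    while i > 0 and j > 0:
        if state == 0:
            cols += 1
            qbases += 1
            if q[i - 1] == r[j - 1] and q[i - 1] != "N":
                matches += 1
            state = tbM[i][j]
            i, j = i - 1, j - 1
        elif state == 1:
            cols += 1
            qbases += 1
            state = 0 if tbX[i][j] == 0 else 1
            i -= 1
        else:
            cols += 1
            state = 0 if tbY[i][j] == 0 else 2
            j -= 1
    return best, matches, cols, qbases


def oracle_overlap_identity(q: str, r: str):
    score, matches, cols, qbases = oracle_overlap_align(q, r)
    identity = 100.0 * matches / cols if cols else 0.0
    coverage = 100.0 * qbases / len(q) if q else 0.0
    return score, identity, coverage


def oracle_viterbi(hmm, seq: str):
    """Exhaustive glocal profile-HMM decoder.

    For every start position s, runs an independent model-global DP on the
    suffix seq[s:] whose first consumed character is fixed to seq[s], and
    enumerates every end position. Returns (score, start, end) with the
    documented tie-break (higher score, then smaller start, then smaller
    end). O(n^2 * L) -- use on short sequences only.
    """
    lme, lie, ltr = hmm._log_tables()
    L = hmm.L
    base = {"A": 0, "C": 1, "G": 2, "T": 3}
    n = len(seq)
    best = (NEG, 0, 0)
    for s in range(n + 1):
        t = seq[s:]
        nt = len(t)
        vm = [[NEG] * (nt + 1) for _ in range(L + 1)]
        vd = [[NEG] * (nt + 1) for _ in range(L + 1)]
        vi = [[NEG] * (nt + 1) for _ in range(L + 1)]
        # begin transitions: entry only at offset 0 of the suffix
        vd[1][0] = ltr[0][2]
        for j in range(2, L + 1):
            vd[j][0] = vd[j - 1][0] + ltr[j - 1][6]
        for i in range(1, nt + 1):
            c = base.get(t[i - 1], -1)
            em_row = [lme[j][c] if c >= 0 else -10.0 for j in range(L + 1)]
            ei = lie[c] if c >= 0 else lie[0] - 10.0
            for j in range(1, L + 1):
                cands = []
                if j == 1:
                    if i == 1:
                        cands.append(ltr[0][0])  # B -> M1 consumes t[0]
                else:
                    cands.append(vm[j - 1][i - 1] + ltr[j - 1][0])
                    cands.append(vi[j - 1][i - 1] + ltr[j - 1][3])
                    cands.append(vd[j - 1][i - 1] + ltr[j - 1][5])
                vm[j][i] = (max(cands) if cands else NEG) + em_row[j]
                if j < L:
                    vi[j][i] = max(vm[j][i - 1] + ltr[j][1], vi[j][i - 1] + ltr[j][4]) + ei
                if j == 1:
                    vd[1][i] = NEG  # B entry at offset > 0 belongs to a later s
                else:
                    vd[j][i] = max(vm[j - 1][i] + ltr[j - 1][2], vd[j - 1][i] + ltr[j - 1][6])
        for i in range(0, nt + 1):
            for v in (vm[L][i], vd[L][i]):
                if v > best[0]:
                    best = (v, s, s + i)
    return best


def oracle_primer_scan(seq: str, primer: str):
    """Brute-force sliding-window Hamming scan over the whole sequence."""
    best = None
    for pos in range(len(seq) - len(primer) + 1):
        mm = sum(1 for a, b in zip(seq[pos : pos + len(primer)], primer) if a != b)
        if best is None or mm < best[1]:
            best = (pos, mm)
    return best
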