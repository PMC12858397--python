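"""Numba kernels for the alignment dynamic programs.

All scores are log2-odds ("bits") against the background residue model.
Local alignment semantics: uniform wing entry into any match column
(probability 1/L), uniform exit after any match column (1/L), and the empty
alignment is permitted and scores 0 bits.
"""
from __future__ import annotations

import math

import numpy as np
from numba import njit

NEG = -1.0e30


# ---------------------------------------------------------------------------
# profile <-> protein
# ---------------------------------------------------------------------------

@njit(cache=False)
def viterbi_kernel(esc, tsc, q, entry, exit_):
    """Max log-odds local path.  Returns (bits, end_j, end_k, ptrM, ptrI, ptrD).

    esc: (L, 22) emission log-odds; tsc: (L+1, 7) transition log2-probs with
    layout (MM, MI, MD, IM, II, DM, DD); q: query residue indices.
    ptr codes: 0 entry, 1 from M, 2 from I, 3 from D.
    """
    L = esc.shape[0]
    m = q.shape[0]
    VM = np.full((L + 1, m + 1), NEG)
    VI = np.full((L + 1, m + 1), NEG)
    VD = np.full((L + 1, m + 1), NEG)
    ptrM = np.zeros((L + 1, m + 1), dtype=np.int8)
    ptrI = np.zeros((L + 1, m + 1), dtype=np.int8)
    ptrD = np.zeros((L + 1, m + 1), dtype=np.int8)
    best = NEG   # raw best non-empty alignment; caller applies the 0 floor
    bj = 0
    bk = 0
    for j in range(1, L + 1):
        for k in range(1, m + 1):
            e = esc[j - 1, q[k - 1]]
            s = entry
            p = 0
            v = VM[j - 1, k - 1] + tsc[j - 1, 0]
            if v > s:
                s = v
                p = 1
            v = VI[j - 1, k - 1] + tsc[j - 1, 3]
            if v > s:
                s = v
                p = 2
            v = VD[j - 1, k - 1] + tsc[j - 1, 5]
            if v > s:
                s = v
                p = 3
            VM[j, k] = s + e
            ptrM[j, k] = p
            # insert after column j
            s = VM[j, k - 1] + tsc[j, 1]
            p = 1
            v = VI[j, k - 1] + tsc[j, 4]
            if v > s:
                s = v
                p = 2
            VI[j, k] = s
            ptrI[j, k] = p
            # delete of column j (interior only; unreachable without a prior M)
            s = VM[j - 1, k] + tsc[j - 1, 2]
            p = 1
            v = VD[j - 1, k] + tsc[j - 1, 6]
            if v > s:
                s = v
                p = 3
            VD[j, k] = s
            ptrD[j, k] = p
            tot = VM[j, k] + exit_
            if tot > best:
                best = tot
                bj = j
                bk = k
    return best, bj, bk, ptrM, ptrI, ptrD


@njit(cache=False)
def forward_kernel(odds, tp, q, entry_p, exit_p):
    """log2 of (1 + sum over all local paths of path odds).

    Linear probability space with rescaling; the leading 1 is the empty
    alignment.  odds: (L, 22) emission odds; tp: (L+1, 7) transition probs.
    """
    L = odds.shape[0]
    m = q.shape[0]
    FM_prev = np.zeros(L + 1)
    FI_prev = np.zeros(L + 1)
    FD_prev = np.zeros(L + 1)
    FM = np.zeros(L + 1)
    FI = np.zeros(L + 1)
    FD = np.zeros(L + 1)
    log_scale = 0.0
    end_sum_log = NEG
    for k in range(1, m + 1):
        FM[0] = 0.0
        FI[0] = 0.0
        FD[0] = 0.0
        colmax = 0.0
        for j in range(1, L + 1):
            e = odds[j - 1, q[k - 1]]
            FM[j] = e * (entry_p
                         + FM_prev[j - 1] * tp[j - 1, 0]
                         + FI_prev[j - 1] * tp[j - 1, 3]
                         + FD_prev[j - 1] * tp[j - 1, 5])
            FD[j] = FM[j - 1] * tp[j - 1, 2] + FD[j - 1] * tp[j - 1, 6]
            FI[j] = FM_prev[j] * tp[j, 1] + FI_prev[j] * tp[j, 4]
            if FM[j] > colmax:
                colmax = FM[j]
            if FI[j] > colmax:
                colmax = FI[j]
            if FD[j] > colmax:
                colmax = FD[j]
        end_k = 0.0
        for j in range(1, L + 1):
            end_k += FM[j] * exit_p
        if end_k > 0.0:
            le = math.log2(end_k) + log_scale
            if le > end_sum_log:
                end_sum_log, le = le, end_sum_log
            end_sum_log = end_sum_log + math.log2(1.0 + 2.0 ** (le - end_sum_log))
        if colmax > 1e100 or (0.0 < colmax < 1e-100):
            for j in range(L + 1):
                FM[j] /= colmax
                FI[j] /= colmax
                FD[j] /= colmax
            log_scale += math.log2(colmax)
        FM_prev, FM = FM, FM_prev
        FI_prev, FI = FI, FI_prev
        FD_prev, FD = FD, FD_prev
    if end_sum_log <= NEG / 2.0:
        return 0.0
    if end_sum_log > 0.0:
        return end_sum_log + math.log2(1.0 + 2.0 ** (-end_sum_log))
    return math.log2(1.0 + 2.0 ** end_sum_log)


# ---------------------------------------------------------------------------
# six-frame windowed seed scan
# ---------------------------------------------------------------------------

@njit(cache=False)
def seed_scan_kernel(esc, q, window):
    """Best ungapped windowed diagonal score per protein window start.

    For each window start p in the translated frame, computes the maximum over
    profile offsets j0 of sum_{t<W} esc[j0+t, q[p+t]] and returns the array of
    best scores (NEG where no full window fits).
    """
    L = esc.shape[0]
    m = q.shape[0]
    best = np.full(m, NEG)
    if m < window or L < window:
        return best
    ring = np.zeros(window)
    for c in range(-(L - window), m - window + 1):
        j_lo = 0 if c >= 0 else -c
        j_hi = L if c + L <= m else m - c
        if j_hi - j_lo < window:
            continue
        wsum = 0.0
        for j in range(j_lo, j_hi):
            v = esc[j, q[j + c]]
            t = j - j_lo
            idx = t % window
            if t >= window:
                wsum -= ring[idx]
            ring[idx] = v
            wsum += v
            if t >= window - 1:
                p = c + j - window + 1
                if wsum > best[p]:
                    best[p] = wsum
    return best


# ---------------------------------------------------------------------------
# spliced profile-to-genome alignment
# ---------------------------------------------------------------------------

# traceback codes for the match state
M_DIRECT = 1      # contiguous codon, from PM[j-1, i-3]
M_INTRON0 = 2     # phase-0 intron [d, i-3), from PM[j-1, d]
M_INTRON1 = 3     # phase-1 intron [d, i-2), from PM[j-1, d-1]
M_INTRON2 = 4     # phase-2 intron [d, i-1), from PM[j-1, d-2]
M_FS1 = 5         # frameshift, 1 nt consumed
M_FS2 = 6         # frameshift, 2 nt consumed
M_FS4 = 7         # frameshift, 4 nt consumed


@njit(cache=False)
def spliced_kernel(escM, escI, tsc, base, cod3, aa1, aa2, donor, acc_end,
                   entry, exit_, ipen, fspen, min_intron):
    """Spliced Viterbi of a profile against one genomic strand.

    escM: (L, 22) match emission log-odds with the stop penalty folded into
    column 21; escI: (22,) insert-codon emission scores; base[i]: nucleotide
    index 0..4; cod3[i]: aa index of codon s[i-3:i]; aa1[x, i]: aa of split
    codon (x, s[i-2], s[i-1]); aa2[xy, i]: aa of (x, y, s[i-1]); donor[d]:
    s[d:d+2]=="GT"; acc_end[c]: s[c-2:c]=="AG".  Introns open at donors,
    close before acceptino positions, have length >= min_intron and cost
    ``ipen``; frameshifts consume 1/2/4 nt, emit X and cost ``fspen``.  The
    maximum intron length is NOT enforced here; the caller validates the
    traceback and splits the locus on violations.

    The alignment is glocal: every profile column must be matched or deleted
    (the begin state acts as a match at column 0, entry is free at any genomic
    position, and the path ends at column L in M or D), which anchors exon
    boundaries at the profile ends even when terminal residues mismatch.

    Returns (best, best_state, bi, mcode, mdon, pmcode, icode, dcode) where
    best_state is 1 if the path ends in M at column L, 2 if in D.
    """
    L = escM.shape[0]
    n = cod3.shape[0] - 1
    R = min_intron + 8

    PMr = np.full((R, L + 1), NEG)
    Mr = np.full((R, L + 1), NEG)
    Ir = np.full((R, L + 1), NEG)

    mcode = np.zeros((L + 1, n + 1), dtype=np.int8)
    mdon = np.full((L + 1, n + 1), -1, dtype=np.int32)
    pmcode = np.zeros((L + 1, n + 1), dtype=np.int8)
    icode = np.zeros((L + 1, n + 1), dtype=np.int8)
    dcode = np.zeros((L + 1, n + 1), dtype=np.int8)

    N0 = np.full(L + 1, NEG)
    N0a = np.full(L + 1, -1, dtype=np.int32)
    N1 = np.full((L + 1, 4), NEG)
    N1a = np.full((L + 1, 4), -1, dtype=np.int32)
    N2 = np.full((L + 1, 16), NEG)
    N2a = np.full((L + 1, 16), -1, dtype=np.int32)

    Mcur = np.full(L + 1, NEG)
    Icur = np.full(L + 1, NEG)
    Dcur = np.full(L + 1, NEG)

    best = NEG
    bstate = 0
    bi = 0

    for i in range(n + 1):
        ri = i % R
        # --- donor eligibility updates (per-phase schedule) ----------------
        d0 = i - 3 - min_intron
        if d0 >= 0 and donor[d0]:
            r = d0 % R
            for j in range(L + 1):
                v = PMr[r, j]
                if v > N0[j]:
                    N0[j] = v
                    N0a[j] = d0
        d1 = i - 2 - min_intron
        if d1 >= 1 and donor[d1]:
            xb = base[d1 - 1]
            if xb < 4:
                r = (d1 - 1) % R
                for j in range(L + 1):
                    v = PMr[r, j]
                    if v > N1[j, xb]:
                        N1[j, xb] = v
                        N1a[j, xb] = d1
        d2 = i - 1 - min_intron
        if d2 >= 2 and donor[d2]:
            x = base[d2 - 2]
            y = base[d2 - 1]
            if x < 4 and y < 4:
                xy = x * 4 + y
                r = (d2 - 2) % R
                for j in range(L + 1):
                    v = PMr[r, j]
                    if v > N2[j, xy]:
                        N2[j, xy] = v
                        N2a[j, xy] = d2
        # --- cells at position i -------------------------------------------
        acc0 = i >= 5 and acc_end[i - 3]
        acc1 = i >= 4 and acc_end[i - 2]
        acc2 = i >= 3 and acc_end[i - 1]
        c3 = cod3[i] if i >= 3 else -1
        r3 = (i - 3) % R
        Mcur[0] = entry          # begin acts as a free match at column 0
        Icur[0] = NEG
        Dcur[0] = NEG
        PMr[ri, 0] = entry + tsc[0, 0]
        pmcode[0, i] = 0
        for j in range(1, L + 1):
            # ---- match state ----
            s = NEG
            code = 0
            don = -1
            if i >= 3:
                e = escM[j - 1, c3]
                v = PMr[r3, j - 1] + e
                if v > s:
                    s = v
                    code = M_DIRECT
                if acc0 and N0[j - 1] > NEG / 2.0:
                    v = N0[j - 1] + ipen + e
                    if v > s:
                        s = v
                        code = M_INTRON0
                        don = N0a[j - 1]
                if acc1:
                    for x in range(4):
                        w = N1[j - 1, x]
                        if w > NEG / 2.0:
                            v = w + ipen + escM[j - 1, aa1[x, i]]
                            if v > s:
                                s = v
                                code = M_INTRON1
                                don = N1a[j - 1, x]
                if acc2:
                    for xy in range(16):
                        w = N2[j - 1, xy]
                        if w > NEG / 2.0:
                            v = w + ipen + escM[j - 1, aa2[xy, i]]
                            if v > s:
                                s = v
                                code = M_INTRON2
                                don = N2a[j - 1, xy]
            if i >= 1:
                v = PMr[(i - 1) % R, j - 1] + fspen
                if v > s:
                    s = v
                    code = M_FS1
                    don = -1
            if i >= 2:
                v = PMr[(i - 2) % R, j - 1] + fspen
                if v > s:
                    s = v
                    code = M_FS2
                    don = -1
            if i >= 4:
                v = PMr[(i - 4) % R, j - 1] + fspen
                if v > s:
                    s = v
                    code = M_FS4
                    don = -1
            Mcur[j] = s
            mcode[j, i] = code
            mdon[j, i] = don
            # ---- insert state (codon inserted after column j) ----
            si = NEG
            ic = 0
            if i >= 3:
                v = Mr[r3, j] + tsc[j, 1]
                if v > si:
                    si = v
                    ic = 1
                v = Ir[r3, j] + tsc[j, 4]
                if v > si:
                    si = v
                    ic = 2
                si += escI[c3]
            Icur[j] = si
            icode[j, i] = ic
            # ---- delete state ----
            sd = Mcur[j - 1] + tsc[j - 1, 2]
            dc = 1
            v = Dcur[j - 1] + tsc[j - 1, 6]
            if v > sd:
                sd = v
                dc = 2
            Dcur[j] = sd
            dcode[j, i] = dc
            # ---- PM: ready to enter column j+1 ----
            pm = Mcur[j] + tsc[j, 0]
            pc = 1
            v = Icur[j] + tsc[j, 3]
            if v > pm:
                pm = v
                pc = 2
            v = Dcur[j] + tsc[j, 5]
            if v > pm:
                pm = v
                pc = 3
            PMr[ri, j] = pm
            pmcode[j, i] = pc
        # ---- end: glocal, only at column L (M or D) ----
        tot = Mcur[L] + exit_
        if tot > best:
            best = tot
            bstate = 1
            bi = i
        tot = Dcur[L] + exit_
        if tot > best:
            best = tot
            bstate = 2
            bi = i
        for j in range(L + 1):
            Mr[ri, j] = Mcur[j]
            Ir[ri, j] = Icur[j]
    return best, bstate, bi, mcode, mdon, pmcode, icode, dcode
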