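"""Spliced alignment of a ProfileHMM to genomic DNA across GT..AG introns.

The dynamic program works on codons: match/insert states consume three
nucleotides, delete states none; introns (flat splice model: mandatory GT/AG,
constant opening penalty, no positional information content) may fall between
codons (phase 0) or split a codon after one or two bases (phases 1/2);
frameshift emissions consume 1, 2 or 4 nucleotides and mark the model as a
pseudogene candidate, as does an internal stop codon read through as X.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .alphabet import CODON_AA, STOP_IDX, X_IDX, dna_to_indices
from .config import MiningConfig
from .seqio import GeneModel, revcomp
from .profiles import ProfileHMM

IDX_TO_AA = "ACDEFGHIKLMNPQRSTVWY" + "X*"


@dataclass
class SpliceSites:
    donors: list[int]       # positions i with dna[i:i+2] == "GT"
    acceptors: list[int]    # positions i with dna[i:i+2] == "AG"


def find_splice_sites(dna: str) -> SpliceSites:
    donors = [i for i in range(len(dna) - 1) if dna[i] == "G" and dna[i + 1] == "T"]
    acceptors = [i for i in range(len(dna) - 1) if dna[i] == "A" and dna[i + 1] == "G"]
    return SpliceSites(donors, acceptors)


def _locus_tables(base: np.ndarray):
    """Precompute codon and splice-site lookup tables for one strand."""
    n = base.shape[0]
    b = base.astype(np.int64)
    cod3 = np.full(n + 1, X_IDX, dtype=np.int8)
    if n >= 3:
        cod3[3:] = CODON_AA[(b[:-2] * 5 + b[1:-1]) * 5 + b[2:]]
    aa1 = np.full((4, n + 1), X_IDX, dtype=np.int8)
    aa2 = np.full((16, n + 1), X_IDX, dtype=np.int8)
    if n >= 2:
        # codon (x, s[i-2], s[i-1]) ending at i for i >= 2
        tail2 = b[:-1] * 5 + b[1:]             # s[i-2]*5 + s[i-1], index i-2
        for x in range(4):
            aa1[x, 2:] = CODON_AA[x * 25 + tail2]
    if n >= 1:
        for x in range(4):
            for y in range(4):
                aa2[x * 4 + y, 1:] = CODON_AA[(x * 5 + y) * 5 + b]
    donor = np.zeros(n + 1, dtype=np.bool_)
    acc_end = np.zeros(n + 1, dtype=np.bool_)
    if n >= 2:
        donor[:-3] = (base[:-2] == 2) & (base[1:-1] == 3)      # G, T
        acc_end[2:] = (base[:-1] == 0) & (base[1:] == 2)       # ends ..A G
    return cod3, aa1, aa2, donor, acc_end


def _traceback(res, base):
    """Decode kernel output into an ordered event list.

    Events: ("M", col, pieces, intron, code), ("I", col, piece), ("D", col);
    pieces are strand-local [start, end) intervals of consumed nucleotides.
    """
    best, bstate, bi, mcode, mdon, pmcode, icode, dcode = res
    L = mcode.shape[0] - 1
    events = []
    j, i = L, bi
    state = "M" if bstate == 1 else "D"
    start_pos = None
    while True:
        if state == "M" and j == 0:      # reached the begin state
            start_pos = i
            break
        if state == "M":
            code = int(mcode[j, i])
            don = int(mdon[j, i])
            intron = None
            if code == _kernels.M_DIRECT:
                pieces = [(i - 3, i)]
                prev = i - 3
            elif code == _kernels.M_INTRON0:
                pieces = [(i - 3, i)]
                intron = (don, i - 3)
                prev = don
            elif code == _kernels.M_INTRON1:
                pieces = [(don - 1, don), (i - 2, i)]
                intron = (don, i - 2)
                prev = don - 1
            elif code == _kernels.M_INTRON2:
                pieces = [(don - 2, don), (i - 1, i)]
                intron = (don, i - 1)
                prev = don - 2
            elif code == _kernels.M_FS1:
                pieces = [(i - 1, i)]
                prev = i - 1
            elif code == _kernels.M_FS2:
                pieces = [(i - 2, i)]
                prev = i - 2
            elif code == _kernels.M_FS4:
                pieces = [(i - 4, i)]
                prev = i - 4
            else:
                raise AssertionError("invalid traceback")
            events.append(("M", j, pieces, intron, code))
            j, i, state = j - 1, prev, "PM"
        elif state == "PM":
            pc = int(pmcode[j, i])
            if pc == 0:
                start_pos = i
                break
            state = "MID"[pc - 1]
        elif state == "I":
            ic = int(icode[j, i])
            events.append(("I", j, (i - 3, i)))
            i -= 3
            state = "M" if ic == 1 else "I"
        else:  # D
            dc = int(dcode[j, i])
            events.append(("D", j))
            j -= 1
            state = "M" if dc == 1 else "D"
    events.reverse()
    return events, start_pos, bi


def _codon_aa(base: np.ndarray, pieces) -> int:
    nts = [int(base[p]) for s, e in pieces for p in range(s, e)]
    if len(nts) != 3 or any(x == 4 for x in nts):
        return X_IDX
    return int(CODON_AA[(nts[0] * 5 + nts[1]) * 5 + nts[2]])


def score_events(events, start_pos, hmm: ProfileHMM, cfg: MiningConfig,
                 base: np.ndarray) -> float:
    """Independently re-evaluate the score of a traceback event list."""
    esc = hmm.emission_scores()
    esc[:, STOP_IDX] = cfg.stop_bits
    tsc = hmm.transition_scores()
    entry = -math.log2(hmm.L)
    total = entry
    prev = "M"   # the begin state acts as a match at column 0
    for ev in events:
        kind = ev[0]
        j = ev[1]
        if kind == "M":
            _, _, pieces, intron, code = ev
            if prev == "M":
                total += tsc[j - 1, 0]
            elif prev == "I":
                total += tsc[j - 1, 3]
            elif prev == "D":
                total += tsc[j - 1, 5]
            if intron is not None:
                total += cfg.intron_open_bits
            if code in (_kernels.M_FS1, _kernels.M_FS2, _kernels.M_FS4):
                total += cfg.frameshift_bits
            else:
                total += esc[j - 1, _codon_aa(base, pieces)]
            prev = "M"
        elif kind == "I":
            _, j, piece = ev
            total += tsc[j, 1] if prev == "M" else tsc[j, 4]
            aa = _codon_aa(base, [piece])
            total += cfg.stop_bits if aa == STOP_IDX else 0.0
            prev = "I"
        else:
            total += tsc[j - 1, 2] if prev == "M" else tsc[j - 1, 6]
            prev = "D"
    total += -math.log2(hmm.L)
    return float(total)


def _events_to_model(events, start_pos, end_pos, hmm: ProfileHMM,
                     cfg: MiningConfig, seq: str, base: np.ndarray,
                     strand: str, contig: str, locus_offset: int, n: int,
                     model_id: str) -> GeneModel:
    introns = []
    protein = []
    frameshift = False
    internal_stop = False
    m_cols = []
    d_cols = 0
    for ev in events:
        if ev[0] == "M":
            _, j, pieces, intron, code = ev
            m_cols.append(j)
            if intron is not None:
                introns.append(intron)
            if code in (_kernels.M_FS1, _kernels.M_FS2, _kernels.M_FS4):
                frameshift = True
                protein.append("X")
            else:
                aa = _codon_aa(base, pieces)
                if aa == STOP_IDX:
                    internal_stop = True
                protein.append(IDX_TO_AA[aa])
        elif ev[0] == "I":
            aa = _codon_aa(base, [ev[2]])
            if aa == STOP_IDX:
                internal_stop = True
            protein.append(IDX_TO_AA[aa])
        else:
            d_cols += 1

    # exons in strand-local coordinates: split consumed span at introns
    exons_local = []
    cur = start_pos
    for (d, c) in introns:
        exons_local.append((cur, d))
        cur = c
    exons_local.append((cur, end_pos))
    for (d, c) in introns:
        assert seq[d:d + 2] == "GT" and seq[c - 2:c] == "AG"

    if strand == "+":
        exons = [(locus_offset + s, locus_offset + e) for s, e in exons_local]
    else:
        exons = [(locus_offset + n - e, locus_offset + n - s) for s, e in exons_local]
        exons.reverse()

    cds = "".join(seq[s:e] for s, e in exons_local)
    # glocal span: every column is M or D, so coverage counts matched columns
    coverage = len(m_cols) / hmm.L
    flags = {
        "frameshift": frameshift,
        "internal_stop": internal_stop,
        "pseudogene": frameshift or internal_stop,
        "partial": coverage < 0.9,
    }
    return GeneModel(
        model_id=model_id, contig=contig, strand=strand, exons=exons,
        cds=cds, protein="".join(protein), flags=flags,
        scores={"coverage": float(coverage), "span_aa": len(m_cols)},
    )


def spliced_align(hmm: ProfileHMM, locus: str, cfg: MiningConfig,
                  strand: str = "+", contig: str = "locus",
                  locus_offset: int = 0, model_id: str = "model",
                  return_events: bool = False, _depth: int = 0):
    """Best spliced gene model of the profile in the locus, or None.

    Works on the given strand (the reverse complement is aligned for '-';
    coordinates are reported on the forward strand).  Introns longer than
    cfg.max_intron are never emitted: a traceback that would need one is
    treated as a chimera of two loci, which are re-aligned separately.
    """
    if len(locus) < 3:
        return None
    seq = locus if strand == "+" else revcomp(locus)
    base = dna_to_indices(seq)
    n = len(seq)
    if np.all(base == 4):
        return None
    cod3, aa1, aa2, donor, acc_end = _locus_tables(base)
    escM = hmm.emission_scores()
    escM[:, STOP_IDX] = cfg.stop_bits
    escI = np.zeros(22)
    escI[STOP_IDX] = cfg.stop_bits
    tsc = hmm.transition_scores()
    lgl = math.log2(hmm.L)
    res = _kernels.spliced_kernel(
        escM, escI, tsc, base, cod3, aa1, aa2, donor, acc_end,
        -lgl, -lgl, cfg.intron_open_bits, cfg.frameshift_bits, cfg.min_intron)
    best = float(res[0])
    floor = min(cfg.min_spliced_score, cfg.report_floor_bits)
    if best < floor:
        return None
    events, start_pos, end_pos = _traceback(res, base)
    if not any(ev[0] == "M" for ev in events):
        return None

    # enforce the maximum intron length: an oversized "intron" is a chimera
    oversized = None
    for ev in events:
        if ev[0] == "M" and ev[3] is not None:
            d, c = ev[3]
            if c - d > cfg.max_intron:
                oversized = (d, c)
                break
    if oversized is not None:
        if _depth >= 8:
            return None
        d, c = oversized
        halves = []
        for lo, hi in ((0, d + 2), (c - 2, n)):
            if hi - lo < n:
                sub = seq[lo:hi]
                if strand == "+":
                    off = locus_offset + lo
                    m = spliced_align(hmm, sub, cfg, "+", contig, off,
                                      model_id, _depth=_depth + 1)
                else:
                    # sub is in reverse-strand coordinates; map back
                    off = locus_offset + (n - hi)
                    m = spliced_align(hmm, revcomp(sub), cfg, "-", contig, off,
                                      model_id, _depth=_depth + 1)
                if m is not None:
                    halves.append(m)
        if not halves:
            return None
        return max(halves, key=lambda m: m.scores["spliced_score"])

    model = _events_to_model(events, start_pos, end_pos, hmm, cfg, seq, base,
                             strand, contig, locus_offset, n, model_id)
    model.scores["spliced_score"] = best
    for (a, b) in model.introns:
        assert cfg.min_intron <= b - a <= cfg.max_intron
    if return_events:
        return model, (events, start_pos, base)
    return model
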