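"""Scoring proteins against a ProfileHMM: Viterbi, forward, E-values.

``bitscore`` is the forward score in bits (all-paths log-odds), matching the
semantics of the HMMER-style cutoff used by the high-quality filter; the
spliced genome aligner reports its own Viterbi-style score on a separate
scale so the two thresholds are never conflated.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import _kernels
from .alphabet import AA, BACKGROUND, protein_to_indices
from .profiles import ProfileHMM


@dataclass
class ProfileAlignment:
    hmm_name: str
    query_id: str
    score_bits: float
    path: list[tuple[str, int, int]]   # (state M/I/D, profile column 1-based, query idx 0-based; -1 for D)
    span_aa: int
    coverage: float


def _entry_exit(hmm: ProfileHMM) -> tuple[float, float]:
    return -math.log2(hmm.L), -math.log2(hmm.L)


def viterbi_raw(hmm: ProfileHMM, query: str) -> float:
    """Best non-empty local alignment score in bits, without the 0 floor.

    Used for E-value calibration, where the tail of chance scores matters
    even when it lies below the empty-alignment baseline.
    """
    if not query:
        raise ValueError("empty query")
    q = protein_to_indices(query.replace("*", "X"))
    entry, exit_ = _entry_exit(hmm)
    bits, *_ = _kernels.viterbi_kernel(hmm.emission_scores(),
                                       hmm.transition_scores(), q, entry, exit_)
    return float(bits)


def viterbi(hmm: ProfileHMM, query: str, query_id: str = "query") -> ProfileAlignment:
    """Best local alignment of a protein to the profile, score in bits.

    '*' in the query is treated as X (background emission).  The empty
    alignment is allowed: a profile indistinguishable from background yields
    score 0 with an empty path.
    """
    if not query:
        raise ValueError("empty query")
    q = protein_to_indices(query.replace("*", "X"))
    esc = hmm.emission_scores()
    tsc = hmm.transition_scores()
    entry, exit_ = _entry_exit(hmm)
    bits, bj, bk, ptrM, ptrI, ptrD = _kernels.viterbi_kernel(esc, tsc, q, entry, exit_)
    bits = max(0.0, float(bits))
    path: list[tuple[str, int, int]] = []
    if bits > 0.0 and bj > 0:
        j, k, state = bj, bk, "M"
        while True:
            if state == "M":
                path.append(("M", j, k - 1))
                p = ptrM[j, k]
                j, k = j - 1, k - 1
                if p == 0:
                    break
                state = "MID"[p - 1]
            elif state == "I":
                path.append(("I", j, k - 1))
                p = ptrI[j, k]
                k -= 1
                state = "M" if p == 1 else "I"
            else:
                path.append(("D", j, -1))
                p = ptrD[j, k]
                j -= 1
                state = "M" if p == 1 else "D"
        path.reverse()
    span = sum(1 for s, _, _ in path if s == "M")
    cov = sum(1 for s, _, _ in path if s in ("M", "D")) / hmm.L
    return ProfileAlignment(hmm.name, query_id, float(bits), path, span, cov)


def forward(hmm: ProfileHMM, query: str) -> float:
    """All-paths log-odds score in bits (always >= the Viterbi score)."""
    if not query:
        raise ValueError("empty query")
    q = protein_to_indices(query.replace("*", "X"))
    odds = np.power(2.0, hmm.emission_scores())
    tp = hmm.transitions
    return float(_kernels.forward_kernel(odds, tp, q, 1.0 / hmm.L, 1.0 / hmm.L))


def bitscore(hmm: ProfileHMM, query: str) -> float:
    """Bitscore of a protein against the profile (defined as the forward score)."""
    return forward(hmm, query)


def fit_gumbel(scores: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood Gumbel fit; returns (mu, lambda)."""
    scores = np.asarray(scores, dtype=float)
    if scores.std() < 1e-12:
        raise ValueError("degenerate score variance; cannot calibrate")
    mu, beta = stats.gumbel_r.fit(scores)
    return float(mu), float(1.0 / beta)


def sample_background_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AA[i] for i in rng.choice(20, size=length, p=BACKGROUND))


def calibrate_evalue(hmm: ProfileHMM, n_decoys: int = 200, decoy_len: int = 720,
                     seed: int = 0) -> tuple[float, float]:
    """Fit a Gumbel law to Viterbi scores of background decoys.

    Stores (mu, lambda) plus the decoy length on the profile so that
    ``evalue`` can extrapolate to a database of arbitrary size.
    """
    if n_decoys < 50:
        raise ValueError("need at least 50 decoys for calibration")
    rng = np.random.default_rng(seed)
    scores = np.array([
        viterbi_raw(hmm, sample_background_protein(rng, decoy_len))
        for _ in range(n_decoys)
    ])
    mu, lam = fit_gumbel(scores)
    hmm.calibration = (mu, lam)
    hmm.calibration_decoy_len = decoy_len
    return mu, lam


def evalue(hmm: ProfileHMM, score_bits: float, db_residues: int) -> float:
    """Expected number of chance hits scoring >= score_bits in db_residues.

    E = (db_residues / decoy_len) * P_Gumbel(S >= score); exactly linear in
    db_residues and strictly decreasing in score.
    """
    if hmm.calibration is None:
        raise ValueError(f"profile {hmm.name} is not calibrated")
    mu, lam = hmm.calibration
    decoy_len = getattr(hmm, "calibration_decoy_len", 720)
    p = float(stats.gumbel_r.sf(score_bits, loc=mu, scale=1.0 / lam))
    return (db_residues / decoy_len) * p
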