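"""Profile-HMM construction from weighted seed alignments.

A profile is built from a multiple alignment whose rows carry Henikoff
position-based weights: match columns (weighted gap fraction < 50%) contribute
match-emission counts, gap patterns contribute the M/I/D transition counts,
and background-proportional pseudocounts regularise both.  The same weighted
alignment underlies the AWSI (average weighted sequence identity) refilter
used by the mining cascade.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .alphabet import AA, AA_INDEX, BACKGROUND, X_IDX, STOP_IDX, protein_to_indices
from .seqio import SeqRecord

GAP = "-"


@dataclass
class WeightedMSA:
    rows: list[tuple[str, str]]            # (id, aligned sequence with '-')
    weights: np.ndarray                    # per-row, sums to n_rows
    match_mask: np.ndarray                 # per-column bool

    def __post_init__(self):
        widths = {len(s) for _, s in self.rows}
        if len(widths) != 1:
            raise ValueError("all MSA rows must have equal length")
        if not np.any(self.match_mask):
            raise ValueError("alignment has no match columns")
        if np.any(self.weights <= 0):
            raise ValueError("row weights must be positive")

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def match_columns(self) -> np.ndarray:
        return np.flatnonzero(self.match_mask)


def henikoff_weights(rows: list[tuple[str, str]]) -> np.ndarray:
    """Position-based sequence weights (Henikoff & Henikoff).

    Each column with r distinct residue types gives a cell with residue a
    (observed s times in the column) a contribution 1/(r*s); gap cells
    contribute nothing and all-gap columns are skipped.  Weights are
    normalised to sum to the number of rows.
    """
    n = len(rows)
    if n == 0:
        raise ValueError("empty alignment")
    width = len(rows[0][1])
    raw = np.zeros(n)
    for c in range(width):
        col = [s[c] for _, s in rows]
        residues = [a for a in col if a != GAP]
        if not residues:
            continue
        counts: dict[str, int] = {}
        for a in residues:
            counts[a] = counts.get(a, 0) + 1
        r = len(counts)
        for i, a in enumerate(col):
            if a != GAP:
                raw[i] += 1.0 / (r * counts[a])
    if raw.sum() == 0:
        raw[:] = 1.0
    return raw * n / raw.sum()


def make_weighted_msa(rows: list[tuple[str, str]],
                      gap_fraction: float = 0.5) -> WeightedMSA:
    """Attach Henikoff weights and the default match mask (<50% weighted gaps)."""
    weights = henikoff_weights(rows)
    width = len(rows[0][1])
    gap_w = np.zeros(width)
    for (_, s), w in zip(rows, weights):
        for c, a in enumerate(s):
            if a == GAP:
                gap_w[c] += w
    mask = gap_w < gap_fraction * weights.sum()
    return WeightedMSA(rows, weights, mask)


@dataclass
class ProfileHMM:
    """Match/insert/delete model with log-odds scoring in bits.

    ``transitions[j]`` holds (MM, MI, MD, IM, II, DM, DD) leaving position j;
    position 0 is the begin state.  Local alignment uses uniform wing entry
    and exit over the L match columns.
    """

    name: str
    L: int
    match_emis: np.ndarray                 # (L, 20)
    insert_emis: np.ndarray                # (20,)
    transitions: np.ndarray                # (L + 1, 7)
    background: np.ndarray                 # (20,)
    group: str | None = None
    calibration: tuple[float, float] | None = None   # Gumbel (mu, lambda)
    calibration_decoy_len: int = 720
    seed_msa: WeightedMSA | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.L < 1:
            raise ValueError("profile must have at least one match column")
        if np.any(self.background <= 0):
            raise ValueError("background must be strictly positive")
        if not np.allclose(self.match_emis.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("match emission rows must sum to 1")
        t = self.transitions
        for sl, what in (((0, 1, 2), "M"), ((3, 4), "I"), ((5, 6), "D")):
            if not np.allclose(t[:, list(sl)].sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{what} transition rows must sum to 1")

    # -- scoring tables -----------------------------------------------------
    def emission_scores(self) -> np.ndarray:
        """(L, 22) log2-odds match emission table; X scores 0, '*' scores 0.

        The stop column is 0 here; the spliced aligner applies its own stop
        penalty on top.
        """
        esc = np.zeros((self.L, 22), dtype=np.float64)
        esc[:, :20] = np.log2(self.match_emis / self.background[None, :])
        esc[:, X_IDX] = 0.0
        esc[:, STOP_IDX] = 0.0
        return esc

    def transition_scores(self) -> np.ndarray:
        return np.log2(self.transitions)

    def consensus(self) -> str:
        return "".join(AA[i] for i in np.argmax(self.match_emis, axis=1))


def build_profile(msa: WeightedMSA, pseudocount_strength: float = 1.0,
                  background: np.ndarray = BACKGROUND, name: str = "profile",
                  group: str | None = None) -> ProfileHMM:
    """Estimate a ProfileHMM from a weighted alignment.

    Match emissions are (weighted counts + pc * background) normalised;
    transitions come from weighted gap patterns with Laplace (+1)
    pseudocounts.  X/ambiguous cells are ignored in the counts.
    """
    if pseudocount_strength <= 0:
        raise ValueError("pseudocount_strength must be positive")
    cols = msa.match_columns
    L = len(cols)
    if L == 0:
        raise ValueError("no match columns")
    counts = np.zeros((L, 20))
    for (_, s), w in zip(msa.rows, msa.weights):
        for j, c in enumerate(cols):
            a = s[c]
            if a in AA_INDEX:
                counts[j, AA_INDEX[a]] += w
    emis = counts + pseudocount_strength * background[None, :]
    emis /= emis.sum(axis=1, keepdims=True)

    # transition counts: per row walk begin -> col_1 -> ... -> col_L -> end
    tc = np.zeros((L + 1, 7))   # MM MI MD IM II DM DD
    col_set = set(int(c) for c in cols)
    for (_, s), w in zip(msa.rows, msa.weights):
        states = ["M"] + ["M" if s[c] != GAP else "D" for c in cols]
        # residues in insert columns between match columns j and j+1
        bounds = [-1] + [int(c) for c in cols] + [msa.width]
        for j in range(L + 1):
            lo, hi = bounds[j] + 1, bounds[j + 1]
            n_ins = sum(1 for c in range(lo, hi) if s[c] != GAP)
            prev = states[j]
            nxt = states[j + 1] if j < L else "M"   # M_L -> end counted as M->M
            if prev == "D" and n_ins > 0:
                n_ins = 0   # D -> I not modelled; rare, fold into D -> next
            if n_ins > 0:
                tc[j, 1] += w                              # M->I
                tc[j, 4] += w * (n_ins - 1)                # I->I
                tc[j, 3] += w                              # I->next (as I->M)
            else:
                if prev == "M":
                    tc[j, 0 if nxt == "M" else 2] += w
                else:
                    tc[j, 5 if nxt == "M" else 6] += w
    tc += 1.0   # Laplace
    trans = np.zeros_like(tc)
    trans[:, 0:3] = tc[:, 0:3] / tc[:, 0:3].sum(axis=1, keepdims=True)
    trans[:, 3:5] = tc[:, 3:5] / tc[:, 3:5].sum(axis=1, keepdims=True)
    trans[:, 5:7] = tc[:, 5:7] / tc[:, 5:7].sum(axis=1, keepdims=True)
    return ProfileHMM(name=name, group=group, L=L, match_emis=emis,
                      insert_emis=background.copy(), transitions=trans,
                      background=background.copy(), seed_msa=msa)


# ---------------------------------------------------------------------------
# AWSI
# ---------------------------------------------------------------------------

def awsi_from_columns(candidate_cols: dict[int, str], msa: WeightedMSA) -> float:
    """AWSI given the candidate's residues per profile match column.

    Returns sum_i w_i * pid_i / sum_i w_i where pid_i is the fractional
    identity between candidate and row i over match columns where both are
    non-gap; a row with no overlap contributes pid 0.
    """
    cols = msa.match_columns
    num = 0.0
    for (_, s), w in zip(msa.rows, msa.weights):
        overlap = 0
        same = 0
        for j, c in enumerate(cols):
            a = s[c]
            b = candidate_cols.get(j)
            if a != GAP and b is not None:
                overlap += 1
                if a == b:
                    same += 1
        pid = same / overlap if overlap else 0.0
        num += w * pid
    return num / msa.weights.sum()


def awsi(candidate: str, msa: WeightedMSA, hmm: ProfileHMM | None = None) -> float:
    """Align the candidate to the MSA's profile and compute AWSI in [0, 1]."""
    from . import scoring   # local import: scoring is a sibling layer
    if hmm is None:
        hmm = build_profile(msa)
    aln = scoring.viterbi(hmm, candidate)
    cand_cols = {col - 1: candidate[q] for st, col, q in aln.path if st == "M"}
    return awsi_from_columns(cand_cols, msa)


# ---------------------------------------------------------------------------
# representative selection and a minimal progressive aligner
# ---------------------------------------------------------------------------

def identity_distance(a: str, b: str) -> float:
    """1 - identity, with identity = 1 - editdistance / max(len)."""
    d = edlib.align(a, b, task="distance")["editDistance"]
    return d / max(len(a), len(b))


def _distance_matrix(seqs: list[SeqRecord]) -> np.ndarray:
    n = len(seqs)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = identity_distance(seqs[i].sequence, seqs[j].sequence)
            dm[i, j] = dm[j, i] = d
    return dm


def select_representatives(seqs: list[SeqRecord], k: int = 100,
                           seed: int = 0) -> list[SeqRecord]:
    """Deterministic farthest-first subset of up to k sequences.

    Starts from the medoid of the pairwise identity-distance matrix and
    repeatedly adds the sequence farthest from the chosen set; ties break on
    lexicographic id.  Below k this is the identity.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(seqs) <= k:
        return list(seqs)
    dm = _distance_matrix(seqs)
    ids = [s.id for s in seqs]
    totals = dm.sum(axis=1)
    medoid = min(range(len(seqs)), key=lambda i: (totals[i], ids[i]))
    chosen = [medoid]
    chosen_set = {medoid}
    mind = dm[medoid].copy()
    while len(chosen) < k:
        best = None
        for i in range(len(seqs)):
            if i in chosen_set:
                continue
            key = (-mind[i], ids[i])
            if best is None or key < best[0]:
                best = (key, i)
        i = best[1]
        chosen.append(i)
        chosen_set.add(i)
        mind = np.minimum(mind, dm[i])
    return [seqs[i] for i in sorted(chosen)]


def _pairwise_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_global(a: str, b: str) -> tuple[float, str, str]:
    """Best global alignment of two proteins (BLOSUM62, affine -11/-1)."""
    aligner = _pairwise_aligner()
    aln = aligner.align(a, b)[0]
    return float(aln.score), str(aln[0]), str(aln[1])


def simple_msa(seqs: list[SeqRecord]) -> WeightedMSA:
    """Center-star progressive alignment.

    The center is the sequence with the greatest summed pairwise identity
    (equivalently, minimal summed identity distance); every other sequence is
    globally aligned to it and the pairwise alignments are merged on the
    center's coordinates.
    """
    if not seqs:
        raise ValueError("no sequences")
    if len(seqs) == 1:
        return make_weighted_msa([(seqs[0].id, seqs[0].sequence)])
    dm = _distance_matrix(seqs)
    ids = [s.id for s in seqs]
    totals = dm.sum(axis=1)
    ci = min(range(len(seqs)), key=lambda i: (totals[i], ids[i]))
    center = seqs[ci].sequence
    others = [s for i, s in enumerate(seqs) if i != ci]

    # parse each pairwise alignment into (inserts before center pos p, residue at p)
    parsed = []
    for s in others:
        _, ca, sa = pairwise_global(center, s.sequence)
        ins: list[str] = [""] * (len(center) + 1)
        aligned: list[str] = []
        p = 0
        for x, y in zip(ca, sa):
            if x == GAP:
                ins[p] += y
            else:
                aligned.append(y)
                p += 1
        parsed.append((s.id, ins, aligned))

    max_ins = [0] * (len(center) + 1)
    for _, ins, _ in parsed:
        for p, chunk in enumerate(ins):
            max_ins[p] = max(max_ins[p], len(chunk))

    def render(ins: list[str], aligned: list[str]) -> str:
        out = []
        for p in range(len(center) + 1):
            chunk = ins[p] if p < len(ins) else ""
            out.append(chunk + GAP * (max_ins[p] - len(chunk)))
            if p < len(center):
                out.append(aligned[p])
        return "".join(out)

    rows = [(seqs[ci].id, render([""] * (len(center) + 1), list(center)))]
    for sid, ins, aligned in parsed:
        rows.append((sid, render(ins, aligned)))
    order = {s.id: i for i, s in enumerate(seqs)}
    rows.sort(key=lambda r: order[r[0]])
    return make_weighted_msa(rows)


# ---------------------------------------------------------------------------
# sampling (fixture support)
# ---------------------------------------------------------------------------

def sample_from_profile(hmm: ProfileHMM, n: int, seed: int = 0) -> list[SeqRecord]:
    """Draw n sequences by stochastic glocal traversal of the profile."""
    rng = np.random.default_rng(seed)
    out = []
    t = hmm.transitions
    for i in range(n):
        residues: list[str] = []
        state = "M"   # begin acts like a match state at position 0
        j = 0
        while j <= hmm.L:
            if state == "M" and j > 0:
                residues.append(AA[rng.choice(20, p=hmm.match_emis[j - 1])])
            if state == "I":
                residues.append(AA[rng.choice(20, p=hmm.insert_emis)])
            if j == hmm.L and state != "I":
                break
            if state == "M":
                probs = t[j, 0:3]
                nxt = ["M", "I", "D"][rng.choice(3, p=probs / probs.sum())]
            elif state == "I":
                probs = t[j, 3:5]
                nxt = ["M", "I"][rng.choice(2, p=probs / probs.sum())]
            else:
                probs = t[j, 5:7]
                nxt = ["M", "D"][rng.choice(2, p=probs / probs.sum())]
            if nxt == "I":
                state = "I"
            else:
                state = nxt
                j += 1
        out.append(SeqRecord(f"{hmm.name}_s{i}", "".join(residues), molecule="protein"))
    return out


# ---------------------------------------------------------------------------
# plain-text serialization (versioned, diffable)
# ---------------------------------------------------------------------------

MAGIC = "OSCMINE-PROFILE\tv1"


def save_profile(hmm: ProfileHMM, path) -> None:
    with open(path, "w") as fh:
        fh.write(MAGIC + "\n")
        fh.write(f"name\t{hmm.name}\n")
        fh.write(f"group\t{hmm.group if hmm.group is not None else '.'}\n")
        fh.write(f"L\t{hmm.L}\n")
        if hmm.calibration is not None:
            fh.write(f"calibration\t{float(hmm.calibration[0])!r}\t"
                     f"{float(hmm.calibration[1])!r}\t{hmm.calibration_decoy_len}\n")
        fh.write("background\t" + "\t".join(repr(float(x)) for x in hmm.background) + "\n")
        fh.write("insert\t" + "\t".join(repr(float(x)) for x in hmm.insert_emis) + "\n")
        for j in range(hmm.L + 1):
            fh.write(f"T{j}\t" + "\t".join(repr(float(x)) for x in hmm.transitions[j]) + "\n")
        for j in range(hmm.L):
            fh.write(f"M{j + 1}\t" + "\t".join(repr(float(x)) for x in hmm.match_emis[j]) + "\n")


def load_profile(path) -> ProfileHMM:
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh]
    if not lines or lines[0] != MAGIC:
        raise ValueError(f"{path}: not an oscmine profile file")
    meta: dict[str, list[str]] = {}
    trans: dict[int, list[float]] = {}
    emis: dict[int, list[float]] = {}
    for line in lines[1:]:
        if not line:
            continue
        key, *vals = line.split("\t")
        if key.startswith("T") and key[1:].isdigit():
            trans[int(key[1:])] = [float(v) for v in vals]
        elif key.startswith("M") and key[1:].isdigit():
            emis[int(key[1:])] = [float(v) for v in vals]
        else:
            meta[key] = vals
    L = int(meta["L"][0])
    hmm = ProfileHMM(
        name=meta["name"][0],
        group=None if meta["group"][0] == "." else meta["group"][0],
        L=L,
        match_emis=np.array([emis[j + 1] for j in range(L)]),
        insert_emis=np.array([float(v) for v in meta["insert"]]),
        transitions=np.array([trans[j] for j in range(L + 1)]),
        background=np.array([float(v) for v in meta["background"]]),
        calibration=(float(meta["calibration"][0]), float(meta["calibration"][1]))
        if "calibration" in meta else None,
        calibration_decoy_len=int(meta["calibration"][2]) if "calibration" in meta else 720,
    )
    return hmm
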