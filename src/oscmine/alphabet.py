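"""Shared alphabets, genetic code tables and amino-acid background frequencies."""
from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

#: canonical amino-acid order used for all emission vectors
AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}
X_IDX = 20   # unknown residue: emitted with background odds (0 bits)
STOP_IDX = 21
N_AA_STATES = 22

DNA = "ACGTN"
DNA_INDEX = {b: i for i, b in enumerate(DNA)}

# Robinson & Robinson amino-acid background frequencies (order of AA above)
BACKGROUND = np.array([
    0.07805, 0.01925, 0.05364, 0.06295, 0.03856, 0.07377, 0.02199, 0.05142,
    0.05744, 0.09019, 0.02243, 0.04487, 0.05203, 0.04264, 0.05129, 0.07120,
    0.05841, 0.06441, 0.01330, 0.03216,
])
BACKGROUND = BACKGROUND / BACKGROUND.sum()

_table1 = CodonTable.unambiguous_dna_by_id[1]


def _codon_lookup() -> np.ndarray:
    """125-entry codon -> amino-acid-index table over the {A,C,G,T,N} alphabet.

    Codons containing N map to X; stop codons map to STOP_IDX.
    """
    lut = np.full(5 * 5 * 5, X_IDX, dtype=np.int8)
    for i, b1 in enumerate(DNA):
        for j, b2 in enumerate(DNA):
            for k, b3 in enumerate(DNA):
                idx = (i * 5 + j) * 5 + k
                codon = b1 + b2 + b3
                if "N" in codon:
                    lut[idx] = X_IDX
                elif codon in _table1.stop_codons:
                    lut[idx] = STOP_IDX
                else:
                    lut[idx] = AA_INDEX[_table1.forward_table[codon]]
    return lut


CODON_AA = _codon_lookup()

#: reverse genetic code: amino acid -> list of codons (table 1)
CODONS_FOR_AA: dict[str, list[str]] = {}
for _codon, _aa in _table1.forward_table.items():
    CODONS_FOR_AA.setdefault(_aa, []).append(_codon)
for _aa in CODONS_FOR_AA:
    CODONS_FOR_AA[_aa].sort()

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def dna_to_indices(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 indices into {A,C,G,T,N}."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in DNA_INDEX.items():
        out[arr == ord(base)] = idx
    if (out < 0).any():
        bad = chr(arr[int(np.argmax(out < 0))])
        raise ValueError(f"invalid nucleotide character {bad!r}")
    return out


def protein_to_indices(seq: str) -> np.ndarray:
    """Encode a protein string; X (and any ambiguity) -> X_IDX, '*' -> STOP_IDX."""
    out = np.full(len(seq), X_IDX, dtype=np.int8)
    for i, a in enumerate(seq):
        if a in AA_INDEX:
            out[i] = AA_INDEX[a]
        elif a == "*":
            out[i] = STOP_IDX
        elif a not in "XBZJUO":
            raise ValueError(f"invalid amino-acid character {a!r}")
    return out
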