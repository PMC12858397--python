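"""FASTA / GFF3 / Stockholm readers and writers plus nucleic-acid utilities.

Internal coordinates are 0-based half-open everywhere; the GFF3 boundary is the
only place 1-based inclusive coordinates appear.  Minus-strand gene models are
stored with forward-strand genomic coordinates plus a strand field.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO

from .alphabet import COMPLEMENT, CODON_AA, dna_to_indices

_PROTEIN_OK = set("ACDEFGHIKLMNPQRSTVWYX*")
_DNA_OK = set("ACGTN")

IDX_TO_AA = "ACDEFGHIKLMNPQRSTVWY" + "X*"


class FastaParseError(ValueError):
    pass


@dataclass
class SeqRecord:
    """A named sequence; ``molecule`` is 'dna' or 'protein'."""

    id: str
    sequence: str
    description: str = ""
    molecule: str = "dna"

    def __post_init__(self):
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GenomeRecord:
    assembly_id: str
    species: str
    contigs: list[SeqRecord]
    annotation: list | None = None

    def __post_init__(self):
        ids = [c.id for c in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.assembly_id}: duplicate contig ids")

    def contig(self, cid: str) -> SeqRecord:
        for c in self.contigs:
            if c.id == cid:
                return c
        raise KeyError(cid)

    @property
    def total_bp(self) -> int:
        return sum(len(c) for c in self.contigs)


def read_fasta(path, molecule: str = "dna") -> list[SeqRecord]:
    """Read a (multi-)FASTA file.

    Sequences are uppercased; for DNA, U is mapped to T and gap characters or
    non-{A,C,G,T,N} ambiguity codes are rejected.  An empty file yields an
    empty list; a sequence line before any header is a parse error naming the
    line number.
    """
    if molecule not in ("dna", "protein"):
        raise ValueError(f"unknown molecule type {molecule!r}")
    records: list[SeqRecord] = []
    cur_id = None
    cur_desc = ""
    chunks: list[str] = []

    def _flush():
        if cur_id is None:
            return
        seq = "".join(chunks)
        if molecule == "dna":
            seq = seq.replace("U", "T")
            bad = set(seq) - _DNA_OK
        else:
            bad = set(seq) - _PROTEIN_OK
        if bad:
            raise FastaParseError(
                f"{path}: record {cur_id!r} contains invalid characters {sorted(bad)}"
            )
        records.append(SeqRecord(cur_id, seq, cur_desc, molecule))

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].strip()
                if not header:
                    raise FastaParseError(f"{path}: empty FASTA header at line {lineno}")
                parts = header.split(None, 1)
                cur_id = parts[0]
                cur_desc = parts[1] if len(parts) > 1 else ""
                chunks = []
            else:
                if cur_id is None:
                    raise FastaParseError(
                        f"{path}: sequence data before first header at line {lineno}"
                    )
                chunks.append(line.strip().upper())
        _flush()
    return records


def write_fasta(records: Iterable[SeqRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_stockholm(path) -> list[tuple[str, str]]:
    """Read a Stockholm seed alignment as (id, aligned sequence) rows.

    '.' gaps are normalised to '-'; sequences are uppercased.
    """
    aln = AlignIO.read(path, "stockholm")
    return [(r.id, str(r.seq).upper().replace(".", "-")) for r in aln]


def revcomp(dna: str) -> str:
    """Reverse complement over {A,C,G,T,N} (uppercase)."""
    bad = set(dna) - _DNA_OK
    if bad:
        raise ValueError(f"invalid nucleotide characters {sorted(bad)}")
    return dna.translate(COMPLEMENT)[::-1]


def translate(dna: str, frame: int = 0, table: int = 1) -> str:
    """Translate with the standard code; stops render '*', N-codons render 'X'.

    The trailing partial codon is dropped.  Only table 1 is supported.
    """
    if table != 1:
        raise ValueError("only genetic code table 1 is supported")
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    if len(dna) < frame + 3:
        raise ValueError("sequence shorter than frame + one codon")
    idx = dna_to_indices(dna)
    sub = idx[frame : frame + 3 * ((len(idx) - frame) // 3)]
    codons = (sub.reshape(-1, 3).astype(np.int64) * np.array([25, 5, 1])).sum(axis=1)
    aas = CODON_AA[codons]
    return "".join(IDX_TO_AA[a] for a in aas)


# ---------------------------------------------------------------------------
# Gene models and GFF3
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A predicted gene: exons in forward-strand 0-based half-open coordinates."""

    model_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds: str = ""
    protein: str = ""
    flags: dict = field(default_factory=lambda: {
        "frameshift": False, "internal_stop": False, "pseudogene": False, "partial": False,
    })
    scores: dict = field(default_factory=dict)
    source: str = "mined"

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        exons = sorted(tuple(e) for e in self.exons)
        for (s, e) in exons:
            if not (0 <= s < e):
                raise ValueError(f"{self.model_id}: invalid exon interval [{s},{e})")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.model_id}: overlapping exons")
        self.exons = exons

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]

    def spliced_sequence(self, contig_seq: str) -> str:
        """Spliced, strand-corrected CDS extracted from the contig."""
        parts = [contig_seq[s:e] for s, e in self.exons]
        seq = "".join(parts)
        return seq if self.strand == "+" else revcomp(seq)


def model_protein(model: GeneModel, contig_seq: str) -> str:
    """Re-derive the protein from genomic sequence and check model consistency.

    A terminal stop is trimmed.  Frameshifted models (CDS length not a multiple
    of 3) are translated up to the last full codon; consistency for those is
    checked only on length agreement within one residue.
    """
    cds = model.spliced_sequence(contig_seq)
    prot = translate(cds) if len(cds) >= 3 else ""
    if prot.endswith("*"):
        prot = prot[:-1]
    if model.protein and not model.flags.get("frameshift"):
        stored = model.protein.rstrip("*")
        if stored.replace("*", "X") != prot.replace("*", "X"):
            raise ValueError(f"{model.model_id}: stored protein disagrees with CDS translation")
    return prot


def write_gff3(models: Sequence[GeneModel], path) -> None:
    """Write gene/mRNA/CDS features with correct GFF3 phase per CDS segment."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            score = m.scores.get("spliced_score")
            score_s = f"{score:.2f}" if score is not None else "."
            fh.write(
                f"{m.contig}\toscmine\tgene\t{m.start + 1}\t{m.end}\t{score_s}\t{m.strand}\t.\t"
                f"ID={m.model_id}\n"
            )
            fh.write(
                f"{m.contig}\toscmine\tmRNA\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={m.model_id}.t1;Parent={m.model_id}\n"
            )
            exons = m.exons if m.strand == "+" else list(reversed(m.exons))
            consumed = 0
            for (s, e) in exons:
                phase = (3 - consumed % 3) % 3
                consumed += e - s
                fh.write(
                    f"{m.contig}\toscmine\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t{phase}\t"
                    f"ID={m.model_id}.cds;Parent={m.model_id}.t1\n"
                )


def read_gff3_models(path, protein_by_id: dict[str, str] | None = None) -> list[GeneModel]:
    """Read CDS features grouped by gene into GeneModels (for prior annotations)."""
    genes: dict[str, dict] = {}
    parent_gene: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}: malformed GFF3 line: {line!r}")
            contig, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                genes[attr["ID"]] = {"contig": contig, "strand": strand, "exons": []}
            elif ftype == "mRNA":
                parent_gene[attr["ID"]] = attr["Parent"]
            elif ftype == "CDS":
                gid = parent_gene.get(attr.get("Parent", ""), attr.get("Parent", ""))
                if gid not in genes:
                    genes[gid] = {"contig": contig, "strand": strand, "exons": []}
                genes[gid]["exons"].append((int(start) - 1, int(end)))
    out = []
    for gid, g in genes.items():
        if not g["exons"]:
            continue
        m = GeneModel(gid, g["contig"], g["strand"], g["exons"], source="prior_annotation")
        if protein_by_id and gid in protein_by_id:
            m.protein = protein_by_id[gid]
        out.append(m)
    return out


def write_tsv(rows: Sequence[dict], columns: Sequence[str], path) -> None:
    """Plain deterministic TSV writer (header + str() cells)."""
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for r in rows:
            fh.write("\t".join(str(r.get(c, "")) for c in columns) + "\n")
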