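"""Synthetic genomes, protein families and copy matrices with known truth.

The generator emulates the mining targets: a star phylogeny of subfamily
consensus sequences around a common ancestor, members sampled per subfamily,
and multi-exon genes implanted into plant-like background DNA (36% GC) with
GT..AG introns of log-uniform length.  Pseudogenes are made by a single
nucleotide insertion (frameshift) or a nonsense substitution (premature
stop); partial genes are truncated below the high-quality length floor.
Implanted intron boundaries are checked for splice-shift ambiguity so that
exon-exact recovery is well defined.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import AA, BACKGROUND, CODONS_FOR_AA, COMPLEMENT
from .profiles import ProfileHMM, WeightedMSA, build_profile, make_weighted_msa
from .profiling import BloomCall, CopyMatrix
from .seqio import GenomeRecord, SeqRecord, revcomp, translate

import pandas as pd

GROUP_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass
class GeneTruth:
    gene_id: str
    genome_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]          # forward-strand, 0-based half-open
    intron_phases: list[int]
    group: str
    status: str                           # intact | frameshift_pseudogene | stop_pseudogene | partial | overlap_decoy
    protein: str

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class FixtureConfig:
    n_genomes: int = 20
    genome_len: int = 1_000_000
    n_intact: int = 200
    n_frameshift: int = 20
    n_stop: int = 10
    n_partial: int = 10
    n_overlap_pairs: int = 10
    protein_len: int = 720
    n_groups: int = 14
    divergence: float = 0.1               # substitutions/site, ancestor -> group consensus
    member_divergence: float | None = None  # default: divergence / 2
    n_per_group: int = 150
    seed_rows_per_group: int = 2
    gc: float = 0.36
    intron_len_range: tuple[int, int] = (60, 5000)
    max_introns: int = 3
    partial_len_range: tuple[int, int] = (300, 550)
    #: minimum intergenic distance; kept above the maximum intron length so
    #: that neighbouring family members can never be spliced into a chimera
    min_gene_spacing: int = 24000
    #: pseudocount strength for the family mining profile; small seed
    #: alignments need heavier smoothing than the per-group libraries
    profile_pseudocount: float = 8.0
    rng_seed: int = 0


@dataclass
class FixtureSuite:
    genomes: list[GenomeRecord]
    truths: list[GeneTruth]
    seed_msa: WeightedMSA
    family_profile: ProfileHMM
    group_seqs: list[tuple[str, SeqRecord]]
    rng_seed: int


# ---------------------------------------------------------------------------
# protein family
# ---------------------------------------------------------------------------

def _mutate(protein: str, divergence: float, rng: np.random.Generator,
            preserve_ends: bool = False) -> str:
    """Substitute each site with probability 1 - exp(-divergence) to a
    background-weighted *different* residue (Poisson substitution model).

    With ``preserve_ends`` the first and last residues are never substituted:
    family members then carry anchored termini, which keeps the true gene
    boundaries identifiable (a diverged terminal residue can otherwise make a
    shifted alignment score-optimal, leaving exon-exact recovery ill-defined).
    """
    p_sub = 1.0 - np.exp(-divergence)
    out = list(protein)
    hits = rng.random(len(out)) < p_sub
    if preserve_ends:
        hits[0] = hits[-1] = False
    for i in np.flatnonzero(hits):
        while True:
            a = AA[rng.choice(20, p=BACKGROUND)]
            if a != out[i]:
                out[i] = a
                break
    return "".join(out)


def make_family(rng_seed: int, L: int = 720, n_groups: int = 14,
                divergence: float = 0.1, n_per_group: int = 150,
                member_divergence: float | None = None,
                seed_rows_per_group: int = 2,
                profile_pseudocount: float = 8.0,
                ) -> tuple[ProfileHMM, list[tuple[str, SeqRecord]], WeightedMSA]:
    """Simulate a star phylogeny of group consensus sequences and members.

    Returns (family profile built from the seed alignment, labeled member
    sequences, seed alignment).  The seed alignment takes the first
    ``seed_rows_per_group`` members of each group; with substitution-only
    evolution the true alignment is gap-free and known by construction.
    """
    rng = np.random.default_rng(rng_seed)
    if member_divergence is None:
        member_divergence = divergence / 2.0
    ancestor = "".join(AA[i] for i in rng.choice(20, size=L, p=BACKGROUND))
    labels = [GROUP_ALPHABET[g] for g in range(n_groups)]
    group_seqs: list[tuple[str, SeqRecord]] = []
    seed_rows: list[tuple[str, str]] = []
    for label in labels:
        consensus = _mutate(ancestor, divergence, rng)
        for i in range(n_per_group):
            member = _mutate(consensus, member_divergence, rng, preserve_ends=True)
            rec = SeqRecord(f"{label}{i:03d}", member, molecule="protein")
            group_seqs.append((label, rec))
            if i < seed_rows_per_group:
                seed_rows.append((rec.id, member))
    seed_msa = make_weighted_msa(seed_rows)
    profile = build_profile(seed_msa, pseudocount_strength=profile_pseudocount,
                            name="family_seed")
    return profile, group_seqs, seed_msa


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------

def random_dna(rng: np.random.Generator, length: int, gc: float = 0.36) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join("ACGT"[i] for i in rng.choice(4, size=length, p=p))


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Random synonymous codons; in-frame stops are impossible by construction."""
    return "".join(CODONS_FOR_AA[a][rng.integers(len(CODONS_FOR_AA[a]))] for a in protein)


def _splice_ambiguous(gene: str, d: int, c: int) -> bool:
    """True if the intron [d, c) can shift by +-1..3 nt giving the same CDS."""
    for delta in (-3, -2, -1, 1, 2, 3):
        nd, nc = d + delta, c + delta
        if nd < 0 or nc + 2 > len(gene):
            continue
        if gene[nd:nd + 2] != "GT" or gene[nc - 2:nc] != "AG":
            continue
        if delta > 0 and gene[d:nd] == gene[c:nc]:
            return True
        if delta < 0 and gene[nd:d] == gene[nc:c]:
            return True
    return False


def build_gene_block(protein: str, n_introns: int, intron_lens: list[int],
                     phases: list[int], rng: np.random.Generator,
                     gc: float = 0.36, min_intron: int = 40,
                     max_intron: int = 20000) -> tuple[str, list[tuple[int, int]], list[int]]:
    """Assemble a gene block (CDS + introns) and return (block, exons, phases).

    Exon coordinates are block-local.  Intron interiors are resampled until no
    splice-shift-equivalent boundary exists, so the true exon structure is
    identifiable from the sequence.
    """
    for ln in intron_lens:
        if not (min_intron <= ln <= max_intron):
            raise ValueError(f"intron length {ln} outside [{min_intron}, {max_intron}]")
    if len(intron_lens) != n_introns or len(phases) != n_introns:
        raise ValueError("intron_lens/phases must have n_introns entries")
    cds = reverse_translate(protein, rng)
    if n_introns == 0:
        return cds, [(0, len(cds))], []
    # intron insertion points keep every exon at >= 10 codons (less for very
    # short proteins): a one- or two-codon terminal exon cannot be placed
    # identifiably by any aligner
    min_exon = max(2, min(10, len(protein) // (2 * (n_introns + 1))))
    offsets = None
    for _ in range(200):
        codon_pos = rng.choice(np.arange(min_exon, len(protein) - min_exon),
                               size=n_introns, replace=False)
        cand = sorted(int(3 * cp + ph) for cp, ph in zip(codon_pos, phases))
        if all(b - a >= 3 * min_exon for a, b in zip(cand, cand[1:])):
            offsets = cand
            break
    if offsets is None:
        raise ValueError("protein too short for the requested intron count")
    ordered_phases = [o % 3 for o in offsets]
    parts = []
    exons = []
    cursor = 0
    pos = 0
    for off, ln in zip(offsets, intron_lens):
        parts.append(cds[cursor:off])
        pos += off - cursor
        exons.append(pos)          # intron start in block coordinates
        for _ in range(50):
            intron = "GT" + random_dna(rng, ln - 4, gc) + "AG"
            candidate = "".join(parts) + intron
            if not _splice_ambiguous(candidate + cds[off:], pos, pos + ln):
                break
        parts.append(intron)
        pos += ln
        cursor = off
    parts.append(cds[cursor:])
    block = "".join(parts)
    # block-local exon intervals
    exon_iv = []
    prev = 0
    cum = 0
    for off, ln in zip(offsets, intron_lens):
        start_in_block = prev
        end_in_block = off + cum
        exon_iv.append((start_in_block, end_in_block))
        prev = end_in_block + ln
        cum += ln
    exon_iv.append((prev, len(block)))
    assert translate("".join(block[s:e] for s, e in exon_iv)) == translate(cds)
    return block, exon_iv, ordered_phases


def implant_gene(genome: str, protein: str, n_introns: int,
                 intron_lens: list[int], phases: list[int],
                 rng: np.random.Generator, position: int | None = None,
                 strand: str | None = None, gc: float = 0.36,
                 gene_id: str = "gene", genome_id: str = "genome",
                 contig: str = "chr1", status: str = "intact",
                 group: str = "A") -> tuple[str, GeneTruth]:
    """Embed a multi-exon gene into background DNA; truth records coordinates."""
    block, exon_iv, ordered_phases = build_gene_block(
        protein, n_introns, intron_lens, phases, rng, gc)
    if strand is None:
        strand = "+-"[rng.integers(2)]
    if strand == "-":
        placed = revcomp(block)
    else:
        placed = block
    if position is None:
        position = int(rng.integers(0, len(genome) - len(placed) + 1))
    if position + len(placed) > len(genome):
        raise ValueError("gene block does not fit at requested position")
    new_genome = genome[:position] + placed + genome[position + len(placed):]
    if strand == "+":
        exons = [(position + s, position + e) for s, e in exon_iv]
    else:
        nb = len(block)
        exons = sorted((position + nb - e, position + nb - s) for s, e in exon_iv)
    truth = GeneTruth(gene_id, genome_id, contig, strand, exons,
                      ordered_phases, group, status, protein)
    return new_genome, truth


def _break_gene(genome: str, truth: GeneTruth, kind: str,
                rng: np.random.Generator) -> tuple[str, GeneTruth]:
    """Introduce a frameshift (1-nt insertion) or a codon-aligned premature
    stop into an implanted gene.  Truth coordinates of broken genes are used
    only for locating them and checking flags, not exact boundaries."""
    g = genome
    # genomic positions of the CDS in spliced (translation) order
    pos_list: list[int] = []
    if truth.strand == "+":
        for s, e in truth.exons:
            pos_list.extend(range(s, e))
    else:
        for s, e in reversed(truth.exons):
            pos_list.extend(range(e - 1, s - 1, -1))
    n_codons = len(pos_list) // 3
    k = int(rng.integers(n_codons // 4, 3 * n_codons // 4))
    if kind == "frameshift":
        p = pos_list[3 * k]
        ins = "ACGT"[rng.integers(4)]
        g = g[:p] + ins + g[p:]
        truth.exons = [(s + (1 if s >= p else 0), e + (1 if e > p else 0))
                       for s, e in truth.exons]
        truth.status = "frameshift_pseudogene"
    else:
        stop = ["TAA", "TGA", "TAG"][rng.integers(3)]
        gl = list(g)
        for t in range(3):
            p = pos_list[3 * k + t]
            gl[p] = stop[t] if truth.strand == "+" else stop[t].translate(COMPLEMENT)
        g = "".join(gl)
        truth.status = "stop_pseudogene"
    return g, truth


# ---------------------------------------------------------------------------
# full suite
# ---------------------------------------------------------------------------

def make_genome_suite(cfg: FixtureConfig) -> FixtureSuite:
    """Generate the standard suite: genomes with implanted intact genes,
    frameshift/stop pseudogenes, sub-length partial genes and same-strand
    overlapping decoy pairs, all recorded in the truth table."""
    rng = np.random.default_rng(cfg.rng_seed)
    profile, group_seqs, seed_msa = make_family(
        int(rng.integers(2 ** 31)), L=cfg.protein_len, n_groups=cfg.n_groups,
        divergence=cfg.divergence, n_per_group=cfg.n_per_group,
        member_divergence=cfg.member_divergence,
        seed_rows_per_group=cfg.seed_rows_per_group,
        profile_pseudocount=cfg.profile_pseudocount)
    by_group: dict[str, list[SeqRecord]] = {}
    for label, rec in group_seqs:
        by_group.setdefault(label, []).append(rec)
    labels = sorted(by_group)

    # jobs: (kind, group); overlap pairs take two slots
    jobs = ([("intact", labels[i % len(labels)]) for i in range(cfg.n_intact)]
            + [("frameshift", labels[i % len(labels)]) for i in range(cfg.n_frameshift)]
            + [("stop", labels[i % len(labels)]) for i in range(cfg.n_stop)]
            + [("partial", labels[i % len(labels)]) for i in range(cfg.n_partial)]
            + [("overlap_pair", labels[i % len(labels)]) for i in range(cfg.n_overlap_pairs)])
    per_genome = -(-len(jobs) // cfg.n_genomes)    # ceil

    member_cursor = {label: cfg.seed_rows_per_group for label in labels}

    def next_member(label: str) -> str:
        i = member_cursor[label]
        member_cursor[label] = (i + 1) % len(by_group[label]) or cfg.seed_rows_per_group
        return by_group[label][i].sequence

    genomes = []
    truths: list[GeneTruth] = []
    gi = 0
    job_idx = 0
    imin, imax = cfg.intron_len_range
    for gi in range(cfg.n_genomes):
        genome_id = f"g{gi + 1:02d}"
        g = random_dna(rng, cfg.genome_len, cfg.gc)
        n_here = min(per_genome, len(jobs) - job_idx)
        if n_here > 0:
            slot = cfg.genome_len // n_here
            for k in range(n_here):
                kind, label = jobs[job_idx]
                job_idx += 1
                gene_id = f"{genome_id}_t{k + 1:02d}"
                protein = next_member(label)
                if kind == "partial":
                    plen = int(rng.integers(*cfg.partial_len_range))
                    protein = protein[:plen]
                n_int = int(rng.integers(0, cfg.max_introns + 1))
                lens = [max(imin, int(round(np.exp(rng.uniform(np.log(imin), np.log(imax))))))
                        for _ in range(n_int)]
                phases = [int(rng.integers(3)) for _ in range(n_int)]
                half_gap = cfg.min_gene_spacing // 2
                for _attempt in range(4):
                    approx_len = 3 * len(protein) + sum(lens)
                    if kind == "overlap_pair":
                        approx_len += 3 * cfg.protein_len + 20
                    lo = k * slot + half_gap
                    hi = min((k + 1) * slot, cfg.genome_len) - approx_len - half_gap
                    if hi > lo:
                        break
                    lens = [max(imin, ln // 2) for ln in lens]   # shrink introns to fit
                else:
                    raise ValueError(
                        "genome too small for the configured gene load and spacing")
                pos = int(rng.integers(lo, hi))
                status = {"intact": "intact", "frameshift": "intact",
                          "stop": "intact", "partial": "partial",
                          "overlap_pair": "overlap_decoy"}[kind]
                g, truth = implant_gene(
                    g, protein, n_int, lens, phases, rng, position=pos,
                    gc=cfg.gc, gene_id=gene_id, genome_id=genome_id,
                    status=status, group=label)
                if kind in ("frameshift", "stop"):
                    g, truth = _break_gene(g, truth, kind, rng)
                truths.append(truth)
                if kind == "overlap_pair":
                    # second gene of the pair overwrites the tail of the first
                    protein2 = next_member(label)
                    pos2 = truth.start + (truth.end - truth.start) // 2
                    if pos2 + 3 * len(protein2) + 10 < cfg.genome_len:
                        g, truth2 = implant_gene(
                            g, protein2, 0, [], [], rng, position=pos2,
                            strand=truth.strand, gc=cfg.gc,
                            gene_id=gene_id + "b", genome_id=genome_id,
                            status="overlap_decoy", group=label)
                        truths.append(truth2)
        genomes.append(GenomeRecord(genome_id, f"species_{gi + 1:02d}",
                                    [SeqRecord("chr1", g, molecule="dna")]))
    return FixtureSuite(genomes, truths, seed_msa, profile, group_seqs,
                        cfg.rng_seed)


# ---------------------------------------------------------------------------
# copy matrices with analytically expected blooms
# ---------------------------------------------------------------------------

def make_copy_matrix(rng_seed: int, clades: dict[str, str],
                     bloom_spec: dict[tuple[str, str], float],
                     groups: list[str] | None = None,
                     base_mean: float = 0.5,
                     threshold: float = 4.0) -> tuple[CopyMatrix, list[BloomCall]]:
    """Poisson species x group counts with clade/group means from bloom_spec.

    The expected bloom set is computed analytically from the *realized*
    clade-group means, so it is exact for any draw.
    """
    rng = np.random.default_rng(rng_seed)
    if groups is None:
        groups = sorted({g for _, g in bloom_spec}) or ["A", "B", "C"]
    species = sorted(clades)
    data = np.zeros((len(species), len(groups)), dtype=int)
    for i, sp in enumerate(species):
        for j, gr in enumerate(groups):
            mean = bloom_spec.get((clades[sp], gr), base_mean)
            data[i, j] = rng.poisson(mean)
    df = pd.DataFrame(data, index=species, columns=groups)
    df["unclassified"] = 0
    m = CopyMatrix(df, dict(clades))
    expected = []
    for clade in sorted(set(clades.values())):
        members = [sp for sp in species if clades[sp] == clade]
        for gr in groups:
            mean = df.loc[members, gr].mean()
            if mean >= threshold:
                expected.append(BloomCall(clade, gr, float(mean), len(members)))
    return m, expected
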