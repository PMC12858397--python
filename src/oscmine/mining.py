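"""End-to-end genome mining: seeding, loci, spliced refinement, filters.

The cascade follows the mining protocol exactly: a pass-1 disjunction
(protein length > 40 aa OR profile coverage > 0.3), an AWSI refilter
(>= 0.2), the spliced-score floor plus E-value < 1e-5, overlap resolution to
a unique non-overlapping candidate set, precedence of prior annotations on
overlap, and the high-quality definition (>= 650 aa, non-pseudogene,
bitscore > 500 or full cascade passage).
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from . import _kernels, scoring
from .alphabet import CODON_AA, dna_to_indices
from .config import MiningConfig
from .profiles import ProfileHMM, awsi_from_columns
from .seqio import (GeneModel, GenomeRecord, SeqRecord, revcomp, translate,
                    write_fasta, write_gff3, write_tsv)
from .spliced import spliced_align


@dataclass
class SeedHit:
    contig: str
    strand: str
    frame: int
    start: int            # forward-strand genomic coordinates
    end: int
    bits: float


@dataclass
class Locus:
    contig: str
    strand: str
    start: int
    end: int
    bits: float


@dataclass
class Candidate:
    model: GeneModel
    locus: tuple[str, tuple[int, int], str]
    stage_flags: dict = field(default_factory=dict)


@dataclass
class MiningResult:
    assembly_id: str
    species: str
    candidates: list[Candidate]
    high_quality: list[Candidate]
    log: dict

    def __post_init__(self):
        hq_ids = {c.model.model_id for c in self.high_quality}
        cand_ids = {c.model.model_id for c in self.candidates}
        if not hq_ids <= cand_ids:
            raise ValueError("high_quality must be a subset of candidates")


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

def _frame_indices(base: np.ndarray, frame: int) -> np.ndarray:
    b = base[frame:].astype(np.int64)
    b = b[: 3 * (len(b) // 3)]
    if len(b) == 0:
        return np.zeros(0, dtype=np.int8)
    return CODON_AA[(b[0::3] * 5 + b[1::3]) * 5 + b[2::3]]


def _strand_has_seed(esc: np.ndarray, seq: str, strand: str,
                     cfg: MiningConfig) -> bool:
    """Quick check whether a (masked) locus still carries seed-level signal."""
    base = dna_to_indices(seq if strand == "+" else revcomp(seq))
    for frame in range(3):
        q = _frame_indices(base, frame)
        if len(q) < cfg.seed_window_codons:
            continue
        best = _kernels.seed_scan_kernel(esc, q, cfg.seed_window_codons)
        if best.max() >= cfg.seed_min_bits:
            return True
    return False


def seed_scan(hmm: ProfileHMM, genome: GenomeRecord, cfg: MiningConfig) -> list[SeedHit]:
    """Windowed ungapped six-frame scan against the profile.

    Keeps every translated window whose best diagonal score against the
    profile reaches cfg.seed_min_bits; contiguous qualifying windows are
    merged into one hit carrying the maximum score.
    """
    esc = hmm.emission_scores()
    W = cfg.seed_window_codons
    hits: list[SeedHit] = []
    for contig in genome.contigs:
        n = len(contig.sequence)
        fwd = dna_to_indices(contig.sequence)
        rev = dna_to_indices(revcomp(contig.sequence))
        for strand, base in (("+", fwd), ("-", rev)):
            for frame in range(3):
                q = _frame_indices(base, frame)
                if len(q) < W:
                    continue
                best = _kernels.seed_scan_kernel(esc, q, W)
                above = np.flatnonzero(best >= cfg.seed_min_bits)
                if len(above) == 0:
                    continue
                # merge runs of overlapping windows
                runs = []
                run_start = above[0]
                prev = above[0]
                for p in above[1:]:
                    if p - prev <= W:
                        prev = p
                    else:
                        runs.append((run_start, prev))
                        run_start = p
                        prev = p
                runs.append((run_start, prev))
                for (p0, p1) in runs:
                    score = float(best[p0:p1 + 1].max())
                    lo = frame + 3 * p0
                    hi = frame + 3 * (p1 + W)
                    if strand == "+":
                        g0, g1 = lo, min(hi, n)
                    else:
                        g0, g1 = max(0, n - hi), n - lo
                    hits.append(SeedHit(contig.id, strand, frame, g0, g1, score))
    hits.sort(key=lambda h: (h.contig, h.strand, h.start, h.end))
    return hits


def define_loci(seeds: list[SeedHit], cfg: MiningConfig,
                contig_lengths: dict[str, int]) -> list[Locus]:
    """Chain same-contig same-strand seeds within max_intron into loci.

    The locus spans the chain plus cfg.locus_flank on both sides, clipped to
    the contig; overlapping loci are merged.
    """
    loci: list[Locus] = []
    by_key: dict[tuple[str, str], list[SeedHit]] = {}
    for h in sorted(seeds, key=lambda h: (h.contig, h.strand, h.start, h.end)):
        by_key.setdefault((h.contig, h.strand), []).append(h)
    for (contig, strand), group in sorted(by_key.items()):
        n = contig_lengths[contig]
        chains: list[list[int]] = []   # [start, end, bits]
        for h in group:
            if chains and h.start - chains[-1][1] <= cfg.max_intron:
                chains[-1][1] = max(chains[-1][1], h.end)
                chains[-1][2] = max(chains[-1][2], h.bits)
            else:
                chains.append([h.start, h.end, h.bits])
        for s, e, b in chains:
            loci.append(Locus(contig, strand, max(0, s - cfg.locus_flank),
                              min(n, e + cfg.locus_flank), b))
    # merge overlapping flanked loci on the same contig/strand
    merged: list[Locus] = []
    for loc in sorted(loci, key=lambda l: (l.contig, l.strand, l.start, l.end)):
        if (merged and merged[-1].contig == loc.contig
                and merged[-1].strand == loc.strand
                and loc.start <= merged[-1].end):
            merged[-1].end = max(merged[-1].end, loc.end)
            merged[-1].bits = max(merged[-1].bits, loc.bits)
        else:
            merged.append(loc)
    return merged


# ---------------------------------------------------------------------------
# the filter cascade
# ---------------------------------------------------------------------------

def p2g_filter(c: Candidate, cfg: MiningConfig) -> bool:
    """Pass-1: protein length > 40 aa OR coverage > 0.3 (strict, disjunctive)."""
    m = c.model
    return (len(m.protein) > cfg.min_protein_aa_pass1
            or m.scores.get("coverage", 0.0) > cfg.min_coverage_pass1)


def awsi_refilter(c: Candidate, cfg: MiningConfig) -> bool:
    """Refilter on average weighted sequence identity (inclusive by default).

    Not applicable (passes) when the profile carries no seed alignment.
    """
    a = c.model.scores.get("awsi", 0.0)
    if a != a:   # NaN: no seed alignment available
        return True
    return a > cfg.min_awsi if cfg.awsi_strict else a >= cfg.min_awsi


def score_and_evalue_filter(c: Candidate, cfg: MiningConfig) -> bool:
    """Spliced score above the floor AND E-value strictly below 1e-5."""
    m = c.model
    return (m.scores.get("spliced_score", 0.0) >= cfg.min_spliced_score
            and m.scores.get("evalue", np.inf) < cfg.max_evalue)


def high_quality_filter(c: Candidate, cfg: MiningConfig) -> bool:
    """>= 650 aa, non-pseudogene, and bitscore > 500 or full cascade passage."""
    m = c.model
    if len(m.protein) < cfg.hq_min_len or m.flags.get("pseudogene"):
        return False
    if m.scores.get("bitscore", 0.0) > cfg.hq_min_bitscore:
        return True
    return bool(c.stage_flags.get("passed_all_mining"))


def _exons_overlap(a: GeneModel, b: GeneModel) -> bool:
    for (s1, e1) in a.exons:
        for (s2, e2) in b.exons:
            if s1 < e2 and s2 < e1:
                return True
    return False


def resolve_overlaps(models: list[GeneModel]) -> list[GeneModel]:
    """Reduce to a pairwise non-overlapping set per (contig, strand).

    Within an overlapping cluster the winner has the highest bitscore, then
    the longer protein, then the leftmost start.  Opposite-strand overlaps
    are retained (nested antisense genes are real).
    """
    kept: list[GeneModel] = []
    by_key: dict[tuple[str, str], list[GeneModel]] = {}
    for m in models:
        by_key.setdefault((m.contig, m.strand), []).append(m)
    for key in sorted(by_key):
        group = sorted(by_key[key], key=lambda m: (
            -m.scores.get("bitscore", 0.0), -len(m.protein), m.start, m.model_id))
        chosen: list[GeneModel] = []
        for m in group:
            if not any(_exons_overlap(m, c) for c in chosen):
                chosen.append(m)
        kept.extend(chosen)
    kept.sort(key=lambda m: (m.contig, m.start, m.strand))
    return kept


def merge_with_annotations(mined: list[GeneModel],
                           prior: list[GeneModel]) -> list[GeneModel]:
    """Prior annotations always win overlaps; everything else is kept."""
    out: list[GeneModel] = list(prior)
    for m in mined:
        if not any(p.contig == m.contig and p.strand == m.strand
                   and _exons_overlap(m, p) for p in prior):
            out.append(m)
    out.sort(key=lambda m: (m.contig, m.start, m.strand))
    return out


def select_best_assembly(results: list[MiningResult]) -> str:
    """Per species, the assembly with the most high-quality models wins;
    ties go to more candidates, then to the lexicographically first id."""
    if not results:
        raise ValueError("no results")
    return min(results, key=lambda r: (-len(r.high_quality),
                                       -len(r.candidates), r.assembly_id)).assembly_id


# ---------------------------------------------------------------------------
# end-to-end mining of one assembly
# ---------------------------------------------------------------------------

def _score_model(m: GeneModel, hmm: ProfileHMM, cfg: MiningConfig,
                 db_residues: int) -> None:
    protein = m.protein.replace("*", "X")
    m.scores["bitscore"] = scoring.bitscore(hmm, protein)
    vit = scoring.viterbi(hmm, protein)
    m.scores["evalue"] = scoring.evalue(hmm, vit.score_bits, db_residues)
    if hmm.seed_msa is not None:
        cand_cols = {col - 1: protein[q] for st, col, q in vit.path if st == "M"}
        m.scores["awsi"] = awsi_from_columns(cand_cols, hmm.seed_msa)
    else:
        m.scores["awsi"] = float("nan")


def mine_genome(genome: GenomeRecord, hmm: ProfileHMM, cfg: MiningConfig,
                prior_models: list[GeneModel] | None = None) -> MiningResult:
    """Mine one assembly: seed -> loci -> spliced models -> filter cascade.

    If prior annotations are given, their proteins are scored against the
    profile (HMMER-branch: bitscore cutoff) and they take precedence over
    mined models wherever the two overlap.
    """
    if hmm.calibration is None:
        scoring.calibrate_evalue(hmm, n_decoys=cfg.calibration_decoys,
                                 decoy_len=cfg.calibration_decoy_len,
                                 seed=cfg.rng_seed)
    db_residues = 2 * genome.total_bp   # six translated frames
    seeds = seed_scan(hmm, genome, cfg)
    contig_lengths = {c.id: len(c.sequence) for c in genome.contigs}
    loci = define_loci(seeds, cfg, contig_lengths)

    models: list[GeneModel] = []
    counter = 0
    esc = hmm.emission_scores()
    for loc in loci:
        contig_seq = genome.contig(loc.contig).sequence
        work = contig_seq[loc.start:loc.end]
        for it in range(cfg.max_models_per_locus):
            if it > 0 and not _strand_has_seed(esc, work, loc.strand, cfg):
                break   # masked locus retains no seed-level signal
            counter += 1
            m = spliced_align(hmm, work, cfg, strand=loc.strand,
                              contig=loc.contig, locus_offset=loc.start,
                              model_id=f"{genome.assembly_id}_m{counter:04d}")
            if m is None:
                break
            models.append(m)
            # mask the model's span inside the working locus and re-align
            lo = max(0, m.start - loc.start)
            hi = min(len(work), m.end - loc.start)
            work = work[:lo] + "N" * (hi - lo) + work[hi:]

    for m in models:
        _score_model(m, hmm, cfg, db_residues)

    wrapped = {m.model_id: Candidate(m, (m.contig, (m.start, m.end), m.strand))
               for m in models}
    for c in wrapped.values():
        c.stage_flags["pass1"] = p2g_filter(c, cfg)
        c.stage_flags["awsi"] = c.stage_flags["pass1"] and awsi_refilter(c, cfg)
        c.stage_flags["score_evalue"] = (c.stage_flags["awsi"]
                                         and score_and_evalue_filter(c, cfg))
        c.stage_flags["passed_all_mining"] = c.stage_flags["score_evalue"]

    surviving = [c.model for c in wrapped.values()
                 if c.stage_flags["passed_all_mining"]]
    nonoverlapping = resolve_overlaps(surviving)

    prior_kept: list[GeneModel] = []
    if prior_models:
        for p in prior_models:
            if not p.protein:
                cds = p.spliced_sequence(genome.contig(p.contig).sequence)
                p.protein = translate(cds).rstrip("*") if len(cds) >= 3 else ""
            if not p.protein:
                continue
            _score_model(p, hmm, cfg, db_residues)
            if p.scores["bitscore"] > cfg.hq_min_bitscore:
                prior_kept.append(p)
    merged = merge_with_annotations(nonoverlapping, prior_kept)

    candidates = []
    for m in merged:
        if m.model_id in wrapped:
            candidates.append(wrapped[m.model_id])
        else:
            c = Candidate(m, (m.contig, (m.start, m.end), m.strand))
            c.stage_flags = {"pass1": True, "awsi": True, "score_evalue": True,
                             "passed_all_mining": False, "hmmer_branch": True}
            candidates.append(c)
    hq = [c for c in candidates if high_quality_filter(c, cfg)]
    for c in hq:
        c.stage_flags["high_quality"] = True

    log = {
        "assembly": genome.assembly_id,
        "seeds": len(seeds),
        "loci": len(loci),
        "models": len(models),
        "pass1": sum(1 for c in wrapped.values() if c.stage_flags["pass1"]),
        "awsi_pass": sum(1 for c in wrapped.values() if c.stage_flags["awsi"]),
        "score_evalue_pass": sum(1 for c in wrapped.values()
                                 if c.stage_flags["score_evalue"]),
        "nonoverlapping": len(nonoverlapping),
        "prior_kept": len(prior_kept),
        "candidates": len(candidates),
        "high_quality": len(hq),
        "rng_seed": cfg.rng_seed,
    }
    return MiningResult(genome.assembly_id, genome.species, candidates, hq, log)


# ---------------------------------------------------------------------------
# output serialization
# ---------------------------------------------------------------------------

CANDIDATE_COLUMNS = [
    "model_id", "contig", "strand", "start", "end", "n_exons", "protein_len",
    "spliced_score", "coverage", "awsi", "bitscore", "evalue",
    "frameshift", "internal_stop", "pseudogene", "partial", "source",
    "pass1", "awsi_pass", "score_evalue_pass", "high_quality",
]


def _candidate_row(c: Candidate, hq: bool) -> dict:
    m = c.model
    return {
        "model_id": m.model_id, "contig": m.contig, "strand": m.strand,
        "start": m.start, "end": m.end, "n_exons": len(m.exons),
        "protein_len": len(m.protein),
        "spliced_score": f"{m.scores.get('spliced_score', float('nan')):.4f}",
        "coverage": f"{m.scores.get('coverage', float('nan')):.4f}",
        "awsi": f"{m.scores.get('awsi', float('nan')):.4f}",
        "bitscore": f"{m.scores.get('bitscore', float('nan')):.4f}",
        "evalue": f"{m.scores.get('evalue', float('nan')):.3e}",
        "frameshift": int(m.flags.get("frameshift", False)),
        "internal_stop": int(m.flags.get("internal_stop", False)),
        "pseudogene": int(m.flags.get("pseudogene", False)),
        "partial": int(m.flags.get("partial", False)),
        "source": m.source,
        "pass1": int(c.stage_flags.get("pass1", False)),
        "awsi_pass": int(c.stage_flags.get("awsi", False)),
        "score_evalue_pass": int(c.stage_flags.get("score_evalue", False)),
        "high_quality": int(hq),
    }


def write_outputs(result: MiningResult, outdir) -> None:
    """models.gff3, proteins.faa, candidates.tsv, hq.tsv, stages.log."""
    os.makedirs(outdir, exist_ok=True)
    models = [c.model for c in result.candidates]
    write_gff3(models, os.path.join(outdir, "models.gff3"))
    write_fasta([SeqRecord(m.model_id, m.protein or "X", molecule="protein")
                 for m in models], os.path.join(outdir, "proteins.faa"))
    hq_ids = {c.model.model_id for c in result.high_quality}
    rows = [_candidate_row(c, c.model.model_id in hq_ids) for c in result.candidates]
    write_tsv(rows, CANDIDATE_COLUMNS, os.path.join(outdir, "candidates.tsv"))
    write_tsv([r for r in rows if r["high_quality"]], CANDIDATE_COLUMNS,
              os.path.join(outdir, "hq.tsv"))
    with open(os.path.join(outdir, "stages.log"), "w") as fh:
        for k, v in result.log.items():
            fh.write(f"stage\t{k}\t{v}\n")
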