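"""Subfamily profiling: per-group profile libraries, classification, blooms.

Each subfamily (canonically groups A-N) gets its own profile built from up to
100 representatives; a query protein is assigned to the best-scoring group
profile among those aligning with a span of at least 450 residues, or left
"unclassified".  Species x group copy-number matrices summarise classified
high-quality proteins, and a lineage "bloom" is called for a clade x group
whose mean copy number reaches 4.
"""
from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import scoring
from .config import MiningConfig
from .profiles import (ProfileHMM, build_profile, load_profile, save_profile,
                       select_representatives, simple_msa)
from .seqio import SeqRecord

UNCLASSIFIED = "unclassified"


@dataclass
class GroupLibrary:
    groups: dict[str, ProfileHMM]
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        for label, hmm in self.groups.items():
            if hmm.calibration is None:
                raise ValueError(f"group {label}: profile not calibrated")

    @property
    def labels(self) -> list[str]:
        return sorted(self.groups)


@dataclass
class ClassificationResult:
    query_id: str
    best_group: str                      # label or "unclassified"
    bitscores: dict[str, float]
    best_span_aa: int
    ambiguous: bool


@dataclass
class CopyMatrix:
    counts: pd.DataFrame                 # rows species, columns group labels + "unclassified"
    clade_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("duplicate row/column labels")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")


@dataclass
class BloomCall:
    clade: str
    group: str
    mean_copies: float
    species_n: int


def build_library(labeled_seqs: list[tuple[str, SeqRecord]], cfg: MiningConfig,
                  k_representatives: int = 100, seed: int | None = None) -> GroupLibrary:
    """Build one calibrated profile per group from labeled sequences.

    Per group: up to ``k_representatives`` are chosen by farthest-first
    traversal, aligned with the center-star aligner, and turned into a
    profile; Gumbel calibration uses background decoys.  Deterministic under
    the seed.
    """
    if seed is None:
        seed = cfg.rng_seed
    if not labeled_seqs:
        raise ValueError("no labeled sequences given")
    by_group: dict[str, list[SeqRecord]] = {}
    for label, rec in labeled_seqs:
        by_group.setdefault(label, []).append(rec)
    groups = {}
    provenance = {}
    for label in sorted(by_group):
        seqs = by_group[label]
        if not seqs:
            raise ValueError(f"group {label!r} has no sequences")
        if len(seqs) == 1:
            warnings.warn(f"group {label!r} has a single sequence; profile will be narrow")
        reps = select_representatives(seqs, k=k_representatives, seed=seed)
        msa = simple_msa(reps)
        hmm = build_profile(msa, name=f"group_{label}", group=label)
        scoring.calibrate_evalue(hmm, n_decoys=cfg.calibration_decoys,
                                 decoy_len=cfg.calibration_decoy_len, seed=seed)
        groups[label] = hmm
        provenance[label] = [r.id for r in reps]
    return GroupLibrary(groups, provenance)


def classify(query: SeqRecord | str, lib: GroupLibrary, cfg: MiningConfig,
             query_id: str | None = None) -> ClassificationResult:
    """Assign a protein to its best-matching group profile.

    Groups whose alignment span (query residues in match states) is below
    cfg.profiling_min_span are ineligible; with no eligible group the result
    is "unclassified".  If the top two eligible bitscores are within
    cfg.ambiguity_margin_bits the call is flagged ambiguous (best still
    reported).
    """
    if isinstance(query, SeqRecord):
        seq = query.sequence
        qid = query.id
    else:
        seq = query
        qid = query_id or "query"
    if not seq:
        raise ValueError("empty query")
    bitscores: dict[str, float] = {}
    spans: dict[str, int] = {}
    for label in lib.labels:
        hmm = lib.groups[label]
        aln = scoring.viterbi(hmm, seq, qid)
        spans[label] = aln.span_aa
        bitscores[label] = scoring.forward(hmm, seq)
    eligible = [g for g in lib.labels if spans[g] >= cfg.profiling_min_span]
    if not eligible:
        return ClassificationResult(qid, UNCLASSIFIED, bitscores, 0, False)
    ranked = sorted(eligible, key=lambda g: (-bitscores[g], g))
    best = ranked[0]
    ambiguous = (len(ranked) > 1 and
                 bitscores[best] - bitscores[ranked[1]] < cfg.ambiguity_margin_bits)
    return ClassificationResult(qid, best, bitscores, spans[best], ambiguous)


def profile_matrix(classified: list[tuple[str, ClassificationResult]],
                   group_labels: list[str] | None = None,
                   clade_map: dict[str, str] | None = None) -> CopyMatrix:
    """Tally classified proteins into a species x group count matrix.

    Unclassified proteins land in a reserved "unclassified" column, so row
    sums conserve per-species totals.
    """
    if group_labels is None:
        labels = sorted({r.best_group for _, r in classified} - {UNCLASSIFIED})
    else:
        labels = list(group_labels)
    cols = labels + [UNCLASSIFIED]
    species = sorted({s for s, _ in classified})
    df = pd.DataFrame(0, index=species, columns=cols, dtype=int)
    for sp, res in classified:
        col = res.best_group if res.best_group in labels else UNCLASSIFIED
        df.loc[sp, col] += 1
    return CopyMatrix(df, clade_map or {})


def detect_blooms(m: CopyMatrix, threshold: float = 4.0,
                  include_unclassified: bool = False) -> list[BloomCall]:
    """Clade x group blooms: mean copy number across the clade's species >= threshold."""
    missing = [sp for sp in m.counts.index if sp not in m.clade_map]
    if missing:
        raise ValueError(f"clade_map does not cover species: {missing}")
    cols = [c for c in m.counts.columns
            if include_unclassified or c != UNCLASSIFIED]
    calls = []
    clades = sorted(set(m.clade_map[sp] for sp in m.counts.index))
    for clade in clades:
        members = [sp for sp in m.counts.index if m.clade_map[sp] == clade]
        if not members:
            warnings.warn(f"clade {clade!r} has no species; skipped")
            continue
        sub = m.counts.loc[members, cols]
        means = sub.mean(axis=0)
        for group in cols:
            if means[group] >= threshold:
                calls.append(BloomCall(clade, group, float(means[group]), len(members)))
    return calls


# ---------------------------------------------------------------------------
# library persistence (directory of plain-text profiles)
# ---------------------------------------------------------------------------

def save_library(lib: GroupLibrary, outdir) -> None:
    os.makedirs(outdir, exist_ok=True)
    for label in lib.labels:
        save_profile(lib.groups[label], os.path.join(outdir, f"group_{label}.prof"))
    with open(os.path.join(outdir, "provenance.tsv"), "w") as fh:
        fh.write("group\trepresentative_ids\n")
        for label in lib.labels:
            fh.write(f"{label}\t{','.join(lib.provenance.get(label, []))}\n")


def load_library(indir) -> GroupLibrary:
    groups = {}
    provenance = {}
    for fn in sorted(os.listdir(indir)):
        if fn.startswith("group_") and fn.endswith(".prof"):
            hmm = load_profile(os.path.join(indir, fn))
            label = hmm.group or fn[len("group_"):-len(".prof")]
            groups[label] = hmm
    prov_path = os.path.join(indir, "provenance.tsv")
    if os.path.exists(prov_path):
        with open(prov_path) as fh:
            next(fh)
            for line in fh:
                label, ids = (line.rstrip("\n").split("\t") + [""])[:2]
                provenance[label] = [x for x in ids.split(",") if x]
    if not groups:
        raise ValueError(f"{indir}: no profile files found")
    return GroupLibrary(groups, provenance)
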