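import numpy as np
import pytest

from oscmine import scoring
from oscmine.config import MiningConfig
from oscmine.fixtures import random_dna, reverse_translate
from oscmine.mining import (Candidate, SeedHit, awsi_refilter, define_loci,
                            high_quality_filter, merge_with_annotations,
                            mine_genome, p2g_filter, resolve_overlaps,
                            score_and_evalue_filter, seed_scan,
                            select_best_assembly, write_outputs, MiningResult)
from oscmine.profiles import build_profile, make_weighted_msa
from oscmine.seqio import GeneModel, GenomeRecord, SeqRecord, revcomp


@pytest.fixture(scope="module")
def family(rng):
    from conftest import random_protein
    prot = random_protein(np.random.default_rng(55), 200)
    rows = [("a", prot), ("b", prot[:90] + "W" + prot[91:]), ("c", prot)]
    hmm = build_profile(make_weighted_msa(rows), name="fam")
    scoring.calibrate_evalue(hmm, n_decoys=100, decoy_len=200, seed=55)
    return hmm


def _cand(protein_len=700, coverage=1.0, awsi=0.5, spliced=400.0, bitscore=600.0,
          evalue=1e-9, pseudo=False, passed_all=True):
    m = GeneModel("m", "c", "+", [(0, 3 * protein_len)], protein="A" * protein_len)
    m.flags["pseudogene"] = pseudo
    m.scores = {"coverage": coverage, "awsi": awsi, "spliced_score": spliced,
                "bitscore": bitscore, "evalue": evalue}
    c = Candidate(m, ("c", (0, 3 * protein_len), "+"))
    c.stage_flags["passed_all_mining"] = passed_all
    return c


class TestFilterBoundaries:
    cfg = MiningConfig()

    @pytest.mark.parametrize("length,cov,expected", [
        (41, 0.10, True),    # length alone passes (strict >)
        (40, 0.30, False),   # both at boundary fail (strict inequalities)
        (10, 0.31, True),    # coverage alone passes (disjunction)
        (41, 0.31, True),
        (40, 0.31, True),
    ])
    def test_pass1_disjunction(self, length, cov, expected):
        assert p2g_filter(_cand(protein_len=length, coverage=cov), self.cfg) is expected

    @pytest.mark.parametrize("awsi,expected", [
        (0.20, True), (0.19, False), (1.0, True),
    ])
    def test_awsi_inclusive_boundary(self, awsi, expected):
        assert awsi_refilter(_cand(awsi=awsi), self.cfg) is expected

    def test_awsi_strict_mode(self):
        cfg = MiningConfig(awsi_strict=True)
        assert not awsi_refilter(_cand(awsi=0.20), cfg)
        assert awsi_refilter(_cand(awsi=0.21), cfg)

    @pytest.mark.parametrize("score,evalue,expected", [
        (400.0, 1e-4, False),   # evalue fails regardless of score
        (400.0, 1e-6, True),
        (50.0, 1e-9, False),    # below score floor
        (100.0, 1e-5, False),   # evalue boundary is strict
    ])
    def test_score_and_evalue(self, score, evalue, expected):
        assert score_and_evalue_filter(
            _cand(spliced=score, evalue=evalue), self.cfg) is expected

    def test_score_floor_monotone(self):
        cands = [_cand(spliced=s) for s in (50, 150, 250, 350)]
        passes = []
        for floor in (100, 200, 300):
            cfg = MiningConfig(min_spliced_score=floor)
            passes.append({i for i, c in enumerate(cands)
                           if score_and_evalue_filter(c, cfg)})
        assert passes[0] >= passes[1] >= passes[2]

    @pytest.mark.parametrize("length,bits,pseudo,passed,expected", [
        (650, 501.0, False, False, True),    # length floor inclusive, bits > 500
        (649, 900.0, False, True, False),    # below length floor
        (700, 600.0, True, True, False),     # pseudogene excluded
        (700, 500.0, False, True, True),     # bitscore at boundary fails ( > ),
                                             # but full cascade passage rescues
        (700, 500.0, False, False, False),
    ])
    def test_high_quality(self, length, bits, pseudo, passed, expected):
        c = _cand(protein_len=length, bitscore=bits, pseudo=pseudo,
                  passed_all=passed)
        assert high_quality_filter(c, self.cfg) is expected


class TestSeedScan:
    def test_implanted_orf_found_on_plus(self, family, rng):
        cfg = MiningConfig()
        cds = reverse_translate(family.consensus(), rng)
        g = random_dna(rng, 20_000) + cds + random_dna(rng, 20_000)
        genome = GenomeRecord("a1", "sp", [SeqRecord("c1", g)])
        hits = seed_scan(family, genome, cfg)
        assert any(h.strand == "+" and h.start < 20_000 + len(cds)
                   and h.end > 20_000 for h in hits)

    def test_implanted_orf_minus_strand_mirrored(self, family, rng):
        cfg = MiningConfig()
        cds = reverse_translate(family.consensus(), rng)
        g = random_dna(rng, 20_000) + revcomp(cds) + random_dna(rng, 20_000)
        genome = GenomeRecord("a1", "sp", [SeqRecord("c1", g)])
        hits = seed_scan(family, genome, cfg)
        matching = [h for h in hits if h.strand == "-"
                    and h.start < 20_000 + len(cds) and h.end > 20_000]
        assert matching

    def test_random_genomes_mostly_seedless(self, family, rng):
        cfg = MiningConfig()
        clean = 0
        for _ in range(20):
            genome = GenomeRecord("a", "sp", [SeqRecord("c1", random_dna(rng, 100_000))])
            if not seed_scan(family, genome, cfg):
                clean += 1
        assert clean >= 19


class TestDefineLoci:
    cfg = MiningConfig(locus_flank=1000)

    def _mk(self, start, end, strand="+"):
        return SeedHit("c1", strand, 0, start, end, 30.0)

    def test_chain_within_max_intron(self):
        loci = define_loci([self._mk(10_000, 10_100), self._mk(15_000, 15_100)],
                           self.cfg, {"c1": 10_000_000})
        assert len(loci) == 1

    def test_split_beyond_max_intron(self):
        loci = define_loci([self._mk(10_000, 10_100), self._mk(35_200, 35_300)],
                           self.cfg, {"c1": 10_000_000})
        assert len(loci) == 2

    def test_chaining_matches_union_find_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 15))
            starts = np.sort(rng.integers(0, 500_000, size=n))
            seeds = [self._mk(int(s), int(s) + 90) for s in starts]
            loci = define_loci(seeds, self.cfg, {"c1": 10_000_000})
            # oracle: transitive closure of the 'within max_intron' relation
            parent = list(range(n))

            def find(x):
                while parent[x] != x:
                    x = parent[x]
                return x

            for i in range(n):
                for j in range(i + 1, n):
                    gap = seeds[j].start - seeds[i].end
                    if gap <= self.cfg.max_intron:
                        parent[find(j)] = find(i)
            assert len(loci) <= len({find(i) for i in range(n)})
            # loci count can shrink further only via flank-overlap merging
            spans = [(l.start, l.end) for l in loci]
            assert all(b[0] > a[1] for a, b in zip(spans, spans[1:]))


class TestResolveOverlaps:
    def _model(self, mid, start, end, strand="+", bits=500.0, plen=100):
        m = GeneModel(mid, "c1", strand, [(start, end)], protein="A" * plen)
        m.scores["bitscore"] = bits
        return m

    def test_disjoint_kept(self):
        out = resolve_overlaps([self._model("a", 0, 100), self._model("b", 200, 300)])
        assert len(out) == 2

    def test_one_bp_overlap_keeps_higher_bitscore(self):
        a = self._model("a", 0, 101, bits=600)
        b = self._model("b", 100, 200, bits=550)
        out = resolve_overlaps([a, b])
        assert [m.model_id for m in out] == ["a"]

    def test_tie_breaks_longer_protein_then_leftmost(self):
        a = self._model("a", 0, 101, bits=500, plen=90)
        b = self._model("b", 100, 200, bits=500, plen=100)
        assert [m.model_id for m in resolve_overlaps([a, b])] == ["b"]
        c = self._model("c", 0, 101, bits=500, plen=100)
        d = self._model("d", 100, 200, bits=500, plen=100)
        assert [m.model_id for m in resolve_overlaps([c, d])] == ["c"]

    def test_opposite_strand_overlap_retained(self):
        a = self._model("a", 0, 150, strand="+")
        b = self._model("b", 100, 250, strand="-")
        assert len(resolve_overlaps([a, b])) == 2

    def test_output_pairwise_nonoverlapping(self, rng):
        models = [self._model(f"m{i}", int(s), int(s) + 120,
                              bits=float(rng.integers(100, 900)))
                  for i, s in enumerate(rng.integers(0, 2000, size=12))]
        out = resolve_overlaps(models)
        for i, a in enumerate(out):
            for b in out[i + 1:]:
                if a.strand == b.strand:
                    assert a.end <= b.start or b.end <= a.start

    def test_intron_only_overlap_is_not_exon_overlap(self):
        # one gene nested inside another's intron, same strand: both kept
        outer = GeneModel("o", "c1", "+", [(0, 100), (5000, 5100)], protein="A" * 66)
        inner = GeneModel("i", "c1", "+", [(1000, 2000)], protein="A" * 300)
        outer.scores["bitscore"] = inner.scores["bitscore"] = 500.0
        assert len(resolve_overlaps([outer, inner])) == 2


class TestMergeWithAnnotations:
    def _model(self, mid, start, end, source="mined"):
        return GeneModel(mid, "c1", "+", [(start, end)], protein="A" * 50,
                         source=source)

    def test_prior_wins_overlap(self):
        mined = [self._model("m", 0, 100)]
        prior = [self._model("p", 50, 150, source="prior_annotation")]
        out = merge_with_annotations(mined, prior)
        assert [m.model_id for m in out] == ["p"]

    def test_nonoverlapping_mined_kept(self):
        mined = [self._model("m", 1000, 1100)]
        prior = [self._model("p", 0, 100, source="prior_annotation")]
        assert {m.model_id for m in merge_with_annotations(mined, prior)} == {"m", "p"}

    def test_merge_empty_mined_is_prior(self):
        prior = [self._model("p", 0, 100, source="prior_annotation")]
        assert merge_with_annotations([], prior) == prior


class TestSelectBestAssembly:
    def _result(self, aid, n_hq, n_cand):
        cands = []
        for i in range(n_cand):
            m = GeneModel(f"{aid}_{i}", "c", "+", [(i * 1000, i * 1000 + 90)],
                          protein="A" * 30)
            cands.append(Candidate(m, ("c", (0, 1), "+")))
        return MiningResult(aid, "sp", cands, cands[:n_hq], {})

    def test_argmax_hq(self):
        assert select_best_assembly([self._result("a1", 5, 9),
                                     self._result("a2", 7, 8)]) == "a2"

    def test_tie_more_candidates(self):
        assert select_best_assembly([self._result("a1", 5, 9),
                                     self._result("a2", 5, 11)]) == "a2"

    def test_single_assembly(self):
        assert select_best_assembly([self._result("a1", 0, 0)]) == "a1"


class TestMineGenome:
    @pytest.fixture(scope="class")
    def mined_fixture(self):
        """Genome with 3 intact genes, 1 frameshift pseudogene, 2 decoy loci."""
        from oscmine.fixtures import implant_gene, make_family
        rng = np.random.default_rng(202)
        profile, group_seqs, seed_msa = make_family(
            202, L=300, n_groups=3, n_per_group=4, divergence=0.1)
        g = random_dna(rng, 220_000)
        truths = []
        members = [rec.sequence for _, rec in group_seqs[:4]]
        for k, prot in enumerate(members[:3]):
            g, t = implant_gene(g, prot, 1, [300], [0], rng,
                                position=30_000 + 55_000 * k, strand="+",
                                gene_id=f"t{k}")
            truths.append(t)
        # frameshift pseudogene
        g, t = implant_gene(g, members[3], 0, [], [], rng,
                            position=195_000, strand="+", gene_id="fs")
        g = g[:195_300] + "G" + g[195_300:]
        truths.append(t)
        genome = GenomeRecord("asm1", "sp1", [SeqRecord("chr1", g)])
        cfg = MiningConfig(rng_seed=202, locus_flank=3000, hq_min_len=250,
                           calibration_decoys=80, calibration_decoy_len=300)
        scoring.calibrate_evalue(profile, 80, 300, seed=202)
        return mine_genome(genome, profile, cfg), truths, cfg

    def test_counts_and_pseudogene_handling(self, mined_fixture):
        res, truths, cfg = mined_fixture
        assert len(res.candidates) == 4
        assert len(res.high_quality) == 3
        pseudo = [c for c in res.candidates if c.model.flags["pseudogene"]]
        assert len(pseudo) == 1
        assert pseudo[0].model.model_id not in {c.model.model_id
                                                for c in res.high_quality}

    def test_stage_counts_non_increasing(self, mined_fixture):
        res, _, _ = mined_fixture
        log = res.log
        assert log["models"] >= log["pass1"] >= log["awsi_pass"] >= \
            log["score_evalue_pass"] >= log["nonoverlapping"]

    def test_empty_genome_empty_result(self, family):
        cfg = MiningConfig(rng_seed=1)
        genome = GenomeRecord("e1", "sp", [SeqRecord("c1", "ACGT" * 2000)])
        res = mine_genome(genome, family, cfg)
        assert res.candidates == [] and res.high_quality == []

    def test_outputs_deterministic(self, mined_fixture, tmp_path):
        res, _, _ = mined_fixture
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        write_outputs(res, d1)
        write_outputs(res, d2)
        for name in ("models.gff3", "proteins.faa", "candidates.tsv", "hq.tsv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()


class TestPriorAnnotations:
    def test_hmmer_branch_prior_replaces_mined(self, rng):
        from oscmine.fixtures import implant_gene, make_family
        profile, group_seqs, _ = make_family(31, L=300, n_groups=2, n_per_group=3)
        rng2 = np.random.default_rng(31)
        g = random_dna(rng2, 60_000)
        prot = group_seqs[0][1].sequence
        g, t = implant_gene(g, prot, 0, [], [], rng2, position=25_000, strand="+",
                            gene_id="t0")
        genome = GenomeRecord("asm", "sp", [SeqRecord("chr1", g)])
        prior = [GeneModel("prior_1", "chr1", "+", t.exons, protein=prot,
                           source="prior_annotation")]
        cfg = MiningConfig(rng_seed=31, locus_flank=3000, hq_min_len=250,
                           calibration_decoys=80, calibration_decoy_len=300)
        scoring.calibrate_evalue(profile, 80, 300, seed=31)
        res = mine_genome(genome, profile, cfg, prior_models=prior)
        ids = [c.model.model_id for c in res.candidates]
        assert "prior_1" in ids
        assert all(c.model.source == "prior_annotation" for c in res.candidates
                   if c.model.model_id == "prior_1")
        assert len([i for i in ids if i != "prior_1"]) == 0   # mined overlap dropped
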