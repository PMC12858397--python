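# Methods

## Scope and model

`oscmine` implements a targeted gene-family mining and subfamily-profiling
workflow, developed around plant oxidosqualene cyclases (OSCs) but generic
over any protein family. The moving parts are:

1. a **profile HMM** estimated from a weighted seed alignment of
   characterised family proteins;
2. a **six-frame translated seed scan** that nominates candidate loci in
   unannotated genome assemblies;
3. a **spliced profile-to-genome dynamic program** that turns each locus into
   a gene model with exon coordinates and pseudogene flags;
4. the **filter cascade** that defines candidate and high-quality (HQ) sets;
5. **subfamily profiling**: per-group profile libraries, best-profile
   classification, species × group copy matrices and clade-level
   copy-number "blooms".

## Profile construction

Rows of the seed alignment carry Henikoff position-based weights (gap cells
contribute nothing; all-gap columns are skipped; weights normalised to sum to
the row count). Match columns are those with weighted gap fraction < 50%.
Match emissions are weighted counts with background-proportional pseudocounts
(`(c_a + pc·bg_a)/(Σc + pc)`); transitions come from weighted gap patterns
with Laplace (+1) pseudocounts. `pc = 1` is the default; the synthetic
family's *mining* profile is built with `pc = 8`, because a small seed
alignment (tens of rows) otherwise scores any unrepresented residue at
≈ log2(pc/(n+pc)) ≈ −5 bits, which lets long delete runs and alignment
shopping outscore the true gene placement. Heavier smoothing for small
alignments plays the role HMMER's entropy weighting plays in practice. The
amino-acid background is the Robinson–Robinson frequency set.

## Scoring

Protein–profile alignment is **local** with uniform wing entry/exit
(probability 1/L each); scores are log2-odds ("bits") against the background
residue model and the empty alignment scores 0. `bitscore` is the forward
(all-paths) score, matching the HMMER-style cutoff semantics of the
HQ filter; Viterbi supplies the alignment path, span (query residues in
match states) and coverage. E-values come from a maximum-likelihood Gumbel
fit to Viterbi scores of i.i.d. background decoys (raw, un-floored scores;
200 decoys of 720 aa by default) and scale exactly linearly with database
size: `E = (db_residues/decoy_len)·P(S ≥ s)`. The simplified null model has
no length correction, so a background-identical profile has a forward score
of a few bits (bounded by start/stop multiplicity) rather than exactly 0;
Viterbi is exactly 0 there.

## Spliced alignment

The genome aligner is a codon-level dynamic program over
(genomic position × profile column × state). Match/insert states consume
three nucleotides; introns use the *flat* GT/AG splice model — mandatory
GT…AG, a constant −8-bit opening penalty, no positional information — and
may fall between codons (phase 0) or split a codon after one or two bases
(phases 1/2; split codons are scored exactly by tracking donor-side bases in
the running donor maxima). Frameshift emissions consume 1/2/4 nt at −15 bits
and emit X; a stop codon is read through as X at −20 bits. A model is flagged
`pseudogene` iff a frameshift or internal stop was used, mirroring the
"frameshifts or indels required" rule of homology-based pseudogene flagging.

The alignment is **glocal**: local in the genome, global over profile
columns (begin acts as a match at column 0, the path must reach column L in
M or D). This matches what protein-to-genome aligners such as GeneWise and
Selenoprofiles do and is what anchors exon boundaries when terminal residues
mismatch — a purely local spliced alignment trims diverged terminal codons
and cannot deliver exon-exact recovery. Under a glocal span "M or D columns
over L" is identically 1, so **coverage is reported as matched columns / L**
(delete runs at the ends of partial genes lower it, as intended by a
coverage filter).

Complexity is O(|locus| · L) via running donor maxima (one per phase-0
state, four per phase-1 donor base, sixteen per phase-2 donor pair). The
running maximum enforces only the *minimum* intron length; the 20-kb maximum
is validated on the traceback, and a violating "intron" — in practice a
chimera of two loci — splits the locus at that point, each half re-aligned.
No emitted model ever contains an intron outside [min_intron, max_intron]
(asserted). Ties in the DP resolve deterministically by candidate order.

## Seeding and loci

The seed scan computes, for every 30-codon window in all six reading frames,
the best ungapped diagonal sum against the profile and keeps windows at
≥ 20 bits. Chance windows against a ~700-column profile reach 13–16 bits, so
the threshold sits above that tail; true exon windows score ≈ 40–95 bits
even at divergence 0.2. This matters because same-contig, same-strand seeds
within the maximum intron length are chained into one locus (span ± flank,
default 20 kb, clipped to the contig): a chance window midway between two
family members would otherwise merge their loci and invite a legitimate but
unwanted spliced chimera. Within a locus, models are extracted iteratively —
align, mask the model's span, re-align — until no seed-level signal remains
or the score floor is reached.

## The filter cascade

With boundary semantics made explicit:

| stage | rule |
|---|---|
| pass 1 | protein length > 40 aa **or** coverage > 0.3 (both strict) |
| refilter | AWSI ≥ 0.2 (inclusive; a strict mode is a config switch) |
| score/E-value | spliced score ≥ floor **and** E-value < 1e-5 (strict) |
| overlap | per (contig, strand), ≥1 bp exon overlap; keep highest bitscore, then longer protein, then leftmost |
| prior annotations | always win overlaps (HMMER branch: prior proteins kept at bitscore > 500) |
| high quality | length ≥ 650 aa, non-pseudogene, and (bitscore > 500 **or** full cascade passage) |

AWSI (average weighted sequence identity) is Σᵢ wᵢ·pidᵢ / Σᵢ wᵢ over seed
rows, pidᵢ the fractional identity over profile match columns where both the
candidate (via its Viterbi path) and row i are non-gap; rows with no overlap
contribute 0. The exact formula used inside Selenoprofiles is not public;
this definition preserves the threshold's role and is documented as our own.
Exonerate's raw score threshold of 300 lives on a tool-internal scale; it
maps to a configurable spliced-score floor (default 100 bits);
models between the 20-bit report floor and the score floor appear as
candidates that fail the score filter. Whether "coverage" is computed before
or after spliced refinement is unstated in the protocol; it is computed
post-refinement here. Per species, the assembly with the most HQ models is
selected (ties: more candidates, then lexicographically first id).

## Profiling, matrices, blooms

Per group, up to 100 representatives are chosen by deterministic
farthest-first traversal on edit-distance identity (starting from the
medoid, ties lexicographic by id), aligned with a center-star progressive
aligner (global pairwise BLOSUM62, gap open −11 / extend −1), built into a
profile and calibrated. A query is assigned to the best-bitscore group among
profiles whose alignment span is ≥ 450 query residues (the span rule is
applied per profile; "aa" is read as query residues); no eligible profile →
"unclassified"; a top-two margin under 1 bit flags the call ambiguous but
still reports the best label. Copy matrices count classified HQ proteins per
species × group with a reserved "unclassified" column so row sums conserve
totals. A bloom is any (clade, group) whose mean copy number across the
clade's species is ≥ 4 (inclusive).

## Synthetic data generator

`fixtures.make_family` simulates a star phylogeny: an ancestor drawn from the
background, group consensuses at a given divergence (substitutions/site,
Poisson model, background-weighted replacement), members at half that
divergence around their consensus. Substitution-only evolution means the
true alignment is gap-free and known. Member termini are never substituted:
anchored first/last residues keep the true gene boundaries identifiable
(otherwise a diverged terminal residue can make a shifted alignment
score-optimal and "exon-exact" loses its meaning). Genes are implanted into
i.i.d. background DNA at 36% GC (plant-like) as randomised synonymous
codons with GT…AG introns (log-uniform lengths, 60–5000 nt by default, all
three phases); intron interiors are resampled if a ±1–3 nt splice shift
would give an identical CDS with valid GT/AG, again for identifiability.
Pseudogenes are made by a single-nucleotide insertion or a codon-aligned
nonsense substitution; partial genes are truncated below the 650-aa HQ
floor; overlap-decoy pairs overwrite a gene's tail with a second gene on the
same strand to exercise overlap resolution. Intergenic spacing is kept above
the maximum intron length (24 kb margin) so that two implanted genes can
never be joined by a legal intron — real tandem arrays violate this, which
is precisely why real-data mining reports candidate overlaps for review.

What the generator does **not** emulate: repeats and transposons, GC
heterogeneity and isochores, non-canonical splice sites, alternative
isoforms, polyploid subgenomes, assembly gaps and errors. Passing the suite
therefore demonstrates the correctness of the algorithms under the stated
gene model, not robustness to every feature of real plant genomes.

## Problem sizes

Test and acceptance runs use desk-scale versions of the study conditions,
chosen so the whole suite runs on one CPU in minutes: the mining suite is
60 intact genes (plus 8 frameshift, 4 stop, 4 partial, 4 overlap pairs)
across 12 × 300-kb genomes at divergence 0.2 with a 6-kb locus flank
(suite introns are ≤ 5 kb, so the flank still covers any unseeded terminal
exon); background specificity uses 12 × 300-kb gene-free genomes; the
classification library is 14 groups × 100 representatives with 500 held-out
members at divergence 0.1; `scripts/acceptance.py` uses the same shapes
slightly reduced. Recovery and accuracy targets (≥95% exon-exact, all
pseudogenes flagged, zero background HQ calls, ≥95% classification accuracy)
are independent of these sizes.

## Numerical choices and edge cases

All scores are float64; score/traceback agreement is asserted to 1e-6.
Emission of X (and of codons containing N) is 0 bits. Probabilities in the
forward pass are rescaled per query position to avoid under/overflow. A locus
of only Ns yields no model. Profiles serialise to a versioned plain-text
format (`repr` of Python floats), so save/load round-trips are bit-exact and
profile files diff cleanly. All randomness flows from explicit seeds
(`MiningConfig.rng_seed`, generator seeds); reruns with one seed are
byte-identical up to manifest timestamps.

## Known limitations

* The E-value null is a single Gumbel fit per profile without composition
  or length corrections; it is honest for ranking and thresholding at 1e-5
  on the synthetic conditions but is not a replacement for HMMER's
  calibrated statistics on real proteomes.
* Insert states inside the spliced aligner do not themselves accept introns
  (introns attach to match codons and codon boundaries); GC–AG and AT–AC
  introns are out of scope.
* The center-star aligner is adequate for building group profiles from
  closely related representatives; it is not a general MSA tool.
* Chimeric models remain possible on real data when paralogs sit closer
  than the maximum intron length; they surface as overlap-resolution
  decisions in the candidate table rather than being silently dropped.
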