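# Methods

## The screening model

`qsweep` treats QS-gene discovery as a deterministic annotation problem over
predicted proteomes. No statistical model is fitted; every verdict is a pure
function of the inputs and the documented parameters, so a run is exactly
reproducible.

**Genome QC.** Genomes enter the screen only when completeness ≥ 80% and
contamination ≤ 10%. Both boundaries are inclusive — a genome at exactly
(80, 10) is kept — matching the ≥/≤ convention of CheckM-based studies. The
filter is idempotent and order-preserving. Deduplication of genomes drawn
from multiple archives is out of scope: callers supply an explicit id drop
list if needed, since no general-purpose duplicate criterion is defensible
from a quality table alone.

**Name matching.** Keyword matching is case-insensitive and whole-word,
where "word" boundaries are any non-alphanumeric character — so hyphens and
underscores separate tokens ("protein luxs-related" matches the LuxS
keyword) but embedded occurrences do not ("luxSR-like" does not). One call
is emitted per (protein, matching catalog entry); a protein may be called in
several families. The shipped catalog covers all 15 families and is plain
YAML so a curated keyword table can replace it verbatim.

**Profile-HMM search.** `hmm_scan` wraps pyhmmer's hmmsearch pipeline. The
threshold policy uses a model's gathering cutoff whenever the profile
carries one (curated Pfam models do) and otherwise requires a per-domain
independent E-value ≤ 1e-5 — a conventional conservative default, exposed as
a parameter since no universal cutoff exists. Envelope coordinates are
reported 1-based inclusive, and hits are sorted by (protein, start) for
stable downstream processing. PF13407 matches are split LuxP vs LsrB by
product-name evidence: LuxP only on an explicit LuxP keyword, LsrB
otherwise, reflecting that LuxP is essentially confined to *Vibrio* and that
name evidence is the only signal separating the two homologous periplasmic
binding proteins at the profile level.

## The CahR five-residue screen

A dCache_1 domain is a CahR-type AI-2 receptor iff the residues at reference
positions 126, 128, 144, 146 and 173 are exactly R, W, Y, D and D. Position
numbering is 1-based within the configured reference sequence (PctA-LBD
coordinates); the screen is agnostic to whether the user supplies an LBD
fragment or a full-length receptor as reference, provided the conserved
positions index the required residues in it (this is validated at
construction).

**Mapping.** Candidates are mapped onto the reference by global pairwise
alignment: BLOSUM62 substitution scores, affine gaps costing
`10 + L` for a gap of length `L` (open 10, extend 1 per residue, end gaps
penalised). Ties are broken deterministically in the traceback — a
substitution column is preferred over a gap column, and a gap in the
candidate over a gap in the reference — so the mapping is a pure function of
the sequences. The aligner is an in-package Gotoh three-state dynamic
program; tests verify its optimality against Biopython's `PairwiseAligner`
under identical scoring on hundreds of random candidates, keeping
implementation and oracle independent. An anchor-based mapping from an
external HMM alignment can be substituted by constructing the residue-state
map directly and calling `screen_five_residues` on it.

**Decision rule.** A position maps to "unmapped" when the reference column
aligns to a gap or the candidate residue is the ambiguity code X; a
candidate shorter than 30 residues is auto-failed without alignment
(fragments that short cannot span the binding pocket). Matching is exact —
no conservative substitutions — because the screen is defined by full
conservation of the five pocket residues. Each dCache_1 domain of a
multi-domain protein is screened independently; a protein is a CahR receptor
when at least one domain passes, so domain counts and protein counts are
reported separately.

**Functional typing.** The host protein's class is the first, in precedence
order MCP > HK > GCD > SP > STK > AC/GC, whose Pfam marker set intersects
the protein's domain architecture, else HP. MCP is first because the
chemoreceptor signalling domain is an unambiguous class marker; hybrid
architectures (e.g. HK + GGDEF) keep their full architecture string in the
call so alternative labelings can be re-derived.

**Conservation profiles.** Passing domains are re-anchored to the reference;
columns gapped in the reference (candidate insertions) are discarded and
per-column amino-acid frequencies are normalised over the sequences
contributing a residue there. At the five screened positions the required
residue has frequency 1.0 by construction of the passing set — a forced
invariant the tests assert. The exported reference-anchored multiple
alignment (pairwise alignments merged on reference coordinates) is intended
for external tree and logo software, not as a likelihood-grade MSA.

## Expression

RPKM = count × 10⁹ / (library size × gene length in bp). "Expressed"
defaults to the weakest defensible rule — raw count > 0 in at least one
sample — with an optional minimum-RPKM override, because detection
thresholds are study-specific. A genome expresses a family when any of its
genes in that family is expressed. Aggregation order for taxon means is
fixed and documented: mean over samples within a gene, then over genes
within the (taxon, family) group.

## Prevalence, partition, network

Percentages are rounded half-up (767/981 → 78.19), matching how such tables
are conventionally printed; `prevalence(n, n) = 100.00` and monotonicity in
the numerator are property-tested. The AI-2 role partition is exhaustive and
exclusive by construction: synthase-only, receptor-only (broken down into
LsrB-only / CahR-only / both, with LuxP counted on the LsrB side) and both;
the three sets always sum to the AI-2-positive total. The output counts
genomes and labels the column "genomes", since "species" and "genome" are
used interchangeably in collection-level screens.

The network stores species, the AI-2 signal and pathway classes as typed
nodes with typed, coloured edges (produce/green, sense/blue,
produce-and-sense/purple). Storage is undirected — the directionality in
diagrams is presentational. Pathway-class nodes are materialised by default
(one blue edge per distinct class per species, plus one signal→class edge
per class present); `collapse_classes=True` reproduces the simpler
species–signal topology. Exports: GraphML (round-trip exact), SIF (one line
per edge) and edge-list CSV.

## The synthetic community generator

The generator emulates the inputs of a collection-scale screen: per-genome
protein FASTA + GFF3 with product names, a quality/taxonomy table drawn from
a pool of realistic rumen lineages, profile HMMs, and count matrices. Role
fractions default to 357:122:201 of 981 (producer : sensor : both, remainder
AI-2-negative), the partition observed in the study system the package was
built around; 10% of genomes get sub-threshold quality metrics, half of the
genomes carry a decoy, and 15% of receptor genomes carry the periplasmic
LsrB receptor.

Planted receptors are copies of the reference scaffold mutated at 3–12% of
sites *outside* the five conserved positions; decoys additionally differ at
exactly one conserved position, so the screen's decision boundary is
precisely the thing under test. Co-domains (MCPsignal, HisKA + HATPase_c,
GGDEF, SpoIIE, Pkinase, guanylate_cyc) are appended according to a class mix
dominated by MCPs (50%) and HKs (35%). Background proteins are
background-composition random sequences named "hypothetical protein".

The reference scaffold is synthetic: a fixed 250-residue
background-composition sequence with R/W/Y/D/D planted at
126/128/144/146/173, and with the immediate flanks of each conserved
position kept distinct from the required residue so that a single-residue
indel cannot yield a score-tied alignment that still satisfies the screen.
Real-data runs replace it with the actual PctA-LBD sequence via config. The
profile HMMs are likewise synthetic, built at run time with pyhmmer from
12-sequence consensus MSAs (8% per-site divergence) and carrying the Pfam
accessions the pipeline keys on, so real Pfam files drop in unchanged.

Counts are negative-binomial with mean 50 and size 2 (variance
m + m²/k, so size → ∞ recovers Poisson — a tested limit), 20 samples by
default, a 20% silent-gene fraction, and library sizes equal to per-sample
column sums.

**What passing on synthetic data shows — and does not.** The generator's
positives and decoys are well-separated (decoy mutations always touch a
conserved position; divergence outside stays ≤ 15%), so perfect
precision/recall demonstrates the correctness of the mapping, screen,
typing, partition and network logic — not the real-data sensitivity of
profile HMMs to remote dCache_1 homologs, the adequacy of any particular
name catalog, or the biological validity of the five-residue rule itself.
Real screens also face fragmented gene models, chimeric contigs and
annotation noise that the generator does not emulate.

## Problem sizes and numerical choices

The shipped test and acceptance runs use 12- and 40-genome communities, 200
oracle alignment comparisons and 1 000 random RPKM checks — sizes chosen so
a full verification completes in a couple of minutes on one core while still
exercising every decision path (multi-domain receptors, tandem dCache_1,
LsrB co-occurrence, QC failures, silent genes). Alignment scores are sums of
integers and the gap constants, so float equality against the oracle is
exact; frequency normalisations are asserted to 1e-9. Degenerate inputs
(empty proteomes, zero denominators, unknown genomes, infeasible role
fractions) raise immediately with the offending identifier in the message.

## Known limitations

- The keyword catalog determines name-screen sensitivity for the 12
  name-only families; the shipped reconstruction is deliberately
  conservative and should be replaced by a curated table for production use.
- PF13407 cannot distinguish LuxP from LsrB without name evidence; unnamed
  PF13407 hits default to LsrB.
- The five-residue screen is exact-match by definition; near-miss pockets
  (conservative substitutions) are reported as failing with their residue
  states, letting users re-screen under relaxed rules.
- Expression percentages depend on the (configurable) "expressed" rule; the
  default nonzero-count rule is the weakest defensible choice.
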