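# Methods

## Hybrid k-mer support model

Short reads are decomposed into k-mers counted in canonical form (the
lexicographic minimum of a k-mer and its reverse complement), merging the
two sequencing orientations of a paired-end library; k must be odd so that
no k-mer is its own reverse complement. K-mers containing N are skipped.
K-mers with count ≥ the solidity threshold form the trusted graph.
Defaults k = 21, solidity = 3: with 21-mers a random match in a
transcriptome-sized k-mer set is vanishingly unlikely, and solidity 3 means
every accepted base is effectively confirmed by at least three independent
short reads.

A long-read position is *supported* when at least one solid k-mer of the
read overlaps it. This "any overlapping solid k-mer" semantics (rather
than requiring all overlapping k-mers solid) matches graph-path support: a
single base error kills all k ≈ 21 k-mers that cross it, and under the
overlap rule the flanking solid k-mers still reach to within 0 bases of the
error, so isolated errors surface as short *internal* unsupported runs —
exactly what the filter targets. The support filter rejects a read iff it
has any internal unsupported run, or its unsupported positions exceed
`max_uncovered_frac` (default 1%, i.e. 99% coverage). The 1% terminal
allowance is applied to the **combined** terminal runs; a per-end variant
is available via `terminal_allowance_per_end`. The allowance exists because
a k-mer covering the first (last) base of a transcript requires a short
read starting (ending) exactly at the terminus, which real libraries only
sometimes provide. Reads shorter than k are fully unsupported by
construction and fail.

### Weak-region correction

The corrector is a deliberately simplified hybrid error corrector, not a
reimplementation of a production tool: for each internal unsupported run
the nearest flanking solid k-mers are anchors (maximality of the run
guarantees they abut it), and a depth-first search enumerates solid-graph
spellings from the left anchor to the right anchor with total length within
±30% of the original span, bounded by `max_path_nodes` (default 20,000)
node expansions. Children are expanded in A<C<G<T order and ties in edit
distance (computed with edlib) break to the lexicographically smallest
path, so results are deterministic. A re-spelling is accepted only if it
strictly increases the read's coverage fraction; otherwise the region is
left untouched (failure to bridge is a no-op). Bases outside the anchored
span are never modified, and coverage fraction is non-decreasing. Split
anchors, inner trimming and disk-backed counting are out of scope.

## Repeat and contaminant screening

Reads matching an interspersed-repeat consensus library are removed whole.
Matching is full affine-gap Smith–Waterman (a gap of length L scores
`gap_open + L·gap_extend`); the default scheme is +2 match, −3 mismatch,
−5 open, −2 extend, and the removal threshold is a score of 225,
inclusive — "score threshold" conventionally includes the threshold value.
Divergence-aware substitution matrices of dedicated repeat maskers are not
reproduced; the threshold is interpreted on the simple scheme's scale and
both are configurable. Library entries are searched in both orientations;
reads are not (they are already 5′→3′ oriented). The DP kernel is
numba-jitted; among equal-score cells the smallest (query_end, target_end)
is reported, making spans deterministic. Contaminant screening removes a
read when a local alignment to a contaminant reference covers ≥ 50% of the
read at ≥ 90% identity (both configurable); identity is matches over
alignment columns of the optimal local alignment.

## Locus grouping and collapse

Loci are connected components of same-chromosome, same-strand exonic
overlap (span overlap would fuse nested antisense genes; strand awareness
can be relaxed by config). Within a locus, multi-exon reads with an
identical intron chain merge when their transcription start positions
differ by ≤ 10,000 bp and their transcription ends by ≤ 1,000 bp
(strand-aware; single linkage, so merging is permutation-invariant). The
generous 5′ fuzz absorbs 5′-truncated fragments of the same isoform; the
tighter 3′ fuzz respects the better-defined polyadenylation boundary. A
mono-exon read merges into another that contains it within the same fuzz
limits — a design choice; mono-exon handling at this stage is genuinely
open. The representative is the member with the longest sequence (ties to
the smallest id). The registry sums FLNC counts and unions contributing
samples at every merge, so total FLNC support is conserved.

Unaligned reads are clustered greedily, longest first: a sequence joins
the qualifying representative of highest local-alignment identity
(identity ≥ 0.99 and member uncovered bases ≤ 1% of its length, replaced
by an absolute 30 bp cap for members longer than 3,000 bp; representative
overhang unrestricted), else founds a new cluster. "Most similar" is
percent identity of the best local alignment. This identity clustering
stands in for pseudo-genome-based family reconstruction, which is out of
scope.

## Structural classification

Exactly one of nine categories, in precedence order: intergenic (no gene
span overlapped on either strand), antisense (only opposite-strand genes
overlapped), fusion (exonic overlap with ≥ 2 same-strand genes),
genic_intron (chain entirely inside one annotated intron), then against
the single associated gene: FSM (identical intron chain to some
transcript), ISM (consecutive sub-chain of a transcript's introns —
"exons missing at the ends" excludes internal gaps), NIC (every junction
known at the gene, combination novel), NNC (≥ 1 unknown junction), and
genic_genomic otherwise. NIC's "known junctions" are tested against the
associated gene's junction set, not genome-wide (config flag to widen);
this matches the sense of a novel combination of a gene's own annotated
junctions. Mono-exon chains contained in an exon of a mono-exon transcript
are FSM, in an exon of a multi-exon transcript ISM, and exon/intron
straddlers genic_genomic — documented defaults where the category
definitions are silent. When several same-strand genes overlap without
fusion evidence, the associated gene is the one sharing the most
junctions, then the most exonic overlap. No sequence-identity percentage
is applied at classification; identity is established upstream by the
support filter.

Annotations: a junction is canonical iff its transcription-strand
donor..acceptor dinucleotides are GT..AG, GC..AG or AT..AC (minus-strand
introns are reverse-complemented before the test). The downstream-A
fraction is the fraction of transcription-strand A among up to 20 genomic
bases 3′ of the mapped end (the denominator truncates at the contig edge);
≥ 0.80 flags likely intra-priming. PolyA signals default to AATAAA/ATTAAA,
searched in the last 50 nt, 3′-most occurrence reported.

## ORF model

Reads are 5′→3′ oriented, so only the three forward frames are scanned.
An ORF is ATG..in-frame-stop, stop codon included; the best call is the
longest complete ORF of ≥ 150 nt (the threshold counts the stop codon and
is config-exposed), ties to the 5′-most start and then the smallest frame.
ATG is the only start codon in both codes — the conservative common
choice. Codons containing N translate to unknown and never terminate an
ORF. The vertebrate mitochondrial table (used for mitochondrially mapped
transcripts) differs where it matters: TGA encodes Trp and never
terminates; AGA/AGG are stops. Coding-potential scoring and
homology-supported ORF selection are out of scope; for transcripts whose
retention hinges on having a complete CDS, longest-complete captures the
decision.

## Evidence filter and comparisons

A transcript is kept iff it has a complete CDS and either (a) category FSM,
NIC, or NNC with **all** junctions canonical, with ≥ 2 FLNCs (the HQ
baseline — 2 FLNCs is what makes a read HQ in the first place), or (b) any
other category, or unmapped, with ≥ 5 FLNCs. The canonicality clause binds
to NNC only (NIC junctions are all annotated, hence canonical in any
well-formed annotation); reading it as "all junctions" rather than "novel
junctions only" is the stricter interpretation and a config flag selects
the other. Dropped records carry one machine-readable reason
(`no_complete_cds`, `low_flnc`, `noncanonical_low_flnc`). The multilocus
estimate is the fraction of gene symbols whose kept transcripts occupy ≥ 2
distinct collapse loci — a paralog signal; "gene" is operationalized as
the collapse locus, the more conservative choice.

Hit-table categorisation applies the printed formulas exactly, strict and
non-strict inequalities as stated, with no floating-point tolerance:
identical isoform iff E < 1e−50 ∧ identity ≥ 99 ∧ (query coverage per HSP
> 99 ∨ aln_len·100/subject_len > 99); else significant iff E < 1e−15;
else non-matching (hitless queries included). For identical isoforms the
UTR subgroup is subject_longer iff qcovhsp < 99, query_longer iff
aln·100/slen < 99, else near_equal. A query with hits tied exactly at
1e−15 is non-matching (strict less-than, as printed).

## Organ specificity

Presence of a transcript in a sample means the sample contributed ≥ 1 FLNC
to its cluster — the only expression signal the pipeline carries; there is
no abundance threshold and absence is literal. A transcript is
organ-specific iff present in ≥ 3 samples of one organ and in zero samples
of every other organ. Specific transcripts are gene-level specific when no
transcript of their locus is detected in any other organ, otherwise
splice-variant-level.

## Synthetic data

The generator emulates the study design the pipeline targets: an 11-sample
× 3-organ layout (4 gill, 4 liver, 3 head-kidney), genes on both strands
(pattern + + − −) spaced 25 kb apart, 4–6 exons of 130–220 nt with 90–160
nt introns, every junction GT..AG, and 2–3 annotated transcripts per gene
(alternative +3 donors on the first two introns make novel-in-catalog
combinations constructible). A CDS of 55–75 codons is embedded in the
second exon, an ORF inside the last intron and a reverse-complement ORF in
the first exon, so intron-contained and antisense isoforms can also carry
complete CDSs; intergenic ORF islands sit ≥ 10 kb from any gene, every
other island ATG-scrubbed to be non-coding. Planted isoforms cover all
nine categories via constructions that are re-derivable from the
annotation (FSM copy, terminal truncation, known-donor recombination, +6
canonical / +9 non-canonical donor shifts, intron-interior and
exon/intron-straddling placements, strand flips, two-gene spans), plus
unmapped free sequences and interspersed-repeat decoys. FLNC counts per
sample are 2–6 with designated minimal-baseline (one sample, 2 FLNCs) and
under-supported (< 5 total) cases on both sides of every evidence rule,
and roughly a third of isoforms get organ-specific designs. Truth labels
(category, canonicality, complete CDS by brute-force enumeration, expected
kept set, expected organ labels) are recorded at generation and re-derived
independently by the pipeline in tests.

Short-read simulation draws uniform fragments of 250–350 nt (paired 150 nt
ends) at 30× default depth **plus** `solidity` end-anchored pairs per
source transcript: without end anchoring, no uniform-coverage depth makes
the terminal k−1 bases of a transcript solid, because a k-mer covering the
first base needs a read starting exactly there. Long reads default to
error-free (one read per isoform per expressing sample, with occasional
5′-truncated fragments to exercise collapse); substitution, indel and
homopolymer error rates are available, in which case the truth SAM keeps
the error-free coordinates and omits SEQ. What the generator does **not**
emulate: realistic platform error profiles and quality models, empirical
read-length distributions, expression-level abundance variation, genomic
repeats beyond the planted library, alternative polyadenylation. Passing
tests therefore demonstrate the correctness of the decision rules and
recovery under clean, in-model conditions — not robustness to real-world
alignment noise, which enters through the upstream aligner this package
deliberately does not provide.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale by design: 16–50 genes,
~50–160 planted isoforms, ~200 long reads, a few thousand short-read
pairs, 500–1,000 randomized trials per oracle check. All randomness flows
from a single integer seed per run (numpy Generator); outputs are sorted
by read id, cluster ordering is re-derived internally, and every
tie-break (representative choice, alignment end cells, correction paths,
ORF ties) is specified, so reruns are byte-identical.

## Known limitations

- The corrector bridges one internal weak region at a time between its
  nearest anchors; overlapping or anchor-less weak regions (e.g. errors
  within k bases of both ends) are left uncorrected — the filter then
  rejects such reads rather than risking a wrong repair.
- The Smith–Waterman threshold of 225 is scheme-relative; screening
  sensitivity against diverged repeats is below that of matrix-based
  repeat maskers.
- Fusion detection requires exonic overlap with two same-strand annotated
  genes; read-through of unannotated neighbours is classified NNC or
  genic.
- The identity collapse is O(n · m) in members × representatives and is
  intended for the unmapped minority, not for full-transcriptome
  clustering.
- `estimate_multilocus_genes` requires externally supplied gene symbols;
  without symbol annotation the paralog estimate is undefined.
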