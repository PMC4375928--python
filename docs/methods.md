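# Methods

## Scope and data model

`ltrkit` operates downstream of read mapping and transcript quantification:
alignments arrive as SAM text (minimal columns 1–6), abundances as TSV
matrices of FPKM or RPKMS, annotations as GTF/BED, aligned loci as aligned
FASTA with a Newick topology and a Vienna dot-bracket structure. All
coordinates are held internally as 0-based half-open intervals; GTF
(1-based inclusive) converts on read and write, BED passes through. T and U
are interchangeable wherever base-pairing logic applies, reconciling
genomic (DNA) and structural (RNA) views of the same locus.

## Targeted-assembly quantification

The quantifier answers "how much of this one transcript is in this
library?" without transcriptome-wide assembly. Seeds are canonical k-mers
(lexicographic minimum of a k-mer and its reverse complement) of the target
cDNA; a read is recruited when it shares at least `min_seed_hits` canonical
k-mers with the seed set, making recruitment strand-insensitive, which
matches unstranded poly(A) libraries. Defaults: k = 15, one seed hit,
20-nt minimum exact assembly overlap, 2× minimum reported coverage, and a
200-nt / 90%-identity contig filter; all are flags.

Assembly is greedy: each contig seeds from the longest unused read and
extends 3′/5′ with the unused read (either orientation) showing the longest
exact overlap; after extension stalls, unused reads contained verbatim in
the consensus are absorbed so coverage and the read tally reflect them.
Each read joins at most one contig; the reported contig is its longest
block with coverage ≥ 2, and ties break lexicographically on sequence so
output is deterministic for a fixed input multiset. Identity to the target
is computed on the best local alignment (match +1, mismatch −1, gap −2)
as matches / alignment columns with gap columns counted as mismatches.

Two tally conventions exist in practice; the package counts reads
assembled into identity-passing contigs by default and can count all
recruited reads instead (`tally="recruited"`). The library size in RPKMS
denominates all reads scanned, not mapped reads, following the metric's
name (per million sequenced).

## Repeat/TSS association

The TSS is the leftmost base of a + gene and the rightmost base of a −
gene. Distance from a TSS to a repeat is the unsigned count of bases to the
nearest repeat base — 0 inside the repeat, 1 when immediately adjacent — so
a window of 0 selects exactly the genes whose TSS falls inside a repeat,
and the association set grows monotonically with the window. Both sides of
the TSS count by default because LTRs act as bidirectional promoters; an
`upstream_only` switch implements the stricter convention. Rescue mode
additionally reports genes with a repeat overlapping an exon while the TSS
lies strictly upstream of the repeat — the configuration where the repeat
donates exonic sequence but not the start site. Read counting over
intervals uses reference spans from the CIGAR (M/D/N/=/X consume
reference); one overlapping base counts, and a read may count toward
several overlapping intervals.

## Expression statistics

Detectability is strict: a sample expresses the transcript iff its
abundance exceeds 0 (in RPKMS, at least one assembled read). The 2×2
group-by-detectability table feeds a Pearson chi-squared independence test
with the Yates continuity correction on by default; goodness-of-fit tests
against analytic proportions are uncorrected with df = categories − 1.
This combination reproduces both conservation statistics from their
published counts (the corrected 2×2 gives P ≈ 8.4×10⁻⁴ where the
uncorrected form gives ≈ 5×10⁻⁴). Group contrasts across co-family
lncRNAs run one-way ANOVA with Tukey's HSD (studentized range) on
log₂(x+1) abundances, the scale on which such contrasts are displayed.
Heatmap ordering uses agglomerative clustering with centroid linkage and
Euclidean distance (`scipy.cluster.hierarchy`). The survival-stratification
cutoff of 5.6 FPKM is stored as a documented constant
(`SURVIVAL_CUTOFF_FPKM`); the threshold-derivation procedure and the
survival models themselves are out of scope.

## Structural conservation

The tree is an input (rooted, strictly binary; polytomies are rejected
rather than silently resolved because resolution changes parsimony counts).
Fitch counting runs over five states — four nucleotides plus the alignment
gap — so single-base indels register as substitution events; events whose
derived state is a gap are deletions and never compensatory. The top-down
pass assigns the parent's state when the child's state set allows it and
otherwise the first state in "-ACGU" order, a deterministic tie-break.

A site is *variable* iff its minimum change count exceeds zero, and the
paired/unpaired × variable/invariant table is tested with the corrected
chi-squared. The species set entering the contrast is a parameter
(`MultiAlignment.subset`), since a consensus structure inferred on a
subclade need not bind the full alignment.

**Compensatory classification.** A stem substitution is compensatory iff
the base pair is canonical (GC/CG, AU/UA, GU/UG) *both* in the parent and,
after the change, in the child node — "maintaining base pairing" in the
strict sense. The post-change-only reading (child pair canonical,
regardless of the parent) was considered and rejected: parsimony cannot
polarize events on the branches adjacent to the root, and under any
deterministic tie-break roughly half of those events are reconstructed in
reverse; the reverse of a pairing-breaking change looks like a
pairing-restoring one and is misread as compensatory. On simulated
alignments this inflated the classified compensatory fraction by about
+0.08 at a generative probability of 4/24; requiring the parent pair to be
canonical removes the bias (measured residual < 0.01) because reversed
breaking events then carry a non-canonical parent pair. Bookkeeping:
`n_locations` counts distinct base-pair positions hit,
`n_pairs_affected` counts distinct (pair position, branch) combinations —
two events on the two sides of one pair on different lineages affect two
pairs at one location.

**The null.** For each canonical pair class GC, GU, AU, enumerate the
eight single-position changes (three substitutions and one deletion at
each partner) and test the result for canonical pairing: 24 outcomes, 4
maintaining (GC:1, AU:1, GU:2), so a random stem change preserves pairing
with probability 4/24. The observed compensatory/non-compensatory split is
tested against (4/24, 20/24) by goodness of fit. At n = 39 events the
test statistic is discrete: its exact null rejection probability at
nominal α = 0.05 is 2.9% (computed by exact binomial summation), and its
power at a true compensatory probability of 0.5 is 99.5%; the calibration
checks compare simulated rates to these exact values rather than to the
nominal level.

Percent identity per region counts a column with a gap in either sequence
as a mismatch, over the full region width (an all-gap region scores 0).
Splice-junction conservation reads the first two and last two non-gap
characters of each intron range (GU..AG; species with fewer than four
non-gap intron characters are flagged undetermined). ORF enumeration scans
the three forward frames for maximal start→stop ORFs, counting the stop
codon in the length, with optional near-cognate CUG/GUG/UUG starts; an ORF
reaching the sequence end is reported as incomplete.

## Synthetic data

One global seed drives every generator through per-operation derived
streams (`default_rng([seed, stream])`), so outputs are bit-reproducible
and adding a generator never shifts another's stream.

*Reads*: each read derives from the target with probability
`target_abundance` (default 0.01) else a uniform decoy, uniform start,
strand flipped with probability 0.5, per-base substitution errors at
`error_rate` (default 0.005; the end-to-end recovery checks run the
error-free regime, where exact-overlap assembly reconstructs the target
verbatim). Default read length 75 nt and 10⁵ reads approximate a
downsampled poly(A) library at desk scale. The generator produces no indel
errors and no quality scores.

*Annotations*: three-exon genes occupy well-separated slots on a synthetic
chromosome; planted repeats realise the boundary cases d = 0 (TSS inside),
d = window, d = window + 1 (just outside) and an exon-overlap/upstream-TSS
rescue case, plus random in/out distances; decoy repeats sit far from all
TSSs. Truth lists every planted association with its mode.

*Alignments*: a root sequence whose stems are built from canonical pairs
evolves down an 8-taxon catarrhine-style tree (or any supplied binary
tree). Each site mutates per branch with probability `subst_rate` (default
0.02). While a pair is canonical, a stem hit is compensatory with
probability `compensatory_prob` — the new state is drawn from the states
that still pair with the partner, switching to the partner side when only
it has a preserving alternative (AU and GC pairs have one mutable side) —
and otherwise pairing-breaking, a deletion with probability 1/8 among
breaking outcomes, mirroring the deletion share of the null's outcome
space. Once a pair is broken, its sites mutate like loop sites. The
simulator evolves substitutions and single-base deletions only — no
insertions, no rate heterogeneity, no branch-length variation — so passing
recovery tests demonstrates correctness of the counting and classification
machinery, not robustness to alignment error or realistic indel processes.

*Matrices*: per-group log-normal abundances (2^N(log₂(mean+1), σ) − 1,
floored at 0, optional zero-inflation) with returned labels for the
ANOVA/chi-squared stages.

## Problem sizes and numerical choices

The bundled checks run at desk scale: 10⁵-read libraries for assembler
recovery, 4–6-leaf trees for the brute-force parsimony oracle (exhaustive
5^internal enumeration), 100 random annotation configurations for the
association miner, eight evolved alignments per compensatory-probability
setting (accumulating ≥ 100 stem substitutions), and 1,000 binomial
replicates for test calibration at the published n = 39. Cohort-scale
quantities reported for the original tumor panels (mean FPKM levels,
quantifier cross-correlation, hazard ratios, percent-detected ranges)
depend on controlled-access TCGA/GEO data and are not recomputed here; the
association and conservation statistics are recomputed from the published
contingency counts, which the package treats as inputs.

Chi-squared machinery comes from `scipy.stats` (`chi2_contingency`,
`chisquare`, `tukey_hsd`, `f_oneway`, `ttest_rel`, `pearsonr`); tests
cross-check Tukey HSD against `statsmodels` as an independent
implementation. Local alignment uses `Bio.Align.PairwiseAligner`; Newick
parsing uses `dendropy` with a strict binary check on conversion.

## Known limitations

- The greedy assembler has no consensus voting: sequencing errors split
  contigs rather than being outvoted, so tallies under high error rates
  undercount relative to an OLC assembler with consensus.
- Parsimony undercounts multiple hits (homoplasy); per-site counts are
  lower bounds on true event counts, and branch placement of root-adjacent
  events is unidentifiable (mitigated for classification as described).
- The compensatory classifier evaluates pairs within one reconstructed
  node; simultaneous double substitutions in a single branch are rare
  under the simulated rates but classified from the joint end state.
- Association mining is O(genes × repeats); adequate for repeat-family
  screens (hundreds of elements), not genome-wide all-repeat scans.
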