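# ltrkit

A toolkit for discovering and characterising long non-coding RNAs (lncRNAs)
whose promoters derive from endogenous retrovirus (ERV) long terminal
repeats (LTRs). Roughly 8% of the human genome is retroviral in origin, and
LTRs retain promoter elements that tumors can reactivate; an LTR sitting at
a lncRNA's transcription start site (TSS) is therefore a candidate driver of
tumor-specific lncRNA expression. `ltrkit` re-implements, as a tested and
reusable library with a CLI, the computational pipeline used to
characterise one such LTR-driven, adenocarcinoma-associated lncRNA:

1. **Targeted-assembly quantification** (`ltrkit.targeted_quant`) —
   overlapping *k*-mers (default *k* = 15, canonicalised over both strands)
   extracted from a target cDNA recruit reads from a sequencing library; the
   recruited reads are greedily assembled (exact overlap ≥ 20 nt, reported
   coverage ≥ 2×); contigs ≥ 200 nt with ≥ 90% local-alignment identity to
   the target are retained, and the assembled-read tally *n* becomes

   RPK = *n* / (*L*/1000),  RPKMS = RPK / (*N*/10⁶)

   for target length *L* and library size *N* (reads per kilobase, per
   million reads sequenced).
2. **Repeat/TSS association mining** (`ltrkit.repeat_association`) — genes
   whose TSS lies within a window (500 bp or 50 bp in the original screens)
   of a repeat element, with an exon-overlap rescue mode for repeats that
   contribute exonic sequence while the TSS lies upstream, plus per-repeat
   read counting over alignment intervals.
3. **Expression statistics** (`ltrkit.expression_stats`) — strict
   detectability (> 0 RPKMS), 2×2 chi-squared association tests
   (continuity-corrected by default), goodness-of-fit against analytic
   proportions, paired *t*, Pearson *r*, one-way ANOVA + Tukey HSD on
   log₂(x+1) abundances, and centroid-linkage/Euclidean heatmap ordering.
4. **Structural conservation** (`ltrkit.conservation`) — per-column Fitch
   parsimony substitution counting on a fixed rooted binary tree (gap as a
   fifth state); a paired-vs-unpaired site-variability contrast; per-event
   compensatory classification (a stem substitution is compensatory iff the
   base pair is canonical — GC/CG, AU/UA, GU/UG — both before and after the
   change); and the combinatorial null in which each of GC, GU and AU
   admits eight single-position changes (3 substitutions + 1 deletion per
   partner), 24 outcomes of which exactly 4 preserve pairing
   (*p* = 4/24). Region-wise percent identity (gaps count as mismatches),
   GT..AG splice-junction checks and ORF enumeration (including
   near-cognate CUG/GUG/UUG starts) complete the locus characterisation.
5. **Synthetic data** (`ltrkit.synthetic_data`) — seeded generators for
   read libraries with planted target abundance, annotations with repeats
   planted at known TSS distances, alignments evolved along a primate-style
   tree with a tunable compensatory-substitution probability, and
   group-structured expression matrices. These make every stage testable
   without external downloads.

## Worked example

```python
from ltrkit import (ContingencyTable2x2, chi2_independence,
                    chi2_goodness_of_fit, null_enumeration,
                    SimConfig, quantify_library)
from ltrkit.synthetic_data import make_target_and_decoys, simulate_reads

null = null_enumeration()
print(f"pair-change outcomes: {null.total_outcomes}, "
      f"pairing-maintaining: {null.maintaining_outcomes}")

var = chi2_independence(ContingencyTable2x2(39, 203, 47, 105))
print(f"paired vs unpaired variability: chi2 = {var.statistic:.2f}, P = {var.p:.2g}")

comp = chi2_goodness_of_fit([19, 20], [4/24, 20/24])
print(f"compensatory vs null 4/24:      chi2 = {comp.statistic:.2f}, P = {comp.p:.2g}")

cfg = SimConfig(seed=1, n_reads=100_000, error_rate=0.0, target_abundance=0.01)
target, decoys = make_target_and_decoys(cfg)
reads, truth = simulate_reads(cfg, target, decoys)
result, contigs = quantify_library(target, reads)
print(f"targeted assembly: {len(contigs)} contig, "
      f"{result.n_reads_assembled}/{truth.n_target_reads} planted reads, "
      f"RPKMS = {result.rpkms:.1f}")
```

prints

```
pair-change outcomes: 24, pairing-maintaining: 4
paired vs unpaired variability: chi2 = 11.14, P = 0.00084
compensatory vs null 4/24:      chi2 = 28.85, P = 7.8e-08
targeted assembly: 1 contig, 1005/1005 planted reads, RPKMS = 25314.9
```

The first line is the analytic null for random single-position changes to
canonical base pairs. The next two recompute the conservation statistics
from the locus's variable-site and substitution counts: stems vary less
than loops (P ≈ 8×10⁻⁴), and the stem substitutions that do occur preserve
pairing far more often than the 4/24 null expects (19/39 observed vs 6.5/39
expected, P ≈ 7.8×10⁻⁸) — the classic signature of selection on RNA
secondary structure. The last line shows the targeted assembler recovering
every planted read of a 397-nt synthetic target from a 100,000-read library
as a single full-length contig; 1005 reads over 0.397 kb and 0.1 M reads
gives RPKMS = 1005/0.397/0.1 ≈ 25315.

A CLI mirrors the stages: `ltrkit validate`, `ltrkit quant`,
`ltrkit associate`, `ltrkit readcount`, `ltrkit stats chi2|gof|anova`,
`ltrkit conserve`, `ltrkit simulate`. Run any with `--help`.

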