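"""Repeat-element / lncRNA TSS association mining and per-repeat read counting.

An LTR repeat is associated with a gene when it lies within a fixed window of
the gene's transcription start site (distance 0 when the TSS falls inside the
repeat).  Distance is unsigned — upstream and downstream both count, since
LTRs can act as bidirectional promoters — with an upstream-only switch for
the stricter convention.  An optional rescue mode additionally reports genes
whose TSS is outside (upstream of) a repeat that nevertheless overlaps one of
their exons, the situation where the repeat contributes exonic sequence but
not the start site itself.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InputError
from .io_formats import GeneModel, GenomicInterval, ReadAlignmentRecord

MODE_TSS_WINDOW = "tss_window"
MODE_EXON_OVERLAP_RESCUE = "exon_overlap_rescue"

#: TSS proximity windows used in the original genome-wide screens (bp).
DEFAULT_WINDOWS = (500, 50)


@dataclass(frozen=True)
class RepeatElement:
    """A repeat-family instance (e.g. an LTR) with a reliability flag."""

    name: str
    interval: GenomicInterval
    reliable: bool = True


@dataclass(frozen=True)
class TssAssociation:
    gene_id: str
    repeat: RepeatElement
    distance: int
    mode: str


def tss_of(gene: GeneModel) -> int:
    """0-based transcription start site: leftmost base on +, rightmost on -."""
    if gene.interval.strand == "+":
        return gene.interval.start
    if gene.interval.strand == "-":
        return gene.interval.end - 1
    raise InputError(f"gene {gene.gene_id} has ambiguous strand '.'")


def _is_upstream(tss: int, strand: str, repeat: GenomicInterval) -> bool:
    """True when the TSS lies strictly 5' of the repeat on the gene's strand."""
    if strand == "+":
        return tss < repeat.start
    return tss >= repeat.end


def associate(
    repeats,
    genes,
    window: int,
    rescue: bool = False,
    upstream_only: bool = False,
) -> list[TssAssociation]:
    """Mine gene-repeat pairs whose TSS distance is within `window`.

    With rescue enabled, genes whose TSS lies upstream of a repeat overlapping
    one of their exons are also reported (mode exon_overlap_rescue).  Each
    gene-repeat pair is reported once, preferring the smaller-distance mode.
    Repeat strand is ignored.
    """
    if window < 0:
        raise InputError("window must be >= 0")
    out: list[TssAssociation] = []
    for gene in genes:
        tss = tss_of(gene)
        strand = gene.interval.strand
        for rep in repeats:
            if rep.interval.chrom != gene.interval.chrom:
                continue
            dist = rep.interval.distance_to_point(tss)
            eligible = True
            if upstream_only and dist > 0:
                # keep only repeats on the 5' side of the TSS
                eligible = (
                    rep.interval.end <= tss if strand == "+" else rep.interval.start > tss
                )
            hit_window = eligible and dist <= window
            hit_rescue = (
                rescue
                and any(rep.interval.overlaps(ex) for ex in gene.exons)
                and _is_upstream(tss, strand, rep.interval)
            )
            if hit_window:
                out.append(TssAssociation(gene.gene_id, rep, dist, MODE_TSS_WINDOW))
            elif hit_rescue:
                out.append(
                    TssAssociation(gene.gene_id, rep, dist, MODE_EXON_OVERLAP_RESCUE)
                )
    return out


def count_reads_in_intervals(
    alignments: list[ReadAlignmentRecord],
    intervals: list[GenomicInterval],
) -> list[int]:
    """Per-interval read counts; a read counts toward every interval its
    reference span overlaps by >= 1 base.  Unmapped reads are ignored."""
    spans = [a.reference_span() for a in alignments if not a.is_unmapped]
    counts = []
    for iv in intervals:
        counts.append(sum(1 for sp in spans if sp.overlaps(iv)))
    return counts
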