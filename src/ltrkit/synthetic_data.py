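"""Generators of synthetic inputs with the statistical structure the analysis
assumes: poly(A) RNA-seq libraries containing a target transcript at known
abundance, genome annotations with repeats planted at known TSS distances,
primate-style alignments evolved along a tree with a tunable
compensatory-substitution probability, and group-structured expression
matrices.

All generators are deterministic under a fixed seed; each operation derives
its own random stream from the global seed, so adding one generator never
shifts the output of another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .io_formats import (
    GeneModel,
    GenomicInterval,
    Phylogeny,
    SecondaryStructure,
    SequenceRecord,
    parse_dotbracket,
    parse_newick,
)
from .repeat_association import (
    MODE_EXON_OVERLAP_RESCUE,
    MODE_TSS_WINDOW,
    RepeatElement,
)
from .conservation import CANONICAL_PAIRS, GAP, SubstitutionEvent, is_canonical
from .targeted_quant import revcomp

_BASES = "ACGT"
_RNA_BASES = "ACGU"

# per-operation stream tags so generators draw from independent substreams
_STREAM_READS = 1
_STREAM_ANNOT = 2
_STREAM_EVOLVE = 3
_STREAM_MATRIX = 4
_STREAM_SEQ = 5


@dataclass
class SimConfig:
    """Knobs for every generator; defaults emulate the study's data regimes.

    read_length/n_reads approximate a downsampled unstranded poly(A) library;
    target_abundance is the expected fraction of reads originating from the
    target transcript; window mirrors the 500-bp TSS screen; subst_rate is
    the expected per-site substitution probability per branch at primate-like
    divergence; compensatory_prob is the probability that a stem substitution
    preserves canonical pairing (the combinatorial null value is 4/24);
    deletion_prob is the share of deletions within pairing-breaking changes,
    mirroring the 1-in-8 deletion share of the null outcome space.
    """

    seed: int = 0
    read_length: int = 75
    n_reads: int = 100_000
    error_rate: float = 0.005
    target_abundance: float = 0.01
    window: int = 500
    n_genes: int = 20
    n_repeats: int = 30
    subst_rate: float = 0.02
    compensatory_prob: float = 4 / 24
    deletion_prob: float = 1 / 8

    def __post_init__(self):
        for name in ("error_rate", "target_abundance", "compensatory_prob",
                     "deletion_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InputError(f"{name} must be in [0, 1]")
        if min(self.read_length, self.n_reads, self.window,
               self.n_genes, self.n_repeats) < 0:
            raise InputError("counts and lengths must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def make_target_and_decoys(
    config: SimConfig, target_length: int = 397, n_decoys: int = 20,
    decoy_length: int = 1500,
) -> tuple[SequenceRecord, list[SequenceRecord]]:
    """A synthetic target transcript plus decoy transcripts for read simulation."""
    rng = config.rng(_STREAM_SEQ)
    target = SequenceRecord("target", random_sequence(target_length, rng))
    decoys = [
        SequenceRecord(f"decoy{i}", random_sequence(decoy_length, rng))
        for i in range(n_decoys)
    ]
    return target, decoys


@dataclass
class ReadSimTruth:
    origins: list[str]
    n_target_reads: int
    library_size: int


def simulate_reads(
    config: SimConfig,
    target: SequenceRecord,
    decoys: list[SequenceRecord],
) -> tuple[list[SequenceRecord], ReadSimTruth]:
    """Draw reads from the target (with prob. target_abundance) or a uniform
    decoy; uniform start positions, strand flipped with prob. 0.5, per-base
    substitution errors at error_rate.  Truth records every read's origin."""
    rng = config.rng(_STREAM_READS)
    L = config.read_length
    sources = [target] + list(decoys)
    for src in sources:
        if len(src.seq) < L:
            raise InputError(f"sequence {src.id} shorter than read_length")
    reads: list[SequenceRecord] = []
    origins: list[str] = []
    n_target = 0
    for i in range(config.n_reads):
        if rng.random() < config.target_abundance:
            src = target
            n_target += 1
        else:
            src = decoys[rng.integers(len(decoys))] if decoys else target
        start = int(rng.integers(0, len(src.seq) - L + 1))
        seq = src.seq[start : start + L]
        if rng.random() < 0.5:
            seq = revcomp(seq)
        if config.error_rate > 0:
            chars = list(seq)
            errs = np.nonzero(rng.random(L) < config.error_rate)[0]
            for j in errs:
                chars[j] = rng.choice([b for b in _BASES if b != chars[j]])
            seq = "".join(chars)
        reads.append(SequenceRecord(f"read{i}", seq))
        origins.append(src.id)
    return reads, ReadSimTruth(origins, n_target, config.n_reads)


@dataclass
class PlantedPair:
    gene_id: str
    repeat_name: str
    distance: int
    mode: str


@dataclass
class AnnotationTruth:
    pairs: list[PlantedPair]
    chrom: str
    chrom_length: int


def plant_annotations(
    config: SimConfig,
) -> tuple[list[GeneModel], list[RepeatElement], AnnotationTruth]:
    """Genes on a synthetic chromosome with repeats planted at known TSS
    distances.

    Each gene occupies its own slot, far enough from every other slot that no
    unintended association can arise at the configured window.  Planted
    distances always include the boundary cases d=0 (TSS inside the repeat),
    d=window, d=window+1 (just outside), and one exon-overlap case whose TSS
    lies upstream of the repeat (recovered only in rescue mode).
    """
    if config.n_genes < 1 or config.n_repeats < 1:
        raise InputError("need n_genes >= 1 and n_repeats >= 1")
    rng = config.rng(_STREAM_ANNOT)
    w = config.window
    gene_len = 3000
    repeat_len = 300
    # slot wide enough that a repeat planted anywhere near one gene is > window
    # away from the neighbouring genes' TSSs
    slot = gene_len + 6 * (w + repeat_len) + 2000
    chrom = "chrS"
    genes: list[GeneModel] = []
    repeats: list[RepeatElement] = []
    truth: list[PlantedPair] = []

    forced = ["d0", "d_window", "d_window_plus1", "exon_rescue"]
    for g in range(config.n_genes):
        base = 5 * (w + repeat_len) + g * slot
        strand = "+" if rng.random() < 0.5 else "-"
        exon1 = GenomicInterval(chrom, base, base + 400, strand)
        exon2 = GenomicInterval(chrom, base + 1000, base + 1400, strand)
        exon3 = GenomicInterval(chrom, base + gene_len - 400, base + gene_len, strand)
        gene = GeneModel(
            f"lnc{g}",
            GenomicInterval(chrom, base, base + gene_len, strand),
            (exon1, exon2, exon3),
        )
        genes.append(gene)
        tss = base if strand == "+" else base + gene_len - 1

        kind = forced[g] if g < len(forced) else rng.choice(
            ["d0", "random_in", "random_out", "none"]
        )
        if kind == "none":
            continue
        if kind == "d0":
            start = tss - repeat_len // 2
            d = 0
        elif kind == "d_window":
            d = w
            start = tss - d - repeat_len + 1 if strand == "+" else tss + d
        elif kind == "d_window_plus1":
            d = w + 1
            start = tss - d - repeat_len + 1 if strand == "+" else tss + d
        elif kind == "random_in":
            d = int(rng.integers(1, w + 1))
            start = tss - d - repeat_len + 1 if strand == "+" else tss + d
        elif kind == "random_out":
            d = int(rng.integers(w + 1, 3 * w + 2))
            start = tss - d - repeat_len + 1 if strand == "+" else tss + d
        else:  # exon_rescue: repeat inside an internal exon, TSS upstream
            mid = exon2.start + (len(exon2) - repeat_len) // 2
            start = mid
            d = GenomicInterval(chrom, start, start + repeat_len).distance_to_point(tss)
        rep = RepeatElement(
            f"REP_{kind}_{g}", GenomicInterval(chrom, start, start + repeat_len, ".",
                                               name=f"REP_{kind}_{g}")
        )
        repeats.append(rep)
        if kind == "exon_rescue":
            truth.append(PlantedPair(gene.gene_id, rep.name, d, MODE_EXON_OVERLAP_RESCUE))
        elif d <= w:
            truth.append(PlantedPair(gene.gene_id, rep.name, d, MODE_TSS_WINDOW))

    # decoy repeats in the far left margin, well away from every gene slot
    n_decoy = max(0, config.n_repeats - len(repeats))
    for r in range(n_decoy):
        start = r * (repeat_len + 10)
        if start + repeat_len > 4 * (w + repeat_len):
            break
        repeats.append(
            RepeatElement(
                f"REP_decoy_{r}",
                GenomicInterval(chrom, start, start + repeat_len, ".",
                                name=f"REP_decoy_{r}"),
            )
        )
    chrom_length = 5 * (w + repeat_len) + config.n_genes * slot + slot
    return genes, repeats, AnnotationTruth(truth, chrom, chrom_length)


def random_structured_sequence(
    n_stems: int, stem_len: int, loop_len: int, rng: np.random.Generator
) -> tuple[str, str]:
    """A sequence of hairpins and its dot-bracket string.

    Stems are built from canonical pairs; loops and linkers are unpaired.
    """
    seq: list[str] = []
    db: list[str] = []
    pairs = sorted(CANONICAL_PAIRS)
    for _ in range(n_stems):
        stem_pairs = [pairs[rng.integers(len(pairs))] for _ in range(stem_len)]
        seq.extend(p[0] for p in stem_pairs)
        db.extend("(" * stem_len)
        loop = [_RNA_BASES[rng.integers(4)] for _ in range(loop_len)]
        seq.extend(loop)
        db.extend("." * loop_len)
        seq.extend(p[1] for p in reversed(stem_pairs))
        db.extend(")" * stem_len)
        linker = [_RNA_BASES[rng.integers(4)] for _ in range(loop_len)]
        seq.extend(linker)
        db.extend("." * loop_len)
    return "".join(seq), "".join(db)


def default_primate_tree() -> Phylogeny:
    """An 8-taxon catarrhine-style topology (apes + Old World monkeys)."""
    return parse_newick(
        "(((((human,chimp),gorilla),orangutan),gibbon),"
        "((macaque,baboon),colobus));"
    )


@dataclass
class EvolveTruth:
    events: list[SubstitutionEvent]
    n_stem_events: int
    n_compensatory: int
    node_sequences: dict[str, str]


def evolve_alignment(
    config: SimConfig,
    root_seq: str,
    structure: SecondaryStructure,
    tree: Phylogeny | None = None,
) -> tuple["MultiAlignment", EvolveTruth]:
    """Evolve a root sequence down a tree over a fixed secondary structure.

    Per branch, each site mutates independently with probability subst_rate.
    At paired sites the new state preserves canonical pairing with the
    partner's current state in that lineage with probability
    compensatory_prob; otherwise a pairing-breaking state is drawn, a
    deletion with probability deletion_prob among the breaking outcomes.
    Unpaired sites substitute uniformly over the three other bases.  Truth
    logs every event with branch, site and states.
    """
    from .conservation import MultiAlignment  # local to avoid cycle at import

    root = root_seq.upper().replace("T", "U")
    if len(root) != len(structure):
        raise InputError("structure length must equal root sequence length")
    tree = tree or default_primate_tree()
    rng = config.rng(_STREAM_EVOLVE)

    # stable internal node ids matching conservation._node_ids (preorder n0..)
    ids: dict[int, str] = {}
    counter = 0
    for node in tree.preorder():
        if node.is_leaf:
            ids[id(node)] = node.label
        else:
            ids[id(node)] = f"n{counter}"
            counter += 1

    events: list[SubstitutionEvent] = []
    node_seqs: dict[str, str] = {}
    n_stem = 0
    n_comp = 0

    def mutate(parent_seq: list[str], parent_id: str, node) -> None:
        nonlocal n_stem, n_comp
        seq = list(parent_seq)
        if node.parent is not None:
            for site in range(len(seq)):
                if seq[site] == GAP:
                    continue
                if rng.random() >= config.subst_rate:
                    continue
                old = seq[site]
                partner = structure.partner(site)
                if (
                    partner is not None
                    and seq[partner] != GAP
                    and is_canonical(old, seq[partner])
                ):
                    # pair-level event: decide the outcome class first, then
                    # pick the side that can realise it (only one side of an
                    # AU or GC pair has a pairing-preserving alternative)
                    n_stem += 1
                    mut_site, partner_site = site, partner
                    if rng.random() < config.compensatory_prob:
                        keep = [
                            b for b in _RNA_BASES
                            if b != seq[mut_site]
                            and is_canonical(b, seq[partner_site])
                        ]
                        if not keep:
                            mut_site, partner_site = partner, site
                            keep = [
                                b for b in _RNA_BASES
                                if b != seq[mut_site]
                                and is_canonical(b, seq[partner_site])
                            ]
                        old = seq[mut_site]
                        new = keep[rng.integers(len(keep))]
                        n_comp += 1
                    else:
                        old = seq[mut_site]
                        if rng.random() < config.deletion_prob:
                            new = GAP
                        else:
                            break_states = [
                                b for b in _RNA_BASES
                                if b != old
                                and not is_canonical(b, seq[partner_site])
                            ]
                            new = break_states[rng.integers(len(break_states))]
                    seq[mut_site] = new
                    events.append(
                        SubstitutionEvent(
                            mut_site, (parent_id, ids[id(node)]), old, new
                        )
                    )
                    continue
                choices = [b for b in _RNA_BASES if b != old]
                new = choices[rng.integers(len(choices))]
                seq[site] = new
                events.append(
                    SubstitutionEvent(site, (parent_id, ids[id(node)]), old, new)
                )
        node_seqs[ids[id(node)]] = "".join(seq)
        for child in node.children:
            mutate(seq, ids[id(node)], child)

    mutate(list(root), "", tree.root)
    leaf_seqs = {n.label: node_seqs[n.label] for n in tree.leaves()}
    return (
        MultiAlignment(leaf_seqs),
        EvolveTruth(events, n_stem, n_comp, node_seqs),
    )


@dataclass
class MatrixTruth:
    labels: dict[str, str]
    group_means: dict[str, float]


def simulate_matrix(
    config: SimConfig,
    group_means: dict[str, float],
    group_sizes: dict[str, int],
    gene: str = "target_lnc",
    sigma: float = 1.0,
    zero_inflation: float = 0.0,
) -> tuple["pd.DataFrame", MatrixTruth]:
    """Log-normal abundances per named group around the stated means.

    Values are drawn as 2**Normal(log2(mean+1), sigma) - 1, floored at 0,
    then zeroed with probability zero_inflation.  Returns a samples x 1
    expression DataFrame plus per-sample group labels.
    """
    import pandas as pd

    if set(group_means) != set(group_sizes):
        raise InputError("group_means and group_sizes must share keys")
    if any(m < 0 for m in group_means.values()):
        raise InputError("group means must be >= 0")
    rng = config.rng(_STREAM_MATRIX)
    rows = {}
    labels = {}
    for group in sorted(group_means):
        mu = np.log2(group_means[group] + 1.0)
        for i in range(group_sizes[group]):
            sample = f"{group}_{i}"
            val = max(0.0, float(2.0 ** rng.normal(mu, sigma) - 1.0))
            if zero_inflation > 0 and rng.random() < zero_inflation:
                val = 0.0
            rows[sample] = val
            labels[sample] = group
    df = pd.DataFrame({gene: rows})
    return df, MatrixTruth(labels, dict(group_means))
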