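"""Targeted k-mer recruitment, greedy de novo assembly and RPK/RPKMS quantification.

Given one target transcript (e.g. a 397-nt lncRNA cDNA), overlapping k-mers
extracted from it recruit matching reads from a sequencing library; the
recruited reads alone are assembled into contigs; contigs are retained when
long enough and sufficiently identical to the target; and the reads assembled
into the passing contigs are tallied into

    RPK   = n_reads / (target_length / 1000)
    RPKMS = RPK / (library_size / 1e6)

i.e. reads per kilobase of target, optionally per million reads sequenced.
Recruitment is strand-insensitive: k-mers are canonicalised as the
lexicographic minimum of the forward k-mer and its reverse complement, which
suits unstranded poly(A) libraries.

Defaults mirror targeted-assembly practice: 15-nt seeds, one seed hit to
recruit, 20-nt exact assembly overlap, 2x minimum reported coverage, and a
200-nt / 90%-identity contig filter.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from .errors import InputError
from .io_formats import SequenceRecord

DEFAULT_K = 15
DEFAULT_MIN_SEED_HITS = 1
DEFAULT_MIN_OVERLAP = 20
DEFAULT_MIN_COVERAGE = 2
DEFAULT_MIN_CONTIG_LEN = 200
DEFAULT_MIN_IDENTITY = 0.90

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _kmers(seq: str, k: int, skip_ambiguous: bool = True):
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if skip_ambiguous and "N" in kmer:
            continue
        yield canonical_kmer(kmer)


@dataclass(frozen=True)
class SeedIndex:
    """Canonical k-mer set extracted from the target sequence."""

    k: int
    kmers: frozenset[str]


@dataclass
class RecruitedReadSet:
    """Reads sharing seed k-mers with the target, plus the library size scanned."""

    reads: list[SequenceRecord]
    library_size: int


@dataclass
class Contig:
    """An assembled consensus with read support and per-base coverage."""

    seq: str
    support: int
    coverage: list[int]
    read_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class QuantResult:
    n_reads_assembled: int
    target_length: int
    library_size: int
    rpk: float
    rpkms: float


def build_seed_index(target: SequenceRecord, k: int = DEFAULT_K) -> SeedIndex:
    """Extract every canonical k-mer of the target; k-mers containing N are skipped."""
    if len(target.seq) < k:
        raise InputError(f"target shorter than k={k}")
    return SeedIndex(k, frozenset(_kmers(target.seq.replace("U", "T"), k)))


def recruit_reads(
    reads,
    index: SeedIndex,
    min_seed_hits: int = DEFAULT_MIN_SEED_HITS,
) -> RecruitedReadSet:
    """Keep reads sharing >= min_seed_hits canonical k-mers with the seed index.

    library_size counts every read scanned, recruited or not.
    """
    if min_seed_hits < 1:
        raise InputError("min_seed_hits must be >= 1")
    recruited = []
    n_scanned = 0
    for read in reads:
        n_scanned += 1
        hits = 0
        for kmer in set(_kmers(read.seq.replace("U", "T"), index.k)):
            if kmer in index.kmers:
                hits += 1
                if hits >= min_seed_hits:
                    recruited.append(read)
                    break
    return RecruitedReadSet(recruited, n_scanned)


class _ReadPool:
    """Unused-read lookup tables keyed by min_overlap-length end-grams.

    Each read contributes both orientations; entries are removed lazily once
    a read is consumed.
    """

    def __init__(self, reads, min_overlap: int):
        self.min_overlap = min_overlap
        self.used: set[int] = set()
        # key -> list of (idx, oriented_seq); prefix keys for 3' extension,
        # suffix keys for 5' extension
        self.by_prefix: dict[str, list[tuple[int, str]]] = {}
        self.by_suffix: dict[str, list[tuple[int, str]]] = {}
        self.reads = reads
        for idx, read in enumerate(reads):
            fwd = read.seq.replace("U", "T")
            for oseq in {fwd, revcomp(fwd)}:
                if len(oseq) < min_overlap:
                    continue
                self.by_prefix.setdefault(oseq[:min_overlap], []).append((idx, oseq))
                self.by_suffix.setdefault(oseq[-min_overlap:], []).append((idx, oseq))

    def best_right(self, contig: str):
        """Read with the longest exact prefix-overlap with the contig's 3' end."""
        m = self.min_overlap
        for olen in range(min(len(contig), self._max_len()), m - 1, -1):
            anchor = contig[len(contig) - olen : len(contig) - olen + m]
            hit = self._match(self.by_prefix.get(anchor), lambda s: (
                len(s) >= olen and contig.endswith(s[:olen])))
            if hit:
                return olen, hit[0], hit[1]
        return None

    def best_left(self, contig: str):
        """Read with the longest exact suffix-overlap with the contig's 5' end."""
        m = self.min_overlap
        for olen in range(min(len(contig), self._max_len()), m - 1, -1):
            anchor = contig[olen - m : olen]
            hit = self._match(self.by_suffix.get(anchor), lambda s: (
                len(s) >= olen and s.endswith(contig[:olen])))
            if hit:
                return olen, hit[0], hit[1]
        return None

    def _match(self, candidates, pred):
        if not candidates:
            return None
        best = None
        for idx, oseq in candidates:
            if idx in self.used or not pred(oseq):
                continue
            if best is None or oseq < best[1] or (oseq == best[1] and idx < best[0]):
                best = (idx, oseq)
        return best

    def _max_len(self) -> int:
        return max((len(r.seq) for i, r in enumerate(self.reads)
                    if i not in self.used), default=0)

    def take(self, idx: int):
        self.used.add(idx)


def assemble_greedy(
    recruited: RecruitedReadSet,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> list[Contig]:
    """Greedy overlap assembly of recruited reads.

    Seeds each contig from the longest unused read, then repeatedly extends 3'
    and 5' with the unused read (either orientation) giving the longest exact
    overlap >= min_overlap; once extension stalls, unused reads contained
    verbatim in the contig are absorbed so coverage and support reflect them.
    Each read joins at most one contig.  The reported contig is the longest
    contiguous block with coverage >= min_coverage; a contig with no such
    block is discarded.  Ties (equal read length, equal overlap) break
    lexicographically on sequence for determinism.
    """
    if min_overlap < 1 or min_coverage < 1:
        raise InputError("min_overlap and min_coverage must be >= 1")
    # deterministic seeding order: longest first, then lexicographic
    order = sorted(
        range(len(recruited.reads)),
        key=lambda i: (
            -len(recruited.reads[i].seq),
            recruited.reads[i].seq,
            recruited.reads[i].id,
        ),
    )
    pool = _ReadPool(recruited.reads, min_overlap)
    contigs: list[Contig] = []

    for seed_idx in order:
        if seed_idx in pool.used:
            continue
        seed = recruited.reads[seed_idx]
        pool.take(seed_idx)
        contig = seed.seq.replace("U", "T")
        # (start offset in contig coords, read length, read id)
        placements: list[tuple[int, int, str]] = [(0, len(seed.seq), seed.id)]
        while True:
            right = pool.best_right(contig)
            left = pool.best_left(contig)
            best = None  # (olen, oseq, idx, side)
            for cand, side in ((right, "right"), (left, "left")):
                if cand is None:
                    continue
                olen, idx, oseq = cand
                if best is None or olen > best[0] or (
                    olen == best[0] and oseq < best[1]
                ):
                    best = (olen, oseq, idx, side)
            if best is None:
                break
            olen, oseq, idx, side = best
            pool.take(idx)
            if side == "right":
                start = len(contig) - olen
                contig = contig + oseq[olen:]
            else:
                shift = len(oseq) - olen
                contig = oseq[:shift] + contig
                placements = [(s + shift, l, rid) for s, l, rid in placements]
                start = 0
            placements.append((start, len(oseq), recruited.reads[idx].id))

        # absorb unused reads wholly contained in the assembled consensus
        for idx, read in enumerate(recruited.reads):
            if idx in pool.used:
                continue
            fwd = read.seq.replace("U", "T")
            for oseq in (fwd, revcomp(fwd)):
                at = contig.find(oseq)
                if at >= 0:
                    pool.take(idx)
                    placements.append((at, len(oseq), read.id))
                    break

        coverage = [0] * len(contig)
        for s, l, _rid in placements:
            for i in range(s, min(s + l, len(contig))):
                coverage[i] += 1
        core = _longest_covered_run(coverage, min_coverage)
        if core is None:
            continue
        lo, hi = core
        members = [rid for s, l, rid in placements if s < hi and s + l > lo]
        contigs.append(
            Contig(
                seq=contig[lo:hi],
                support=len(members),
                coverage=coverage[lo:hi],
                read_ids=tuple(members),
            )
        )
    return contigs


def _longest_covered_run(coverage: list[int], min_cov: int):
    best = None
    run_start = None
    for i, c in enumerate(coverage + [0]):
        if c >= min_cov:
            if run_start is None:
                run_start = i
        else:
            if run_start is not None:
                if best is None or i - run_start > best[1] - best[0]:
                    best = (run_start, i)
                run_start = None
    return best


def _local_identity(contig_seq: str, target_seq: str) -> float:
    """Identity over the best local alignment; gap columns count as mismatches."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    aln = aligner.align(contig_seq, target_seq)[0]
    matches = 0
    columns = 0
    blocks_a, blocks_b = aln.aligned
    prev_a_end = prev_b_end = None
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        if prev_a_end is not None:
            columns += max(a0 - prev_a_end, b0 - prev_b_end)  # gap columns
        for x, y in zip(aln.sequences[0][a0:a1], aln.sequences[1][b0:b1]):
            columns += 1
            if x == y:
                matches += 1
        prev_a_end, prev_b_end = a1, b1
    return matches / columns if columns else 0.0


def filter_contigs(
    contigs,
    target: SequenceRecord,
    min_len: int = DEFAULT_MIN_CONTIG_LEN,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[Contig]:
    """Keep contigs of length >= min_len whose local identity to the target is
    >= min_identity (matches / alignment columns, gaps as mismatches)."""
    if not (0 < min_identity <= 1):
        raise InputError("min_identity must be in (0, 1]")
    tseq = target.seq.replace("U", "T")
    kept = []
    for contig in contigs:
        if len(contig.seq) < min_len:
            continue
        ident = max(
            _local_identity(contig.seq, tseq),
            _local_identity(revcomp(contig.seq), tseq),
        )
        if ident >= min_identity:
            kept.append(contig)
    return kept


def quantify(
    n_reads_assembled: int, target_length: int, library_size: int
) -> QuantResult:
    """RPK and RPKMS from a read tally, target length and library size."""
    if target_length < 1:
        raise InputError("target_length must be >= 1")
    if library_size < 1:
        raise InputError("library_size must be >= 1")
    if n_reads_assembled < 0:
        raise InputError("n_reads_assembled must be >= 0")
    rpk = n_reads_assembled / (target_length / 1000)
    rpkms = rpk / (library_size / 1e6)
    return QuantResult(n_reads_assembled, target_length, library_size, rpk, rpkms)


def quantify_library(
    target: SequenceRecord,
    reads,
    k: int = DEFAULT_K,
    min_seed_hits: int = DEFAULT_MIN_SEED_HITS,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    min_len: int = DEFAULT_MIN_CONTIG_LEN,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    tally: str = "assembled",
) -> tuple[QuantResult, list[Contig]]:
    """End-to-end targeted quantification of one target in one library.

    tally="assembled" counts reads assembled into identity-passing contigs;
    tally="recruited" counts every recruited read.
    """
    if tally not in ("assembled", "recruited"):
        raise InputError("tally must be 'assembled' or 'recruited'")
    index = build_seed_index(target, k)
    recruited = recruit_reads(reads, index, min_seed_hits)
    contigs = assemble_greedy(recruited, min_overlap, min_coverage)
    passing = filter_contigs(contigs, target, min_len, min_identity)
    if tally == "assembled":
        n = sum(c.support for c in passing)
    else:
        n = len(recruited.reads)
    return quantify(n, len(target.seq), recruited.library_size), passing
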