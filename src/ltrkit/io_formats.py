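"""Readers, writers and core domain types for the formats the pipeline touches.

All genomic coordinates are held internally as 0-based half-open intervals.
GTF (1-based inclusive) converts on read and write; BED is native and passes
through untouched.  DNA and RNA views of the same locus are reconciled by
treating T and U as equivalent wherever base-pairing logic applies.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .errors import FormatError, InputError, ValidationError

STRANDS = {"+", "-", "."}
SEQ_ALPHABET = set("ACGTUN-")
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
#: CIGAR operations that consume reference bases.
_REF_CONSUMING = set("MDN=X")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A stranded 0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance_to_point(self, pos: int) -> int:
        """Unsigned distance from a point to the nearest interval edge.

        Zero when the point lies inside the interval.
        """
        if self.start <= pos < self.end:
            return 0
        return self.start - pos if pos < self.start else pos - (self.end - 1)


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence; dashes permitted only in aligned records."""

    id: str
    seq: str

    def __post_init__(self):
        if not self.id:
            raise ValidationError("sequence id must be non-empty")
        if not self.seq:
            raise ValidationError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - SEQ_ALPHABET
        if bad:
            raise ValidationError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneModel:
    """A gene with its spanning interval and sorted, non-overlapping exons."""

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self):
        if not self.exons:
            raise ValidationError(f"gene {self.gene_id} has no exons")
        prev_end = None
        for ex in self.exons:
            if ex.strand != self.interval.strand or ex.chrom != self.interval.chrom:
                raise ValidationError(f"gene {self.gene_id}: exon strand/chrom mismatch")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValidationError(f"gene {self.gene_id}: exon outside gene interval")
            if prev_end is not None and ex.start < prev_end:
                raise ValidationError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = ex.end


@dataclass(frozen=True)
class ReadAlignmentRecord:
    """Minimal SAM record (columns 1-6) with its reference span precomputed."""

    qname: str
    flag: int
    rname: str
    pos: int  # 1-based leftmost, as in SAM
    cigar: str

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & 0x4)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & 0x10)

    def reference_span(self) -> GenomicInterval:
        """0-based half-open reference interval covered by this alignment."""
        if self.is_unmapped:
            raise InputError(f"read {self.qname} is unmapped")
        length = cigar_reference_length(self.cigar)
        return GenomicInterval(self.rname, self.pos - 1, self.pos - 1 + length)


class PhyloNode:
    """Node of a rooted binary phylogeny (children empty at leaves)."""

    __slots__ = ("label", "children", "parent")

    def __init__(self, label: str = "", parent: "PhyloNode | None" = None):
        self.label = label
        self.children: list[PhyloNode] = []
        self.parent = parent

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Phylogeny:
    """Rooted strictly binary tree with uniquely labeled leaves."""

    def __init__(self, root: PhyloNode):
        self.root = root
        labels = [n.label for n in self.leaves()]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate leaf labels in tree")
        for node in self.preorder():
            if node.children and len(node.children) != 2:
                raise ValidationError(
                    f"non-binary node with {len(node.children)} children; "
                    "resolve the polytomy upstream"
                )

    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self):
        out = list(self.preorder())
        return reversed(out)

    def leaves(self) -> list[PhyloNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def n_leaves(self) -> int:
        return len(self.leaves())


@dataclass(frozen=True)
class SecondaryStructure:
    """Vienna dot-bracket structure with its base-pair partner table."""

    dotbracket: str
    pair_table: dict[int, int]

    def __post_init__(self):
        for i, j in self.pair_table.items():
            if i == j or self.pair_table.get(j) != i:
                raise ValidationError("pair_table is not a self-free involution")

    def __len__(self) -> int:
        return len(self.dotbracket)

    def partner(self, i: int) -> int | None:
        return self.pair_table.get(i)

    @property
    def paired_sites(self) -> set[int]:
        return set(self.pair_table)


@dataclass
class ExpressionMatrix:
    """Samples x genes abundance matrix with a unit tag (FPKM or RPKMS)."""

    values: pd.DataFrame  # index = sample ids, columns = gene ids
    unit: str = "FPKM"

    def __post_init__(self):
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample or gene ids")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("negative abundance values")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# parsers
# ---------------------------------------------------------------------------

def _as_lines(stream) -> list[str]:
    if isinstance(stream, str):
        return stream.splitlines()
    return stream.read().splitlines()


def parse_fasta(stream) -> list[SequenceRecord]:
    """Parse (optionally aligned) FASTA text into SequenceRecords.

    Sequences are upper-cased; U is preserved as written; duplicate ids and
    characters outside {A,C,G,T,U,N,-} are rejected.
    """
    lines = _as_lines(stream)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    name: str | None = None
    chunks: list[str] = []

    def flush():
        if name is None:
            return
        rec = SequenceRecord(name, "".join(chunks).upper())
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(rec)

    for line in lines:
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].split()[0] if line[1:].strip() else ""
            chunks = []
        else:
            if name is None:
                raise FormatError("sequence data before first FASTA header")
            chunks.append(line)
    flush()
    if not records:
        raise FormatError("empty FASTA stream")
    return records


def write_fasta(records, width: int = 70) -> str:
    out = []
    for rec in records:
        out.append(f">{rec.id}")
        for i in range(0, len(rec.seq), width):
            out.append(rec.seq[i : i + width])
    return "\n".join(out) + "\n"


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for m in re.finditer(r'(\w+)\s+"([^"]*)"', text):
        attrs[m.group(1)] = m.group(2)
    return attrs


def parse_gtf_genes(stream) -> list[GeneModel]:
    """Group GTF exon features by gene_id into GeneModels.

    GTF coordinates are 1-based inclusive; they are converted to the internal
    0-based half-open convention on read.
    """
    exons_by_gene: dict[str, list[GenomicInterval]] = {}
    order: list[str] = []
    for lineno, line in enumerate(_as_lines(stream), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 9:
            raise FormatError(f"GTF line {lineno}: expected 9 tab-separated fields")
        chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
        if feature != "exon":
            continue
        try:
            start0, end0 = int(start) - 1, int(end)
        except ValueError as exc:
            raise FormatError(f"GTF line {lineno}: non-integer coordinates") from exc
        if start0 >= end0 or start0 < 0:
            raise FormatError(f"GTF line {lineno}: start > end after conversion")
        gene_id = _parse_gtf_attributes(attrs).get("gene_id")
        if not gene_id:
            raise FormatError(f"GTF line {lineno}: missing gene_id attribute")
        if gene_id not in exons_by_gene:
            order.append(gene_id)
        exons_by_gene.setdefault(gene_id, []).append(
            GenomicInterval(chrom, start0, end0, strand)
        )
    genes = []
    for gid in order:
        exons = sorted(exons_by_gene[gid], key=lambda e: (e.start, e.end))
        span = GenomicInterval(
            exons[0].chrom, exons[0].start, exons[-1].end, exons[0].strand
        )
        genes.append(GeneModel(gid, span, tuple(exons)))
    return genes


def write_gtf_genes(genes, source: str = "ltrkit") -> str:
    """Render GeneModels back to GTF (1-based inclusive)."""
    lines = []
    for g in genes:
        for ex in g.exons:
            lines.append(
                "\t".join(
                    [
                        ex.chrom,
                        source,
                        "exon",
                        str(ex.start + 1),
                        str(ex.end),
                        ".",
                        ex.strand,
                        ".",
                        f'gene_id "{g.gene_id}";',
                    ]
                )
            )
    return "\n".join(lines) + "\n"


def parse_bed(stream) -> list[GenomicInterval]:
    """Parse BED3+ lines; coordinates are already 0-based half-open."""
    intervals = []
    for lineno, line in enumerate(_as_lines(stream), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"BED line {lineno}: fewer than 3 columns")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise FormatError(f"BED line {lineno}: non-integer coordinates") from exc
        name = fields[3] if len(fields) > 3 else ""
        strand = fields[5] if len(fields) > 5 and fields[5] in STRANDS else "."
        try:
            intervals.append(GenomicInterval(fields[0], start, end, strand, name))
        except ValidationError as exc:
            raise FormatError(f"BED line {lineno}: {exc}") from exc
    return intervals


def write_bed(intervals) -> str:
    lines = []
    for iv in intervals:
        lines.append(
            f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}"
        )
    return "\n".join(lines) + "\n"


def cigar_reference_length(cigar: str) -> int:
    """Number of reference bases consumed by a CIGAR string."""
    if cigar == "*":
        return 0
    pos = 0
    length = 0
    for m in _CIGAR_RE.finditer(cigar):
        if m.start() != pos:
            raise FormatError(f"malformed CIGAR {cigar!r}")
        pos = m.end()
        if m.group(2) in _REF_CONSUMING:
            length += int(m.group(1))
    if pos != len(cigar):
        raise FormatError(f"malformed CIGAR {cigar!r}")
    return length


def parse_sam_min(stream) -> list[ReadAlignmentRecord]:
    """Parse minimal SAM text (columns 1-6); header lines are skipped.

    Unmapped records (flag 0x4) are retained and can be filtered by the
    caller; mapped records must have a reference-consuming CIGAR.
    """
    records = []
    for lineno, line in enumerate(_as_lines(stream), 1):
        if not line.strip() or line.startswith("@"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 6:
            raise FormatError(f"SAM line {lineno}: fewer than 6 columns")
        qname, flag, rname, pos, _mapq, cigar = fields[:6]
        try:
            rec = ReadAlignmentRecord(qname, int(flag), rname, int(pos), cigar)
        except ValueError as exc:
            raise FormatError(f"SAM line {lineno}: non-integer flag/pos") from exc
        if not rec.is_unmapped:
            if rec.pos < 1:
                raise FormatError(f"SAM line {lineno}: mapped record with pos < 1")
            if cigar_reference_length(cigar) < 1:
                raise FormatError(
                    f"SAM line {lineno}: mapped record consumes no reference"
                )
        records.append(rec)
    return records


def parse_newick(stream) -> Phylogeny:
    """Parse a rooted binary Newick tree; polytomies are rejected."""
    text = stream if isinstance(stream, str) else stream.read()
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"invalid Newick: {exc}") from exc

    def convert(dnode, parent):
        label = ""
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else (dnode.label or "")
            if not label:
                raise FormatError("unlabeled leaf in Newick tree")
        node = PhyloNode(label, parent)
        for child in dnode.child_nodes():
            node.children.append(convert(child, node))
        return node

    return Phylogeny(convert(dtree.seed_node, None))


def parse_dotbracket(text: str) -> SecondaryStructure:
    """Build a pair table from dot-bracket notation by stack matching."""
    text = text.strip()
    bad = set(text) - set("().")
    if bad:
        raise FormatError(f"invalid dot-bracket characters {sorted(bad)}")
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, ch in enumerate(text):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise FormatError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pairs[i], pairs[j] = j, i
    if stack:
        raise FormatError(f"unbalanced '(' at position {stack[-1]}")
    return SecondaryStructure(text, pairs)


def render_dotbracket(structure: SecondaryStructure) -> str:
    chars = ["."] * len(structure)
    for i, j in structure.pair_table.items():
        chars[i] = "(" if i < j else ")"
    return "".join(chars)


def read_matrix_tsv(stream, unit: str = "FPKM") -> ExpressionMatrix:
    """Read a TSV with gene ids in the header and sample ids in column one."""
    text = stream if isinstance(stream, str) else stream.read()
    try:
        df = pd.read_csv(io.StringIO(text), sep="\t", index_col=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"malformed TSV matrix: {exc}") from exc
    if df.empty:
        raise FormatError("empty expression matrix")
    body = df.to_numpy()
    if not np.issubdtype(body.dtype, np.number):
        raise FormatError("non-numeric values in expression matrix")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, unit=unit)


def write_matrix_tsv(matrix: ExpressionMatrix) -> str:
    return matrix.values.to_csv(sep="\t")
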