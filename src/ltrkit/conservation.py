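"""Structure-aware conservation analysis of an aligned locus on a phylogeny.

The procedure: (1) count per-column minimum substitution events with Fitch
parsimony on a fixed rooted binary tree, treating the alignment gap as a
fifth character state so indels register as changes; (2) contrast the number
of variable columns inside and outside base-paired (stem) regions of a fixed
secondary structure with a continuity-corrected chi-squared test; (3)
classify each stem substitution as compensatory (the post-substitution pair
is still canonical: GC/CG, AU/UA or GU/UG, with T == U) or non-compensatory;
(4) compare the observed compensatory fraction with the combinatorial null
in which each of the canonical pair types GC, GU and AU admits eight
single-position changes (three substitutions plus one deletion per partner),
24 outcomes in all, of which exactly four preserve canonical pairing
(probability 4/24 = 1/6).

Region-wise percent identity, GT..AG splice-junction conservation, and ORF
enumeration (including near-cognate CUG/GUG/UUG starts) round out the
locus-characterisation toolkit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .errors import InputError, ValidationError
from .expression_stats import (
    ContingencyTable2x2,
    TestResult,
    chi2_goodness_of_fit,
    chi2_independence,
)
from .io_formats import Phylogeny, PhyloNode, SecondaryStructure, SequenceRecord

GAP = "-"
#: Canonical base pairs (RNA view; T is normalised to U beforehand).
CANONICAL_PAIRS = {"GC", "CG", "AU", "UA", "GU", "UG"}
_STATE_ORDER = "-ACGU"  # alphabetical tie-break order for Fitch assignment


def _normalize(seq: str) -> str:
    return seq.upper().replace("T", "U")


def is_canonical(x: str, y: str) -> bool:
    """Canonical Watson-Crick or wobble pair; gaps never pair."""
    return (x + y) in CANONICAL_PAIRS


@dataclass
class MultiAlignment:
    """Equal-length aligned sequences keyed by species id (RNA alphabet)."""

    sequences: dict[str, str]

    def __post_init__(self):
        if not self.sequences:
            raise ValidationError("empty alignment")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValidationError("alignment rows differ in length")
        self.sequences = {k: _normalize(v) for k, v in self.sequences.items()}

    @classmethod
    def from_records(cls, records: list[SequenceRecord]) -> "MultiAlignment":
        return cls({r.id: r.seq for r in records})

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def species(self) -> list[str]:
        return list(self.sequences)

    def column(self, i: int) -> dict[str, str]:
        return {sp: seq[i] for sp, seq in self.sequences.items()}

    def subset(self, species: list[str]) -> "MultiAlignment":
        missing = set(species) - set(self.sequences)
        if missing:
            raise InputError(f"species not in alignment: {sorted(missing)}")
        return MultiAlignment({sp: self.sequences[sp] for sp in species})


@dataclass(frozen=True)
class SubstitutionEvent:
    """One inferred change on one branch at one alignment column."""

    site: int
    branch: tuple[str, str]  # (parent node id, child node id)
    from_state: str
    to_state: str

    def __post_init__(self):
        if self.from_state == self.to_state:
            raise ValidationError("event with identical states")

    @property
    def is_deletion(self) -> bool:
        return self.to_state == GAP


@dataclass(frozen=True)
class FitchResult:
    per_site_changes: tuple[int, ...]
    events: tuple[SubstitutionEvent, ...]
    #: most-parsimonious state assignment, node id -> sequence
    ancestral_states: dict[str, str]


@dataclass(frozen=True)
class PairClassification:
    n_compensatory: int
    n_noncompensatory: int
    n_pairs_affected: int
    n_locations: int

    @property
    def total(self) -> int:
        return self.n_compensatory + self.n_noncompensatory

    @property
    def compensatory_fraction(self) -> float:
        return self.n_compensatory / self.total if self.total else 0.0


@dataclass(frozen=True)
class NullSpec:
    """Outcome space of single-position random changes to canonical pairs."""

    per_pair_maintaining: dict[str, int]
    outcomes_per_pair: int
    total_outcomes: int
    maintaining_outcomes: int

    @property
    def maintaining_prob(self) -> float:
        return self.maintaining_outcomes / self.total_outcomes


def _node_ids(tree: Phylogeny) -> dict[PhyloNode, str]:
    """Stable ids: leaf labels for leaves, n0, n1, ... preorder for internals."""
    ids = {}
    counter = itertools.count()
    for node in tree.preorder():
        ids[node] = node.label if node.is_leaf else f"n{next(counter)}"
    return ids


def fitch_count(alignment: MultiAlignment, tree: Phylogeny) -> FitchResult:
    """Per-column minimum change counts and one most-parsimonious labeling.

    Bottom-up Fitch pass over 5 states (4 nucleotides + gap) counts a change
    at every empty set intersection; the top-down pass assigns the parent's
    state when possible and otherwise the alphabetically first member of the
    node's state set, and emits a SubstitutionEvent for every branch whose
    endpoints differ.
    """
    leaves = set(tree.leaf_labels())
    if leaves != set(alignment.species):
        raise InputError("tree leaf set does not match alignment species")
    ids = _node_ids(tree)
    n_cols = alignment.n_columns
    per_site = []
    events: list[SubstitutionEvent] = []
    assigned: dict[str, list[str]] = {ids[n]: [] for n in tree.preorder()}

    postorder = list(tree.postorder())
    preorder = list(tree.preorder())
    for col in range(n_cols):
        states: dict[PhyloNode, frozenset] = {}
        changes = 0
        for node in postorder:
            if node.is_leaf:
                states[node] = frozenset(alignment.sequences[node.label][col])
            else:
                left, right = (states[c] for c in node.children)
                inter = left & right
                if inter:
                    states[node] = inter
                else:
                    states[node] = left | right
                    changes += 1
        per_site.append(changes)
        # top-down assignment with deterministic tie-break
        for node in preorder:
            if node.parent is None:
                choice = min(states[node], key=_STATE_ORDER.index)
            else:
                parent_state = assigned[ids[node.parent]][col]
                if parent_state in states[node]:
                    choice = parent_state
                else:
                    choice = min(states[node], key=_STATE_ORDER.index)
                if choice != parent_state:
                    events.append(
                        SubstitutionEvent(
                            col, (ids[node.parent], ids[node]), parent_state, choice
                        )
                    )
            assigned[ids[node]].append(choice)

    ancestral = {nid: "".join(chars) for nid, chars in assigned.items()}
    return FitchResult(tuple(per_site), tuple(events), ancestral)


def structured_variability_test(
    per_site_changes,
    structure: SecondaryStructure,
) -> tuple[ContingencyTable2x2, TestResult]:
    """Contrast variable-site fractions between paired and unpaired positions.

    A site is variable iff its minimum change count is > 0.  Returns the 2x2
    (paired/unpaired x variable/invariant) table and the continuity-corrected
    chi-squared test on it.
    """
    changes = list(per_site_changes)
    if len(changes) != len(structure):
        raise InputError("structure length does not match number of sites")
    paired = structure.paired_sites
    pv = sum(1 for i, c in enumerate(changes) if c > 0 and i in paired)
    pi = sum(1 for i, c in enumerate(changes) if c == 0 and i in paired)
    uv = sum(1 for i, c in enumerate(changes) if c > 0 and i not in paired)
    ui = sum(1 for i, c in enumerate(changes) if c == 0 and i not in paired)
    table = ContingencyTable2x2(pv, pi, uv, ui)
    return table, chi2_independence(table, continuity=True)


def classify_substitutions(
    events,
    structure: SecondaryStructure,
    ancestral_states: dict[str, str],
) -> PairClassification:
    """Classify stem substitutions as compensatory or pairing-disrupting.

    An event at a paired site is compensatory iff it maintains base pairing:
    the pair must be canonical both in the parent and, after the change, in
    the child node (states at the site and its partner in each node).
    Requiring the parent pair to be canonical keeps the classification
    invariant under the direction ambiguity of parsimony reconstruction on
    the root edge — the reversal of a pairing-breaking change reads as a
    "restoration" with a non-canonical parent pair and stays
    non-compensatory.  Deletions never pair, hence are never compensatory.
    n_pairs_affected counts distinct (pair location, branch) combinations;
    n_locations counts distinct pair locations.
    """
    n_comp = 0
    n_noncomp = 0
    pairs_affected: set[tuple[int, int, tuple[str, str]]] = set()
    locations: set[tuple[int, int]] = set()
    for ev in events:
        partner = structure.partner(ev.site)
        if partner is None:
            raise InputError(f"event at unpaired site {ev.site}")
        parent_id, child_id = ev.branch
        if child_id not in ancestral_states or parent_id not in ancestral_states:
            raise InputError(f"no ancestral states for branch {ev.branch!r}")
        child_seq = ancestral_states[child_id]
        parent_seq = ancestral_states[parent_id]
        maintained = is_canonical(
            parent_seq[ev.site], parent_seq[partner]
        ) and is_canonical(child_seq[ev.site], child_seq[partner])
        if maintained:
            n_comp += 1
        else:
            n_noncomp += 1
        loc = (min(ev.site, partner), max(ev.site, partner))
        locations.add(loc)
        pairs_affected.add((loc[0], loc[1], ev.branch))
    return PairClassification(n_comp, n_noncomp, len(pairs_affected), len(locations))


def null_enumeration() -> NullSpec:
    """Exhaustive single-change outcome space over GC, GU and AU pairs.

    Each pair admits 8 changes: 3 substitutions + 1 deletion at each partner.
    Counts how many of the 24 outcomes leave a canonical pair.
    """
    per_pair = {}
    total = 0
    maintaining = 0
    for pair in ("GC", "GU", "AU"):
        keep = 0
        n_outcomes = 0
        for pos in (0, 1):
            current = pair[pos]
            others = [b for b in "ACGU" if b != current] + [GAP]
            for new in others:
                n_outcomes += 1
                mutated = (new + pair[1]) if pos == 0 else (pair[0] + new)
                if GAP not in mutated and mutated in CANONICAL_PAIRS:
                    keep += 1
        per_pair[pair] = keep
        total += n_outcomes
        maintaining += keep
    return NullSpec(per_pair, 8, total, maintaining)


def compensatory_test(
    classification: PairClassification, null: NullSpec | None = None
) -> TestResult:
    """Goodness-of-fit of observed compensatory/non-compensatory counts to the
    combinatorial null proportions (4/24 maintaining)."""
    if classification.total < 1:
        raise InputError("no stem substitutions to test")
    if null is None:
        null = null_enumeration()
    p_maint = null.maintaining_prob
    return chi2_goodness_of_fit(
        [classification.n_compensatory, classification.n_noncompensatory],
        [p_maint, 1.0 - p_maint],
    )


def region_identity(
    alignment: MultiAlignment,
    regions: dict[str, tuple[int, int]],
    reference_species: str,
) -> dict[str, dict[str, float]]:
    """Percent identity of every species to the reference, per region.

    Regions are half-open column ranges.  A column with a gap in either
    sequence counts as non-matching; identity = matches / region width * 100.
    """
    if reference_species not in alignment.sequences:
        raise InputError(f"reference {reference_species!r} not in alignment")
    ref = alignment.sequences[reference_species]
    out: dict[str, dict[str, float]] = {}
    for name, (lo, hi) in regions.items():
        if not (0 <= lo < hi <= alignment.n_columns):
            raise InputError(f"region {name!r} out of range or empty")
        out[name] = {}
        for sp, seq in alignment.sequences.items():
            matches = sum(
                1
                for i in range(lo, hi)
                if ref[i] != GAP and seq[i] != GAP and ref[i] == seq[i]
            )
            out[name][sp] = 100.0 * matches / (hi - lo)
    return out


def splice_junction_check(
    alignment: MultiAlignment,
    introns: dict[str, tuple[int, int]],
) -> dict[str, dict[str, str]]:
    """Per-species GT..AG (GU..AG) splice-junction conservation per intron.

    The donor is the first two non-gap characters of the intron range, the
    acceptor the last two; species with fewer than 4 non-gap intron
    characters are flagged 'undetermined'.
    """
    out: dict[str, dict[str, str]] = {}
    for name, (lo, hi) in introns.items():
        if hi - lo < 4:
            raise InputError(f"intron {name!r} shorter than 4 columns")
        out[name] = {}
        for sp, seq in alignment.sequences.items():
            chars = [c for c in seq[lo:hi] if c != GAP]
            if len(chars) < 4:
                out[name][sp] = "undetermined"
                continue
            donor = "".join(chars[:2])
            acceptor = "".join(chars[-2:])
            ok = donor == "GU" and acceptor == "AG"
            out[name][sp] = "conserved" if ok else "not_conserved"
    return out


START_CODON = "AUG"
NEAR_COGNATE_STARTS = ("CUG", "GUG", "UUG")
STOP_CODONS = {"UAA", "UAG", "UGA"}


@dataclass(frozen=True)
class Orf:
    start: int  # 0-based, inclusive
    end: int  # 0-based, exclusive (includes stop codon when complete)
    frame: int
    start_codon: str
    complete: bool

    @property
    def n_codons(self) -> int:
        """Codons spanned, including the stop codon when complete."""
        return (self.end - self.start) // 3


def find_orfs(
    seq: SequenceRecord,
    min_codons: int = 10,
    allow_near_cognate: bool = False,
) -> list[Orf]:
    """Enumerate maximal ORFs in the three forward frames.

    An ORF runs from a start codon (AUG, plus CUG/GUG/UUG when near-cognate
    starts are allowed) to the first in-frame stop; within each frame only
    the first start after the previous stop opens an ORF (maximal ORFs).  An
    ORF reaching the sequence end without a stop is reported as incomplete.
    """
    s = _normalize(seq.seq)
    starts = {START_CODON}
    if allow_near_cognate:
        starts |= set(NEAR_COGNATE_STARTS)
    orfs: list[Orf] = []
    for frame in range(3):
        open_at: int | None = None
        open_codon = ""
        for i in range(frame, len(s) - 2, 3):
            codon = s[i : i + 3]
            if open_at is None:
                if codon in starts:
                    open_at, open_codon = i, codon
            elif codon in STOP_CODONS:
                n_codons = (i + 3 - open_at) // 3
                if n_codons >= min_codons:
                    orfs.append(Orf(open_at, i + 3, frame, open_codon, True))
                open_at = None
        if open_at is not None:
            end = frame + 3 * ((len(s) - frame) // 3)
            if (end - open_at) // 3 >= min_codons:
                orfs.append(Orf(open_at, end, frame, open_codon, False))
    return sorted(orfs, key=lambda o: (o.start, o.frame))
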