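"""Fitch counting against a brute-force oracle, compensatory classification,
the combinatorial null, identities, splice junctions and ORFs."""

import itertools

import numpy as np
import pytest

from ltrkit.conservation import (
    GAP,
    MultiAlignment,
    classify_substitutions,
    compensatory_test,
    find_orfs,
    fitch_count,
    is_canonical,
    null_enumeration,
    region_identity,
    splice_junction_check,
    structured_variability_test,
)
from ltrkit.errors import DegenerateTableError, InputError
from ltrkit.io_formats import SequenceRecord, parse_dotbracket, parse_newick


def brute_force_min_changes(tree, leaf_states: dict) -> int:
    """Oracle: minimum changes over all ancestral labelings, by enumeration."""
    internals = [n for n in tree.preorder() if not n.is_leaf]
    states = "-ACGU"
    best = None
    for combo in itertools.product(states, repeat=len(internals)):
        labeling = dict(zip((id(n) for n in internals), combo))
        for leaf in tree.leaves():
            labeling[id(leaf)] = leaf_states[leaf.label]
        changes = sum(
            1
            for node in tree.preorder()
            if node.parent is not None
            and labeling[id(node)] != labeling[id(node.parent)]
        )
        best = changes if best is None else min(best, changes)
    return best


class TestFitch:
    @pytest.mark.parametrize(
        "column,expected",
        [("AAAA", 0), ("AAGG", 1), ("AGAG", 2), ("ACGU", 3), ("AA-A", 1)],
    )
    def test_quartet_columns(self, quartet_tree, column, expected):
        aln = MultiAlignment(dict(zip("ABCD", column)))
        res = fitch_count(aln, quartet_tree)
        assert res.per_site_changes == (expected,)

    def test_events_per_site_match_counts(self, quartet_tree):
        aln = MultiAlignment({"A": "AG", "B": "AG", "C": "GG", "D": "GA"})
        res = fitch_count(aln, quartet_tree)
        for site, count in enumerate(res.per_site_changes):
            assert sum(1 for e in res.events if e.site == site) == count

    def test_leaf_mismatch_rejected(self, quartet_tree):
        with pytest.raises(InputError):
            fitch_count(MultiAlignment({"A": "A", "B": "A", "X": "A", "D": "A"}),
                        quartet_tree)

    @pytest.mark.parametrize("newick", [
        "((A,B),(C,D));",
        "(((A,B),C),(D,E));",
        "(((A,B),(C,D)),(E,F));",
    ])
    def test_matches_brute_force_oracle(self, newick):
        tree = parse_newick(newick)
        labels = tree.leaf_labels()
        rng = np.random.default_rng(17)
        states = list("-ACGU")
        for _ in range(40):
            column = {lab: states[rng.integers(5)] for lab in labels}
            aln = MultiAlignment({k: v for k, v in column.items()})
            got = fitch_count(aln, tree).per_site_changes[0]
            assert got == brute_force_min_changes(tree, column)

    def test_reconstruction_changes_equal_fitch_minimum(self):
        # the emitted event list realises exactly the per-site minimum
        tree = parse_newick("(((A,B),(C,D)),(E,F));")
        rng = np.random.default_rng(23)
        chars = list("ACGU")
        seqs = {lab: "".join(chars[rng.integers(4)] for _ in range(30))
                for lab in tree.leaf_labels()}
        res = fitch_count(MultiAlignment(seqs), tree)
        assert len(res.events) == sum(res.per_site_changes)


class TestStructuredVariability:
    def test_published_counts_give_published_p(self):
        changes = [1] * 39 + [0] * 203 + [1] * 47 + [0] * 105
        db = "(" * 121 + ")" * 121 + "." * 152
        structure = parse_dotbracket(db)
        table, res = structured_variability_test(changes, structure)
        assert (table.a, table.b, table.c, table.d) == (39, 203, 47, 105)
        assert res.p == pytest.approx(8e-4, rel=0.12)

    def test_margins_sum_to_length(self):
        rng = np.random.default_rng(4)
        changes = rng.integers(0, 3, size=20)
        structure = parse_dotbracket("((((....))))" + "." * 8)
        table, _ = structured_variability_test(changes, structure)
        assert table.total == 20

    def test_all_invariant_degenerate(self, hairpin):
        with pytest.raises(DegenerateTableError):
            structured_variability_test([0] * 16, hairpin)

    def test_no_paired_sites_degenerate(self):
        structure = parse_dotbracket("....")
        with pytest.raises(DegenerateTableError):
            structured_variability_test([1, 0, 1, 0], structure)

    def test_length_mismatch(self, hairpin):
        with pytest.raises(InputError):
            structured_variability_test([0, 1], hairpin)


def make_events_and_states(structure, specs):
    """Build SubstitutionEvents plus parent/child sequences from tuples
    (site, parent_seq, child_seq, branch)."""
    from ltrkit.conservation import SubstitutionEvent

    events = []
    states = {}
    for site, parent_seq, child_seq, branch in specs:
        events.append(
            SubstitutionEvent(site, branch, parent_seq[site], child_seq[site])
        )
        states[branch[0]] = parent_seq
        states[branch[1]] = child_seq
    return events, states


class TestClassification:
    STRUCT = parse_dotbracket("((....))")  # pairs 0-7, 1-6

    def test_gc_to_gu_compensatory(self):
        events, states = make_events_and_states(
            self.STRUCT, [(7, "GAAAAAAC", "GAAAAAAU", ("p", "c"))]
        )
        cls = classify_substitutions(events, self.STRUCT, states)
        assert (cls.n_compensatory, cls.n_noncompensatory) == (1, 0)

    def test_au_to_ac_noncompensatory(self):
        events, states = make_events_and_states(
            self.STRUCT, [(7, "AAAAAAAU", "AAAAAAAC", ("p", "c"))]
        )
        cls = classify_substitutions(events, self.STRUCT, states)
        assert (cls.n_compensatory, cls.n_noncompensatory) == (0, 1)

    def test_gu_to_au_compensatory(self):
        events, states = make_events_and_states(
            self.STRUCT, [(0, "GAAAAAAU", "AAAAAAAU", ("p", "c"))]
        )
        assert classify_substitutions(events, self.STRUCT, states).n_compensatory == 1

    def test_deletion_never_compensatory(self):
        events, states = make_events_and_states(
            self.STRUCT, [(0, "GAAAAAAC", "-AAAAAAC", ("p", "c"))]
        )
        cls = classify_substitutions(events, self.STRUCT, states)
        assert cls.n_noncompensatory == 1

    def test_restoration_of_broken_pair_not_compensatory(self):
        # parent pair AC (non-canonical); child pair AU: not "maintaining"
        events, states = make_events_and_states(
            self.STRUCT, [(7, "AAAAAAAC", "AAAAAAAU", ("p", "c"))]
        )
        assert classify_substitutions(events, self.STRUCT, states).n_compensatory == 0

    def test_pair_and_location_bookkeeping(self):
        # two events on the same base pair, at its two sites, on two branches
        events, states = make_events_and_states(
            self.STRUCT,
            [
                (0, "GAAAAAAC", "AAAAAAAC", ("p", "c1")),
                (7, "GAAAAAAC", "GAAAAAAU", ("p", "c2")),
            ],
        )
        cls = classify_substitutions(events, self.STRUCT, states)
        assert cls.n_pairs_affected == 2
        assert cls.n_locations == 1
        assert cls.n_locations <= cls.n_pairs_affected <= cls.total

    def test_unpaired_site_rejected(self):
        events, states = make_events_and_states(
            self.STRUCT, [(3, "GAAAAAAC", "GAACAAAC", ("p", "c"))]
        )
        with pytest.raises(InputError):
            classify_substitutions(events, self.STRUCT, states)


class TestNullEnumeration:
    def test_totals(self):
        null = null_enumeration()
        assert null.total_outcomes == 24
        assert null.maintaining_outcomes == 4
        assert null.outcomes_per_pair == 8
        assert null.maintaining_prob == pytest.approx(4 / 24)

    def test_per_pair_split(self):
        null = null_enumeration()
        assert null.per_pair_maintaining == {"GC": 1, "AU": 1, "GU": 2}

    def test_matches_independent_enumeration(self):
        # second, direct enumeration over explicit outcomes
        total = maintaining = 0
        for x, y in ("GC", "GU", "AU"):
            for pos, base in ((0, x), (1, y)):
                for new in [b for b in "ACGU" if b != base] + [GAP]:
                    total += 1
                    pair = (new, y) if pos == 0 else (x, new)
                    if GAP not in pair and is_canonical(*pair):
                        maintaining += 1
        null = null_enumeration()
        assert (total, maintaining) == (
            null.total_outcomes, null.maintaining_outcomes
        )


class TestCompensatoryTest:
    def test_published_counts(self):
        from ltrkit.conservation import PairClassification

        res = compensatory_test(PairClassification(19, 20, 32, 27))
        assert res.p == pytest.approx(7.8e-8, rel=0.05)

    def test_exact_expectation_gives_p_one(self):
        from ltrkit.conservation import PairClassification

        res = compensatory_test(PairClassification(13, 65, 78, 78))
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_zero_events_rejected(self):
        from ltrkit.conservation import PairClassification

        with pytest.raises(InputError):
            compensatory_test(PairClassification(0, 0, 0, 0))


class TestRegionIdentity:
    def test_identical_rows(self):
        aln = MultiAlignment({"h": "ACGUACGU", "m": "ACGUACGU"})
        out = region_identity(aln, {"all": (0, 8)}, "h")
        assert out["all"]["m"] == pytest.approx(100.0)

    def test_gap_counts_as_mismatch(self):
        aln = MultiAlignment({"h": "ACGU", "m": "AC-U"})
        out = region_identity(aln, {"r": (0, 4)}, "h")
        assert out["r"]["m"] == pytest.approx(75.0)

    def test_symmetry(self):
        aln = MultiAlignment({"h": "ACGU-CGU", "m": "ACAUAC-U"})
        a = region_identity(aln, {"r": (0, 8)}, "h")["r"]["m"]
        b = region_identity(aln, {"r": (0, 8)}, "m")["r"]["h"]
        assert a == pytest.approx(b)
        assert 0.0 <= a <= 100.0

    def test_all_gap_region_zero(self):
        aln = MultiAlignment({"h": "AC--GU", "m": "AC--GU"})
        assert region_identity(aln, {"r": (2, 4)}, "h")["r"]["m"] == 0.0

    def test_empty_region_rejected(self):
        aln = MultiAlignment({"h": "ACGU"})
        with pytest.raises(InputError):
            region_identity(aln, {"r": (2, 2)}, "h")


class TestSpliceJunctions:
    def test_canonical_conserved(self):
        aln = MultiAlignment({"h": "AAGUAAGCCAAGAA"})
        out = splice_junction_check(aln, {"i1": (2, 12)})
        assert out["i1"]["h"] == "conserved"

    def test_gc_donor_not_conserved(self):
        aln = MultiAlignment({"h": "AAGCAAGCCAAGAA"})
        assert splice_junction_check(aln, {"i1": (2, 12)})["i1"]["h"] == "not_conserved"

    def test_leading_gaps_skipped(self):
        aln = MultiAlignment({"h": "AA--GUACAGAGAA"})
        assert splice_junction_check(aln, {"i1": (2, 12)})["i1"]["h"] == "conserved"

    def test_too_short_undetermined(self):
        aln = MultiAlignment({"h": "AA--------GAAA", "m": "AAGUAAGCCAAGAA"})
        out = splice_junction_check(aln, {"i1": (2, 12)})
        assert out["i1"]["h"] == "undetermined"
        assert out["i1"]["m"] == "conserved"


class TestOrfs:
    def test_simple_orf(self):
        orfs = find_orfs(SequenceRecord("s", "ATGAAATAG"), min_codons=3)
        assert len(orfs) == 1
        orf = orfs[0]
        assert (orf.start, orf.end, orf.frame) == (0, 9, 0)
        assert orf.n_codons == 3 and orf.complete

    def test_near_cognate_flag(self):
        seq = SequenceRecord("s", "CTGAAATAG")
        assert find_orfs(seq, min_codons=3) == []
        orfs = find_orfs(seq, min_codons=3, allow_near_cognate=True)
        assert len(orfs) == 1 and orfs[0].start_codon == "CUG"

    def test_open_ended_orf_flagged_incomplete(self):
        orfs = find_orfs(SequenceRecord("s", "ATGAAAAAAAAA"), min_codons=3)
        assert len(orfs) == 1
        assert not orfs[0].complete
        assert orfs[0].end == 12

    def test_multiple_frames_scanned(self):
        # AUG..stop in frame 1 (offset 1) and frame 2 (offset 11)
        orfs = find_orfs(SequenceRecord("s", "AATGAAATAGCATGAAATAGC"), min_codons=3)
        assert {o.frame for o in orfs} == {1, 2}
        assert len(orfs) == 2
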