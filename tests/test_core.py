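"""The six algorithm steps: pattern extraction, noise filtering, merging,
subgenome assignment, base election and finalization."""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from homeocall import (
    AlignedFragment,
    CoreConfig,
    DiploidProfile,
    GenomicPosition,
    HSPRecord,
    assign_bases_to_subgenomes,
    assign_patterns_to_subgenomes,
    extract_base_patterns,
    filter_rare_basepairs,
    finalize_assignments,
    merge_overlapping_patterns,
    remove_embedded_patterns,
)
from homeocall.core import BasePattern, _elect

CFG = CoreConfig()
P = lambda pos: GenomicPosition("ref", pos)


def pat(pairs, support=1, gene="g1"):
    return BasePattern(gene, "ref", tuple(sorted(pairs)), support)


def hsp(pos, ref="A", observed=("A", "C", "G", "T")):
    return HSPRecord(P(pos), ref, set(observed))


def profile(label, bases):
    return DiploidProfile(label, {P(p): b for p, b in bases.items()})


# ---------------------------------------------------------------------------
# Step 1


class TestExtractPatterns:
    HSPS = {"g1": [hsp(101), hsp(150)]}

    def test_pairs_at_covered_hsp_positions(self):
        frag = AlignedFragment.from_bases(
            "r1", "g1", "ref", {100: "T", 101: "A", 120: "G", 150: "C"}
        )
        (p,) = extract_base_patterns([frag], self.HSPS)
        assert p.pairs == ((101, "A"), (150, "C"))
        assert p.support == 1

    def test_identical_fragments_collapse_with_summed_support(self):
        frags = [
            AlignedFragment.from_bases(f"r{i}", "g1", "ref", {101: "A", 150: "C"})
            for i in range(2)
        ]
        (p,) = extract_base_patterns(frags, self.HSPS)
        assert p.support == 2

    def test_non_acgt_base_at_hsp_omitted(self):
        frag = AlignedFragment.from_bases("r1", "g1", "ref", {101: "N", 150: "C"})
        (p,) = extract_base_patterns([frag], self.HSPS)
        assert p.pairs == ((150, "C"),)

    def test_fragment_covering_no_hsp_yields_nothing(self):
        frag = AlignedFragment.from_bases("r1", "g1", "ref", {120: "G"})
        assert extract_base_patterns([frag], self.HSPS) == []


# ---------------------------------------------------------------------------
# Step 2


class TestRareBasepairFilter:
    HSPS = {"g1": [hsp(1), hsp(2)]}

    def test_rare_combination_removes_its_patterns(self):
        patterns = [pat([(1, "A"), (2, "C")], support=97), pat([(1, "A"), (2, "G")], support=3)]
        out = filter_rare_basepairs(patterns, self.HSPS, CFG)
        assert [p.pairs for p in out] == [((1, "A"), (2, "C"))]

    def test_balanced_combinations_all_survive(self):
        patterns = [pat([(1, "A"), (2, "C")], support=50), pat([(1, "G"), (2, "T")], support=50)]
        assert len(filter_rare_basepairs(patterns, self.HSPS, CFG)) == 2

    def test_exactly_at_threshold_survives(self):
        # 5 of 100 is not "less than 5%"
        patterns = [pat([(1, "A"), (2, "C")], support=95), pat([(1, "A"), (2, "G")], support=5)]
        assert len(filter_rare_basepairs(patterns, self.HSPS, CFG)) == 2

    def test_single_position_patterns_never_removed(self):
        patterns = [pat([(1, "A")], support=1), pat([(1, "C"), (2, "G")], support=99)]
        out = filter_rare_basepairs(patterns, self.HSPS, CFG)
        assert len(out) == 2


class TestEmbeddedRemoval:
    def test_subset_pattern_removed_support_discarded(self):
        p_small = pat([(1, "A")], support=5)
        p_big = pat([(1, "A"), (2, "C")], support=3)
        out = remove_embedded_patterns([p_small, p_big])
        assert out == [p_big]
        assert p_big.support == 3

    def test_base_mismatch_is_not_embedding(self):
        patterns = [pat([(1, "G")]), pat([(1, "A"), (2, "C")])]
        assert len(remove_embedded_patterns(patterns)) == 2

    def test_chain_of_subsets_keeps_only_maximal(self):
        p1 = pat([(1, "A")])
        p2 = pat([(1, "A"), (2, "C")])
        p3 = pat([(1, "A"), (2, "C"), (3, "G")])
        assert remove_embedded_patterns([p1, p2, p3]) == [p3]

    def test_different_genes_never_embed(self):
        p1 = pat([(1, "A")], gene="g1")
        p2 = pat([(1, "A"), (2, "C")], gene="g2")
        assert len(remove_embedded_patterns([p1, p2])) == 2


# ---------------------------------------------------------------------------
# Step 3


class TestMerging:
    def test_overlap_of_two_merges_into_union(self):
        p = pat([(1, "A"), (2, "C"), (3, "G")], support=2)
        q = pat([(2, "C"), (3, "G"), (4, "T")], support=3)
        (m,) = merge_overlapping_patterns([p, q], CFG)
        assert m.pairs == ((1, "A"), (2, "C"), (3, "G"), (4, "T"))
        assert m.support == 5

    def test_conflicting_shared_position_blocks_merge(self):
        p = pat([(1, "A"), (2, "C")])
        q = pat([(2, "G"), (3, "T")])
        out = merge_overlapping_patterns([p, q], CFG)
        assert sorted(m.pairs for m in out) == sorted([p.pairs, q.pairs])

    def test_chain_merges_to_single_spanning_pattern(self):
        p = pat([(1, "A"), (2, "C")], support=1)
        q = pat([(2, "C"), (3, "G")], support=1)
        r = pat([(3, "G"), (4, "T")], support=1)
        (m,) = merge_overlapping_patterns([p, q, r], CFG)
        assert m.pairs == ((1, "A"), (2, "C"), (3, "G"), (4, "T"))
        assert m.support == 3

    def test_longest_overlap_merged_first(self):
        # overlap(p,q)=2 beats overlap(p,r)=1; all three coalesce eventually
        p = pat([(1, "A"), (2, "C"), (3, "G")])
        q = pat([(2, "C"), (3, "G"), (4, "T")])
        r = pat([(1, "A"), (5, "T")])
        out = merge_overlapping_patterns([p, q, r], CFG)
        (m,) = out
        assert m.pairs == ((1, "A"), (2, "C"), (3, "G"), (4, "T"), (5, "T"))

    def test_min_overlap_two_blocks_single_shared_position(self):
        cfg = CoreConfig(min_overlap=2)
        p = pat([(1, "A"), (2, "C")])
        q = pat([(2, "C"), (3, "G")])
        assert len(merge_overlapping_patterns([p, q], cfg)) == 2


@st.composite
def random_patterns(draw):
    n = draw(st.integers(min_value=1, max_value=8))
    haplotypes = {
        1: ("A", "G"), 2: ("C", "T"), 3: ("G", "A"), 4: ("T", "C"), 5: ("A", "C"),
    }
    patterns = []
    for i in range(n):
        positions = draw(
            st.sets(st.integers(min_value=1, max_value=5), min_size=1, max_size=5)
        )
        hap = draw(st.integers(min_value=0, max_value=1))
        pairs = tuple(sorted((p, haplotypes[p][hap]) for p in positions))
        patterns.append(BasePattern("g1", "ref", pairs, draw(st.integers(1, 5))))
    return patterns


@settings(max_examples=60, derandomize=True)
@given(random_patterns())
def test_merge_invariants(patterns):
    """Support is conserved, the result is pairwise non-mergeable, and every
    input pattern is contained in exactly one output pattern."""
    total_support = sum(p.support for p in patterns)
    originals = [frozenset(p.pairs) for p in patterns]
    out = merge_overlapping_patterns(patterns, CFG)
    assert sum(p.support for p in out) == total_support
    from homeocall.core import _overlap

    for i, a in enumerate(out):
        for b in out[i + 1 :]:
            assert _overlap(a, b, CFG.min_overlap) == 0
    for orig in originals:
        containers = [m for m in out if orig <= frozenset(m.pairs)]
        assert len(containers) == 1


# ---------------------------------------------------------------------------
# Step 4


class TestPatternAssignment:
    def test_identity_is_matches_over_informative(self):
        p = pat([(1, "A"), (2, "C"), (3, "G"), (4, "T")])
        profiles = {"s1": profile("s1", {1: "A", 2: "C", 3: "G", 4: "A"})}
        assign_patterns_to_subgenomes([p], profiles, None, CFG)
        assert p.identity["s1"] == Fraction(75)
        assert p.assigned_to == {"s1"}

    def test_exactly_half_matches_is_assigned(self):
        p = pat([(1, "A"), (2, "C")])
        profiles = {"s1": profile("s1", {1: "A", 2: "T"})}
        assign_patterns_to_subgenomes([p], profiles, None, CFG)
        assert p.assigned_to == {"s1"}

    def test_non_concrete_profile_states_not_informative(self):
        p = pat([(1, "A"), (2, "C")])
        profiles = {"s1": DiploidProfile("s1", {P(1): "A", P(2): "*"})}
        assign_patterns_to_subgenomes([p], profiles, None, CFG)
        assert p.identity["s1"] == Fraction(100)

    def test_low_identity_everywhere_falls_to_missing(self):
        p = pat([(1, "A"), (2, "C"), (3, "G"), (4, "T"), (5, "A")])
        profiles = {
            "s1": profile("s1", {1: "G", 2: "T", 3: "A", 4: "T", 5: "C"}),  # 20%
            "s2": profile("s2", {1: "G", 2: "T", 3: "C", 4: "C", 5: "C"}),  # 0%
            "s3": DiploidProfile("s3", is_missing=True),
        }
        assign_patterns_to_subgenomes([p], profiles, "s3", CFG)
        assert p.assigned_to == {"s3"}

    def test_no_informative_positions_and_no_missing_leaves_unassigned(self):
        p = pat([(1, "A")])
        profiles = {"s1": DiploidProfile("s1", {P(1): "0"})}
        assign_patterns_to_subgenomes([p], profiles, None, CFG)
        assert p.identity["s1"] is None
        assert p.assigned_to == set()

    def test_pattern_may_be_assigned_to_several_subgenomes(self):
        p = pat([(1, "A"), (2, "C")])
        profiles = {
            "s1": profile("s1", {1: "A", 2: "C"}),
            "s2": profile("s2", {1: "A", 2: "T"}),
        }
        assign_patterns_to_subgenomes([p], profiles, None, CFG)
        assert p.assigned_to == {"s1", "s2"}


@settings(max_examples=50, derandomize=True)
@given(
    matches=st.lists(st.integers(min_value=0, max_value=6), min_size=1, max_size=6),
    lo=st.floats(min_value=0.05, max_value=0.5),
    hi=st.floats(min_value=0.5, max_value=0.95),
)
def test_raising_identity_min_never_adds_assignments(matches, lo, hi):
    """Pre-finalization monotonicity: a stricter identity threshold can only
    shrink the set of (pattern, subgenome) assignments."""
    profs = {"s1": profile("s1", {i + 1: "A" for i in range(6)})}
    counts = {}
    for threshold, key in ((lo, "lo"), (hi, "hi")):
        patterns = [
            # pattern k matches s1 at exactly m of its 6 positions
            pat([(i + 1, "A" if i < m else "C") for i in range(6)])
            for m in matches
        ]
        assign_patterns_to_subgenomes(
            patterns, profs, None, CoreConfig(identity_min=threshold)
        )
        counts[key] = sum(len(p.assigned_to) for p in patterns)
    assert counts["hi"] <= counts["lo"]


# ---------------------------------------------------------------------------
# Step 5


def assigned(pairs, support=1, ident=None, to=()):
    p = pat(pairs, support)
    p.identity = {k: (Fraction(v) if v is not None else None) for k, v in (ident or {}).items()}
    p.assigned_to = set(to)
    return p


class TestBaseElection:
    HSPS = [hsp(1), hsp(2)]

    def test_max_mode_picks_highest_identity_pattern(self):
        patterns = [
            assigned([(1, "A")], ident={"s1": 80}, to=["s1"]),
            assigned([(1, "G")], ident={"s1": 60}, to=["s1"]),
        ]
        calls = assign_bases_to_subgenomes(patterns, self.HSPS, CFG, subgenomes=["s1"])
        assert calls.call(P(1), "s1") == "A"

    def test_additive_mode_sums_identities_per_base(self):
        cfg = CoreConfig(mode="additive")
        patterns = [
            assigned([(1, "A")], ident={"s1": 60}, to=["s1"]),
            assigned([(1, "A")], ident={"s1": 55}, to=["s1"]),
            assigned([(1, "G")], ident={"s1": 90}, to=["s1"]),
        ]
        calls = assign_bases_to_subgenomes(patterns, self.HSPS, cfg, subgenomes=["s1"])
        assert calls.call(P(1), "s1") == "A"

    def test_exact_tie_elects_nothing(self):
        patterns = [
            assigned([(1, "A")], ident={"s1": 70}, to=["s1"]),
            assigned([(1, "G")], ident={"s1": 70}, to=["s1"]),
        ]
        calls = assign_bases_to_subgenomes(patterns, self.HSPS, CFG, subgenomes=["s1"])
        assert calls.call(P(1), "s1") is None

    def test_conflicting_pattern_removed_after_election(self):
        winner = assigned([(1, "A"), (2, "C")], ident={"s1": 90}, to=["s1"])
        loser = assigned([(2, "G")], ident={"s1": 60}, to=["s1"])
        calls = assign_bases_to_subgenomes([winner, loser], self.HSPS, CFG, subgenomes=["s1"])
        assert calls.call(P(2), "s1") == "C"
        assert loser.state == "removed"
        assert winner.state == "active"

    def test_base_outside_observed_set_not_electable(self):
        hsps = [HSPRecord(P(1), "A", {"A", "G"})]
        patterns = [assigned([(1, "T")], ident={"s1": 99}, to=["s1"])]
        calls = assign_bases_to_subgenomes(patterns, hsps, CFG, subgenomes=["s1"])
        assert calls.call(P(1), "s1") is None

    def test_missing_subgenome_scored_by_distance_from_present_diploids(self):
        # the pattern least like the present diploid wins the missing slot
        patterns = [
            assigned([(1, "G")], ident={"s1": Fraction(0)}, to=["s2"]),
            assigned([(1, "T")], ident={"s1": Fraction(40)}, to=["s2"]),
        ]
        calls = assign_bases_to_subgenomes(
            patterns, self.HSPS, CFG, missing="s2", subgenomes=["s1", "s2"]
        )
        assert calls.call(P(1), "s2") == "G"


def _oracle_elect(patterns, observed_at, mode, subgenomes):
    """Independent brute-force election (no missing subgenome)."""
    result = {}
    for position, observed in observed_at.items():
        for sub in subgenomes:
            per_base = {}
            for p in patterns:
                if p.state != "active" or sub not in p.assigned_to:
                    continue
                ident = p.identity.get(sub)
                if ident is None:
                    continue
                for pos, base in p.pairs:
                    if pos == position.pos and base in observed:
                        per_base.setdefault(base, []).append(ident)
            winner = None
            if per_base:
                agg = {
                    b: (max(v) if mode == "max" else sum(v)) for b, v in per_base.items()
                }
                strictly_best = [
                    b for b, s in agg.items() if all(s > s2 for b2, s2 in agg.items() if b2 != b)
                ]
                winner = strictly_best[0] if len(strictly_best) == 1 else None
            result[(position, sub)] = winner
    return result


@st.composite
def election_instances(draw):
    n = draw(st.integers(min_value=1, max_value=6))
    patterns = []
    for _ in range(n):
        positions = draw(st.sets(st.integers(1, 4), min_size=1, max_size=4))
        pairs = tuple(sorted((p, draw(st.sampled_from("ACGT"))) for p in positions))
        ident = {
            s: Fraction(draw(st.integers(0, 4)) * 25) for s in ("s1", "s2")
        }
        to = {s for s in ("s1", "s2") if draw(st.booleans())}
        p = BasePattern("g1", "ref", pairs, 1, identity=ident, assigned_to=to)
        patterns.append(p)
    mode = draw(st.sampled_from(["max", "additive"]))
    return patterns, mode


@settings(max_examples=100, derandomize=True)
@given(election_instances())
def test_election_matches_brute_force_oracle(instance):
    patterns, mode = instance
    observed_at = {P(i): {"A", "C", "G", "T"} for i in range(1, 5)}
    cfg = CoreConfig(mode=mode)
    ours = _elect(patterns, observed_at, cfg, None, ["s1", "s2"])
    oracle = _oracle_elect(patterns, observed_at, mode, ["s1", "s2"])
    assert ours == oracle


# ---------------------------------------------------------------------------
# Step 6


class TestFinalize:
    def test_last_base_eliminated_onto_last_subgenome(self):
        hsps = [HSPRecord(P(1), "A", {"A", "G"})]
        patterns = [assigned([(1, "A")], ident={"s1": 100}, to=["s1"])]
        calls = assign_bases_to_subgenomes(patterns, hsps, CFG, subgenomes=["s1", "s2"])
        assert calls.call(P(1), "s2") is None
        finalize_assignments(calls, patterns, CFG)
        assert calls.call(P(1), "s2") == "G"
        assert calls[P(1)].fully_characterized()

    def test_no_elimination_with_two_unassigned_bases(self):
        hsps = [HSPRecord(P(1), "A", {"A", "C", "G"})]
        patterns = [assigned([(1, "A")], ident={"s1": 100}, to=["s1"])]
        calls = assign_bases_to_subgenomes(patterns, hsps, CFG, subgenomes=["s1", "s2", "s3"])
        finalize_assignments(calls, patterns, CFG)
        assert calls.call(P(1), "s2") is None and calls.call(P(1), "s3") is None

    def test_disabled_finalization_changes_nothing(self):
        cfg = CoreConfig(finalize_enabled=False)
        hsps = [HSPRecord(P(1), "A", {"A", "G"})]
        patterns = [assigned([(1, "A")], ident={"s1": 100}, to=["s1"])]
        calls = assign_bases_to_subgenomes(patterns, hsps, cfg, subgenomes=["s1", "s2"])
        finalize_assignments(calls, patterns, cfg)
        assert calls.call(P(1), "s2") is None

    def test_leftover_pattern_fills_gap_via_recheck(self):
        # three subgenomes, so elimination cannot apply at position 2:
        # the leftover pattern must be rechecked against the assigned bases
        hsps = [HSPRecord(P(1), "A", {"A", "G"}), HSPRecord(P(2), "C", {"C", "T"})]
        anchor1 = assigned([(1, "A"), (2, "C")], ident={"s1": 100, "s2": 0}, to=["s1"])
        anchor2 = assigned([(1, "G")], ident={"s1": 0, "s2": 100}, to=["s2"])
        leftover = assigned([(1, "G"), (2, "T")], ident={"s1": 0, "s2": None}, to=[])
        calls = assign_bases_to_subgenomes(
            [anchor1, anchor2], hsps, CFG, subgenomes=["s1", "s2", "s3"]
        )
        assert calls.call(P(2), "s2") is None
        finalize_assignments(calls, [anchor1, anchor2, leftover], CFG)
        # leftover matches s2's called base at position 1 (100%) -> fills position 2
        assert calls.call(P(2), "s2") == "T"
        assert calls.call(P(2), "s3") is None
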