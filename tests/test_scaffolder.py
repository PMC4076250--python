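"""Chaining, repeat placement, trimming, rejoining and junction resolution."""

import pytest

from lrstitch.io_formats import Contig, scaffold_sequence
from lrstitch.linkage import (Link, LinkageGraph, LinkParams, canonical_key,
                              canonical_path)
from lrstitch.scaffolder import (Junction, MergeParams, Scaffold, ScaffoldPart,
                                 chain_scaffolds, circularize,
                                 finalize_repeat_singletons, place_repeats,
                                 rejoin_scaffolds, resolve_all_junctions,
                                 resolve_junction, trim_edge_repeats)


def mk_link(e1, e2, gaps=(10,)):
    a, b = canonical_key(e1, e2)
    return Link(a, b, list(gaps))


def links_of(*pairs):
    out = {}
    for e1, e2, *rest in pairs:
        gaps = rest[0] if rest else (10,)
        l = mk_link(e1, e2, gaps)
        out[l.key] = l
    return out


def contig_map(*spec):
    return {cid: Contig(cid, ln, "A" * ln) for cid, ln in spec}


class TestChainScaffolds:
    def test_simple_chain_forward(self):
        cm = contig_map(("A", 100), ("B", 100), ("C", 100))
        accepted = links_of((("A", "tail"), ("B", "head")),
                            (("B", "tail"), ("C", "head")))
        (s,) = chain_scaffolds(accepted, cm)
        assert [(p.contig_id, p.orientation) for p in s.parts] == \
            [("A", "+"), ("B", "+"), ("C", "+")]

    def test_tail_tail_link_flips_partner(self):
        cm = contig_map(("A", 100), ("B", 100))
        accepted = links_of((("A", "tail"), ("B", "tail")))
        (s,) = chain_scaffolds(accepted, cm)
        assert [(p.contig_id, p.orientation) for p in s.parts] == \
            [("A", "+"), ("B", "-")]

    def test_unlinked_contigs_become_singletons(self):
        cm = contig_map(("A", 100), ("B", 100), ("Z", 50))
        accepted = links_of((("A", "tail"), ("B", "head")))
        scaffolds = chain_scaffolds(accepted, cm)
        assert sorted(len(s.parts) for s in scaffolds) == [1, 2]

    def test_cycle_opened_at_weakest_junction(self):
        cm = contig_map(("A", 100), ("B", 100), ("C", 100))
        accepted = links_of((("A", "tail"), ("B", "head"), [1] * 9),
                            (("B", "tail"), ("C", "head"), [1] * 8),
                            (("C", "tail"), ("A", "head"), [1] * 3))
        (s,) = chain_scaffolds(accepted, cm)
        assert s.circular
        # weakest junction (C->A, support 3) is the opened one, so the
        # chain must run A..B..C with C->A as the closing link
        ids = [p.contig_id for p in s.parts]
        assert ids in (["A", "B", "C"], ["C", "B", "A"])
        assert s.closing_link.support == 3

    def test_two_accepted_links_on_one_end_rejected(self):
        cm = contig_map(("A", 100), ("B", 100), ("C", 100))
        l1 = mk_link(("A", "tail"), ("B", "head"))
        l2 = mk_link(("A", "tail"), ("C", "head"))
        with pytest.raises(AssertionError):
            chain_scaffolds({l1.key: l1, l2.key: l2}, cm)

    def test_pending_gap_from_link_median(self):
        cm = contig_map(("A", 100), ("B", 100))
        accepted = links_of((("A", "tail"), ("B", "head"), [48, 52, 50]))
        (s,) = chain_scaffolds(accepted, cm)
        assert s.parts[0].pending_gap == 50


def repeat_graph(path_counts, flags):
    """Graph with given oriented-path multiplicities and repeat flags."""
    g = LinkageGraph()
    for p, n in path_counts.items():
        g.paths[canonical_path(p)] += n
    g.repeat_flags = set(flags)
    return g


class TestPlaceRepeats:
    def scaffold_xy(self):
        s = Scaffold(parts=[ScaffoldPart("X", "+", pending_gap=2100,
                                         pending_support=4),
                            ScaffoldPart("Y", "+")])
        return s

    def test_supported_repeat_inserted(self):
        g = repeat_graph({(("X", "F"), ("R", "F"), ("Y", "F")): 4}, {"R"})
        l1 = mk_link(("X", "tail"), ("R", "head"), [40] * 4)
        l2 = mk_link(("R", "tail"), ("Y", "head"), [60] * 4)
        g.links = {l.key: l for l in (l1, l2)}
        s = self.scaffold_xy()
        placed = place_repeats([s], g, LinkParams(min_support=3),
                               contig_map(("X", 1000), ("R", 2000), ("Y", 1000)))
        assert [p.contig_id for p in s.parts] == ["X", "R", "Y"]
        assert placed == {"R": 1}
        assert s.parts[0].pending_gap == 40 and s.parts[1].pending_gap == 60

    def test_below_support_not_placed(self):
        g = repeat_graph({(("X", "F"), ("R", "F"), ("Y", "F")): 2}, {"R"})
        s = self.scaffold_xy()
        placed = place_repeats([s], g, LinkParams(min_support=3),
                               contig_map(("X", 1000), ("R", 2000), ("Y", 1000)))
        assert placed == {} and [p.contig_id for p in s.parts] == ["X", "Y"]

    def test_tied_distinct_repeats_place_neither(self):
        g = repeat_graph({(("X", "F"), ("R1", "F"), ("Y", "F")): 4,
                          (("X", "F"), ("R2", "F"), ("Y", "F")): 4}, {"R1", "R2"})
        s = self.scaffold_xy()
        placed = place_repeats([s], g, LinkParams(min_support=3),
                               contig_map(("X", 1000), ("R1", 2000),
                                          ("R2", 2000), ("Y", 1000)))
        assert placed == {}

    def test_reverse_oriented_repeat(self):
        g = repeat_graph({(("X", "F"), ("R", "R"), ("Y", "F")): 5}, {"R"})
        l1 = mk_link(("X", "tail"), ("R", "tail"), [40] * 5)
        l2 = mk_link(("R", "head"), ("Y", "head"), [60] * 5)
        g.links = {l.key: l for l in (l1, l2)}
        s = self.scaffold_xy()
        place_repeats([s], g, LinkParams(min_support=3),
                      contig_map(("X", 1000), ("R", 2000), ("Y", 1000)))
        assert [(p.contig_id, p.orientation) for p in s.parts] == \
            [("X", "+"), ("R", "-"), ("Y", "+")]


class TestTrimEdgeRepeats:
    def scaffold_of(self, *cids):
        return Scaffold(parts=[ScaffoldPart(c, "+") for c in cids])

    def test_edge_repeats_stripped(self):
        s = self.scaffold_of("R1", "A", "B", "R2")
        (out,) = trim_edge_repeats([s], {"R1", "R2"})
        assert [p.contig_id for p in out.parts] == ["A", "B"]

    def test_iterative_strip(self):
        s = self.scaffold_of("R1", "R2", "A")
        (out,) = trim_edge_repeats([s], {"R1", "R2"})
        assert [p.contig_id for p in out.parts] == ["A"]

    def test_all_repeat_scaffold_dissolves(self):
        s = self.scaffold_of("R1", "R2")
        assert trim_edge_repeats([s], {"R1", "R2"}) == []

    def test_internal_repeat_untouched(self):
        s = self.scaffold_of("A", "R1", "B")
        (out,) = trim_edge_repeats([s], {"R1"})
        assert [p.contig_id for p in out.parts] == ["A", "R1", "B"]

    def test_unplaced_repeats_emitted_once(self):
        s = self.scaffold_of("A", "B")
        out = finalize_repeat_singletons([s], {"R1"})
        singles = [sc for sc in out if len(sc.parts) == 1]
        assert [sc.parts[0].contig_id for sc in singles] == ["R1"]


class TestRejoinScaffolds:
    def mk_two(self):
        s1 = Scaffold(parts=[ScaffoldPart("A", "+"), ScaffoldPart("B", "+")])
        s1.parts[0].pending_gap = 10
        s2 = Scaffold(parts=[ScaffoldPart("C", "+"), ScaffoldPart("D", "+")])
        s2.parts[0].pending_gap = 10
        return s1, s2

    def graph_with_pool(self, *links):
        g = LinkageGraph()
        g.links = {l.key: l for l in links}
        g.resolved_pool = dict(g.links)
        return g

    def test_terminal_link_joins(self):
        s1, s2 = self.mk_two()
        g = self.graph_with_pool(mk_link(("B", "tail"), ("C", "head"), [30] * 4))
        out = rejoin_scaffolds([s1, s2], g, LinkParams(min_support=3), set())
        assert len(out) == 1
        assert [p.contig_id for p in out[0].parts] == ["A", "B", "C", "D"]
        assert out[0].parts[1].pending_gap == 30

    def test_below_support_no_join(self):
        s1, s2 = self.mk_two()
        g = self.graph_with_pool(mk_link(("B", "tail"), ("C", "head"), [30] * 2))
        out = rejoin_scaffolds([s1, s2], g, LinkParams(min_support=3), set())
        assert len(out) == 2

    def test_join_with_orientation_flip(self):
        s1, s2 = self.mk_two()
        g = self.graph_with_pool(mk_link(("B", "tail"), ("D", "tail"), [30] * 5))
        out = rejoin_scaffolds([s1, s2], g, LinkParams(min_support=3), set())
        assert [(p.contig_id, p.orientation) for p in out[0].parts] == \
            [("A", "+"), ("B", "+"), ("D", "-"), ("C", "-")]

    def test_ambiguous_terminals_no_join(self):
        s1, s2 = self.mk_two()
        s3 = Scaffold(parts=[ScaffoldPart("E", "+")])
        g = self.graph_with_pool(
            mk_link(("B", "tail"), ("C", "head"), [30] * 4),
            mk_link(("B", "tail"), ("E", "head"), [30] * 4))
        out = rejoin_scaffolds([s1, s2, s3], g, LinkParams(min_support=3), set())
        assert len(out) == 3


class TestResolveJunction:
    def test_positive_estimate_gap(self):
        j = resolve_junction(120, "ACGT", "ACGT", MergeParams())
        assert (j.kind, j.gap_len) == ("gap", 120)

    def test_zero_estimate_abuts(self):
        j = resolve_junction(0, "ACGT", "ACGT", MergeParams())
        assert (j.kind, j.gap_len) == ("gap", 0)

    def test_negative_with_overlap_merges(self):
        j = resolve_junction(-20, "ACGTACGT", "ACGTTTTT", MergeParams())
        assert (j.kind, j.overlap_len) == ("merge", 4)

    def test_negative_without_overlap_falls_back_to_min_gap(self):
        j = resolve_junction(-50, "AAAAAAAA", "CCCCCCCC", MergeParams())
        assert (j.kind, j.gap_len) == ("gap", 1)

    def test_overlap_capped_below_contig_length(self):
        j = resolve_junction(-8, "ACGTACGT", "ACGTACGT",
                             MergeParams(), max_overlap=7)
        assert j.kind == "merge" and j.overlap_len <= 7

    def test_no_sequences_emits_clamped_gap(self):
        assert resolve_junction(-30, None, None, MergeParams()).gap_len == 1
        assert resolve_junction(75, None, None, MergeParams()).gap_len == 75

    def test_noisy_estimate_finds_true_overlap_within_band(self):
        import random
        rng = random.Random(5)
        core = "".join(rng.choice("ACGT") for _ in range(60))
        a = "".join(rng.choice("ACGT") for _ in range(80)) + core
        b = core + "".join(rng.choice("ACGT") for _ in range(80))
        j = resolve_junction(-45, a, b, MergeParams())  # true overlap 60
        assert (j.kind, j.overlap_len) == ("merge", 60)


class TestLengthBookkeeping:
    def test_emitted_length_matches_sequence(self):
        cm = {"A": Contig("A", 30, "ACGTACGTACGTACGTACGTACGTACGTAC"),
              "B": Contig("B", 20, "GGGGGCCCCCGGGGGCCCCC")}
        s = Scaffold(parts=[ScaffoldPart("A", "+", pending_gap=12,
                                         pending_support=3),
                            ScaffoldPart("B", "-")])
        resolve_all_junctions([s], cm, MergeParams())
        assert s.emitted_length(cm) == len(scaffold_sequence(s, cm)) == 62

    def test_merge_reduces_length(self):
        cm = {"A": Contig("A", 12, "TTTTTTTTACGT"), "B": Contig("B", 12, "ACGTGGGGGGGG")}
        s = Scaffold(parts=[ScaffoldPart("A", "+", pending_gap=-4,
                                         pending_support=3),
                            ScaffoldPart("B", "+")])
        resolve_all_junctions([s], cm, MergeParams())
        assert s.parts[0].junction_after.kind == "merge"
        assert s.emitted_length(cm) == len(scaffold_sequence(s, cm)) == 20

    def test_circular_merge_trims_closing_overlap(self):
        seq_a = "ACGTACGTAAAATTTT"
        seq_b = "CCCCGGGGACGTACGT"  # B's tail overlaps A's head by 8
        cm = {"A": Contig("A", 16, seq_a), "B": Contig("B", 16, seq_b)}
        link_ab = mk_link(("A", "tail"), ("B", "head"), [5] * 5)
        closing = mk_link(("B", "tail"), ("A", "head"), [-8] * 5)
        g = LinkageGraph()
        g.links = {link_ab.key: link_ab, closing.key: closing}
        g.resolved_pool = dict(g.links)
        s = Scaffold(parts=[ScaffoldPart("A", "+", pending_gap=5,
                                         pending_support=5),
                            ScaffoldPart("B", "+")])
        resolve_all_junctions([s], cm, MergeParams())
        circularize([s], g, LinkParams(min_support=3), cm, MergeParams())
        assert s.circular and s.closing_junction.kind == "merge"
        assert s.closing_junction.overlap_len == 8
        assert s.emitted_length(cm) == 16 + 16 + 5 - 8


class TestConservation:
    def test_every_contig_accounted_for(self, run_sim):
        from lrstitch.simulator import SimConfig
        cm, layout, run, _ = run_sim(SimConfig(
            genome_len=150_000, repeat_families=[(2000, 2)],
            break_at_repeats=True, coverage=40, read_len_mean=3000,
            error_rate=0.0, seed=2))
        emitted = [p.contig_id for s in run.scaffolds for p in s.parts]
        assert set(emitted) == set(cm)
        for cid in set(emitted) - run.repeat_flags:
            assert emitted.count(cid) == 1
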