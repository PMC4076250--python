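"""Chain accepted links into scaffolds and resolve every junction.

The accepted links (at most one per contig end) induce a graph in which each
connected component is a simple chain or a cycle of contigs. Chains become
preliminary scaffolds; cycles are opened at their weakest-support junction
and remembered as circular replicons. Repeat-flagged contigs are excluded
from chaining — they are re-inserted afterwards at junctions whose flanking
contigs are bridged by multi-contig read paths running through the repeat.

Every junction finally resolves to either an N-gap (positive distance
estimate) or a sequence merge (negative estimate confirmed by an end-anchored
overlap alignment between the flanking contig sequences).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import edlib

from .io_formats import Contig, revcomp
from .linkage import (End, Link, LinkageGraph, LinkParams, canonical_key,
                      estimate_gap, left_end, right_end)

log = logging.getLogger(__name__)

__all__ = [
    "Junction", "ScaffoldPart", "Scaffold", "MergeParams",
    "chain_scaffolds", "place_repeats", "trim_edge_repeats",
    "rejoin_scaffolds", "resolve_junction", "resolve_all_junctions",
    "circularize", "finalize_repeat_singletons", "reverse_scaffold",
]


@dataclass
class Junction:
    """A resolved inter-contig junction: an N-gap or a sequence merge."""

    kind: str  # 'gap' | 'merge'
    gap_len: int = 0        # gap only; 0 means the contigs abut exactly
    overlap_len: int = 0    # merge only; >= 1
    support: int = 0

    def __post_init__(self):
        if self.kind not in ("gap", "merge"):
            raise ValueError(f"bad junction kind {self.kind!r}")
        if self.kind == "gap" and self.gap_len < 0:
            raise ValueError("gap_len must be >= 0")
        if self.kind == "merge" and self.overlap_len < 1:
            raise ValueError("merge overlap_len must be >= 1")


@dataclass
class ScaffoldPart:
    contig_id: str
    orientation: str  # '+' | '-'
    junction_after: Optional[Junction] = None
    pending_gap: Optional[int] = None   # signed estimate, pre-resolution
    pending_support: int = 0
    trim_head: int = 0  # oriented leading bases consumed by a merge
    trim_tail: int = 0  # oriented trailing bases (circular closure only)


@dataclass
class Scaffold:
    id: Optional[str] = None
    parts: list[ScaffoldPart] = field(default_factory=list)
    circular: bool = False
    closing_link: Optional[Link] = None
    closing_junction: Optional[Junction] = None

    def part_span(self, part: ScaffoldPart, contig_map: dict[str, Contig]) -> int:
        return contig_map[part.contig_id].length - part.trim_head - part.trim_tail

    def emitted_length(self, contig_map: dict[str, Contig]) -> int:
        total = 0
        for p in self.parts:
            total += self.part_span(p, contig_map)
            if p.junction_after is not None and p.junction_after.kind == "gap":
                total += p.junction_after.gap_len
        return total

    def left_terminal(self) -> End:
        p = self.parts[0]
        return (p.contig_id, "head" if p.orientation == "+" else "tail")

    def right_terminal(self) -> End:
        p = self.parts[-1]
        return (p.contig_id, "tail" if p.orientation == "+" else "head")


@dataclass
class MergeParams:
    """Overlap-merge verification knobs.

    merge_band widens the searched overlap lengths around |estimated gap| to
    absorb long-read gap-estimate noise; merge_min_identity is safe to keep
    high because draft contigs are short-read-accurate; merge_min_overlap
    guards against chance micro-overlaps passing any identity bar; min_gap_n
    is the N-run recorded when a negative estimate cannot be confirmed as an
    overlap.
    """

    merge_min_identity: float = 0.85
    merge_band: int = 100
    min_gap_n: int = 1
    merge_min_overlap: int = 4

    def __post_init__(self):
        if not (0.0 < self.merge_min_identity <= 1.0):
            raise ValueError("merge_min_identity must be in (0,1]")


def reverse_scaffold(s: Scaffold) -> Scaffold:
    """In-place reversal: flip part order, orientations and junction sides."""
    junctions = [(p.junction_after, p.pending_gap, p.pending_support)
                 for p in s.parts[:-1]]
    for p in s.parts:
        p.orientation = "+" if p.orientation == "-" else "-"
        p.trim_head, p.trim_tail = p.trim_tail, p.trim_head
    s.parts.reverse()
    junctions.reverse()
    for p in s.parts:
        p.junction_after, p.pending_gap, p.pending_support = None, None, 0
    for p, (j, g, sup) in zip(s.parts, junctions):
        p.junction_after, p.pending_gap, p.pending_support = j, g, sup
    return s


def _orient_presentation(s: Scaffold) -> Scaffold:
    """Deterministic presentation: smaller terminal contig id first."""
    if len(s.parts) > 1 and s.parts[0].contig_id > s.parts[-1].contig_id:
        reverse_scaffold(s)
    return s


def chain_scaffolds(accepted: dict[tuple[End, End], Link],
                    contigs: dict[str, Contig],
                    repeat_flags: set[str] | None = None) -> list[Scaffold]:
    """Linearize the accepted end-link graph into preliminary scaffolds.

    Components are simple chains (each end carries at most one accepted
    link — guaranteed upstream) or cycles; a cycle is opened at its weakest
    junction and flagged circular. Unlinked non-repeat contigs become
    singleton scaffolds; repeat-flagged contigs are withheld for placement.
    """
    repeat_flags = repeat_flags or set()
    end_link: dict[End, tuple[End, Link]] = {}
    for link in accepted.values():
        for mine, other in ((link.a_end, link.b_end), (link.b_end, link.a_end)):
            if mine in end_link:
                raise AssertionError(f"contig end {mine} carries two accepted links")
            end_link[mine] = (other, link)

    scaffolds: list[Scaffold] = []
    visited: set[str] = set()

    def walk(cid: str, exit_side: str):
        """Follow links from one side of a contig; yields (contig, orient, link)."""
        while True:
            nxt = end_link.get((cid, exit_side))
            if nxt is None:
                return
            (cid2, entry), link = nxt
            orient = "+" if entry == "head" else "-"
            yield cid2, orient, link, entry
            cid = cid2
            exit_side = "tail" if orient == "+" else "head"

    for seed in sorted(contigs):
        if seed in visited or seed in repeat_flags:
            continue
        visited.add(seed)
        parts = [ScaffoldPart(seed, "+")]
        links_after: list[Link] = []
        circular = False
        closing = None
        # forward (rightward, out of the tail)
        for cid2, orient, link, _entry in walk(seed, "tail"):
            if cid2 == seed:  # cycle closed
                circular = True
                links_after.append(link)
                closing = link
                break
            parts.append(ScaffoldPart(cid2, orient))
            links_after.append(link)
            visited.add(cid2)
        if not circular:
            # leftward, out of the head; orientation logic mirrors
            pre_parts: list[ScaffoldPart] = []
            pre_links: list[Link] = []
            cid, side = seed, "head"
            while True:
                nxt = end_link.get((cid, side))
                if nxt is None:
                    break
                (cid2, entry), link = nxt
                orient = "+" if entry == "tail" else "-"
                pre_parts.append(ScaffoldPart(cid2, orient))
                pre_links.append(link)
                visited.add(cid2)
                cid = cid2
                side = "head" if orient == "+" else "tail"
            pre_parts.reverse()
            pre_links.reverse()
            parts = pre_parts + parts
            links_after = pre_links + links_after

        s = Scaffold(parts=parts, circular=circular)
        if circular:
            # open at the weakest-support junction (tie: lexicographic key)
            w = min(range(len(links_after)),
                    key=lambda i: (links_after[i].support, links_after[i].key))
            opened = links_after[w]
            parts = parts[w + 1:] + parts[:w + 1]
            links_after = links_after[w + 1:] + links_after[:w]
            s.parts = parts
            s.closing_link = opened
        for p, link in zip(s.parts, links_after):
            p.pending_gap = estimate_gap(link)
            p.pending_support = link.support
        _orient_presentation(s)
        scaffolds.append(s)
    return scaffolds


def _triple_index(graph: LinkageGraph):
    """Index stored paths by junction frame: (right end of X, left end of Y)
    -> Counter of (intermediate contig, its strand in that frame)."""
    idx: dict[tuple[End, End], Counter] = {}
    for p, count in graph.paths.items():
        for variant in (p, tuple((cid, {"F": "R", "R": "F"}[s])
                                 for cid, s in reversed(p))):
            for a, mid, c in zip(variant, variant[1:], variant[2:]):
                key = (right_end(*a), left_end(*c))
                idx.setdefault(key, Counter())[mid] += count
    return idx


def place_repeats(scaffolds: list[Scaffold], graph: LinkageGraph,
                  params: LinkParams, contigs: dict[str, Contig]
                  ) -> dict[str, int]:
    """Insert repeat-flagged contigs at junctions bridged by stored paths.

    For each adjacent pair (X, Y) inside a scaffold, a repeat R qualifies
    when the path store holds X->R->Y (in the scaffold's junction frame)
    with at least min_support reads. The winner by support is inserted as a
    fresh copy; a tie between two distinct repeats places neither. Gaps for
    the two new junctions come from the original pairwise links X--R and
    R--Y. Returns placement counts per repeat contig.
    """
    placed: dict[str, int] = {}
    if not graph.repeat_flags:
        return placed
    idx = _triple_index(graph)
    for s in scaffolds:
        i = 0
        while i < len(s.parts) - 1:
            x, y = s.parts[i], s.parts[i + 1]
            key = ((x.contig_id, "tail" if x.orientation == "+" else "head"),
                   (y.contig_id, "head" if y.orientation == "+" else "tail"))
            cands = idx.get(key)
            if cands:
                per_contig: dict[str, int] = {}
                strand_votes: dict[str, Counter] = {}
                for (cid, strand), n in sorted(cands.items()):
                    if cid not in graph.repeat_flags:
                        continue
                    per_contig[cid] = per_contig.get(cid, 0) + n
                    strand_votes.setdefault(cid, Counter())[strand] += n
                strand_of = {cid: max(votes.items(),
                                      key=lambda kv: (kv[1], kv[0] == "F"))[0]
                             for cid, votes in strand_votes.items()}
                ranked = sorted(per_contig.items(), key=lambda kv: (-kv[1], kv[0]))
                if ranked and ranked[0][1] >= params.min_support:
                    if len(ranked) > 1 and ranked[1][1] == ranked[0][1]:
                        log.warning(
                            "junction %s--%s: tied repeat candidates %s/%s, placing neither",
                            x.contig_id, y.contig_id, ranked[0][0], ranked[1][0])
                    else:
                        rid = ranked[0][0]
                        orient = "+" if strand_of[rid] == "F" else "-"
                        lgap, lsup = _lookup_gap(graph, key[0],
                                                 (rid, "head" if orient == "+" else "tail"))
                        rgap, rsup = _lookup_gap(graph,
                                                 (rid, "tail" if orient == "+" else "head"),
                                                 key[1])
                        if lgap is None or rgap is None:
                            span = x.pending_gap if x.pending_gap is not None else 0
                            residue = span - contigs[rid].length
                            lgap = rgap = residue // 2
                            lsup = rsup = ranked[0][1]
                        part = ScaffoldPart(rid, orient,
                                            pending_gap=rgap, pending_support=rsup)
                        x.pending_gap, x.pending_support = lgap, lsup
                        s.parts.insert(i + 1, part)
                        placed[rid] = placed.get(rid, 0) + 1
                        i += 2
                        continue
            i += 1
    return placed


def _lookup_gap(graph: LinkageGraph, e1: End, e2: End):
    link = graph.links.get(canonical_key(e1, e2))
    if link is None:
        return None, 0
    return estimate_gap(link), link.support


def trim_edge_repeats(scaffolds: list[Scaffold], repeat_flags: set[str]
                      ) -> list[Scaffold]:
    """Strip repeat-flagged contigs from both ends of multi-contig scaffolds.

    Trimming iterates until both ends are non-repeat; a scaffold consisting
    solely of repeats dissolves. Stripped copies are not re-emitted here —
    finalize_repeat_singletons accounts for every flagged contig exactly once.
    """
    out: list[Scaffold] = []
    for s in scaffolds:
        if len(s.parts) > 1 and not s.circular:
            while s.parts and s.parts[0].contig_id in repeat_flags:
                s.parts.pop(0)
            while s.parts and s.parts[-1].contig_id in repeat_flags:
                s.parts.pop()
            if s.parts:
                last = s.parts[-1]
                last.junction_after, last.pending_gap, last.pending_support = None, None, 0
        if s.parts:
            out.append(s)
    return out


def rejoin_scaffolds(scaffolds: list[Scaffold], graph: LinkageGraph,
                     params: LinkParams, repeat_flags: set[str]
                     ) -> list[Scaffold]:
    """Reconnect preliminary scaffolds through their terminal contigs.

    Link acceptance re-runs restricted to outward-facing terminal ends of
    distinct scaffolds, over the full candidate pool (including span links
    promoted across flagged repeats, i.e. links previously shadowed by a
    trimmed repeat). Mutually chosen terminal links merge their scaffolds;
    the procedure iterates to a fixed point.
    """
    pool = getattr(graph, "resolved_pool", graph.links)
    while True:
        term: dict[End, tuple[int, str]] = {}
        for i, s in enumerate(scaffolds):
            if not s.parts or s.circular:
                continue
            if s.parts[0].contig_id in repeat_flags or s.parts[-1].contig_id in repeat_flags:
                continue
            term[s.left_terminal()] = (i, "left")
            term[s.right_terminal()] = (i, "right")

        by_end: dict[End, list[Link]] = {}
        for key in sorted(pool):
            link = pool[key]
            if link.support < params.min_support:
                continue
            a, b = link.a_end, link.b_end
            if a not in term or b not in term:
                continue
            if term[a][0] == term[b][0]:
                continue  # self-closure is circularization, not a rejoin
            by_end.setdefault(a, []).append(link)
            by_end.setdefault(b, []).append(link)

        chosen: dict[End, Link] = {}
        for end in sorted(by_end):
            cands = sorted(by_end[end], key=lambda l: (-l.support, l.key))
            if len(cands) == 1 or \
                    cands[1].support / cands[0].support <= params.ratio_threshold:
                chosen[end] = cands[0]

        join = None
        for end in sorted(chosen):
            link = chosen[end]
            other = link.b_end if end == link.a_end else link.a_end
            if chosen.get(other) is link:
                join = link
                break
        if join is None:
            return scaffolds

        ia, sa_side = term[join.a_end]
        ib, sb_side = term[join.b_end]
        s1, s2 = scaffolds[ia], scaffolds[ib]
        if sa_side == "left":
            reverse_scaffold(s1)
        if sb_side == "right":
            reverse_scaffold(s2)
        bridge = s1.parts[-1]
        bridge.pending_gap = estimate_gap(join)
        bridge.pending_support = join.support
        s1.parts.extend(s2.parts)
        scaffolds = [s for j, s in enumerate(scaffolds) if j != ib]
        log.debug("rejoined scaffolds via %s", join.key)


def finalize_repeat_singletons(scaffolds: list[Scaffold],
                               repeat_flags: set[str]) -> list[Scaffold]:
    """Emit each never-placed repeat contig once as a singleton scaffold so
    that every input contig is accounted for in the output."""
    present = {p.contig_id for s in scaffolds for p in s.parts}
    for rid in sorted(repeat_flags):
        if rid not in present:
            scaffolds.append(Scaffold(parts=[ScaffoldPart(rid, "+")]))
    return scaffolds


def resolve_junction(estimate: int, seq_a_tail: Optional[str],
                     seq_b_head: Optional[str], params: MergeParams,
                     support: int = 0,
                     max_overlap: Optional[int] = None) -> Junction:
    """Resolve one junction to a gap or a verified overlap merge.

    A positive distance estimate is taken at face value as an N-gap; zero
    means the contigs abut exactly (no N inserted). A negative estimate
    promises an overlap: overlap lengths within merge_band of |estimate| are
    scored by end-anchored (suffix-vs-prefix) alignment identity and the
    junction becomes a merge when the best passes merge_min_identity;
    otherwise a minimal N-gap of min_gap_n records the unresolved join.
    Without flanking sequences the gap is max(estimate, min_gap_n).
    """
    if seq_a_tail is None or seq_b_head is None:
        return Junction("gap", gap_len=max(estimate, params.min_gap_n),
                        support=support)
    if estimate > 0:
        return Junction("gap", gap_len=estimate, support=support)
    if estimate == 0:
        return Junction("gap", gap_len=0, support=support)
    want = -estimate
    hi = min(want + params.merge_band, len(seq_a_tail), len(seq_b_head))
    if max_overlap is not None:
        hi = min(hi, max_overlap)
    lo = max(params.merge_min_overlap, want - params.merge_band)
    best = None  # (identity, -dist_to_want, length)
    for ln in range(lo, hi + 1):
        suffix = seq_a_tail[-ln:]
        prefix = seq_b_head[:ln]
        dist = edlib.align(suffix, prefix, task="distance")["editDistance"]
        ident = 1.0 - dist / ln
        cand = (ident, -abs(ln - want), ln)
        if best is None or cand > best:
            best = cand
    if best is not None and best[0] >= params.merge_min_identity:
        return Junction("merge", overlap_len=best[2], support=support)
    return Junction("gap", gap_len=params.min_gap_n, support=support)


def _oriented_window(contig: Contig, orientation: str, side: str,
                     size: int) -> Optional[str]:
    """Window of a part's *oriented* sequence: its head (leading) or tail."""
    if contig.sequence is None:
        return None
    seq = contig.sequence if orientation == "+" else revcomp(contig.sequence)
    return seq[:size] if side == "head" else seq[-size:]


def resolve_all_junctions(scaffolds: list[Scaffold],
                          contigs: dict[str, Contig],
                          params: MergeParams) -> None:
    """Resolve every pending junction in place; merges trim the downstream
    part's oriented leading bases."""
    for s in scaffolds:
        for a, b in zip(s.parts, s.parts[1:]):
            if a.pending_gap is None:
                a.junction_after = a.junction_after or Junction(
                    "gap", gap_len=params.min_gap_n)
                continue
            ca, cb = contigs[a.contig_id], contigs[b.contig_id]
            window = max(0, -a.pending_gap) + params.merge_band
            j = resolve_junction(
                a.pending_gap,
                _oriented_window(ca, a.orientation, "tail", window),
                _oriented_window(cb, b.orientation, "head", window),
                params,
                support=a.pending_support,
                max_overlap=min(ca.length, cb.length) - 1,
            )
            a.junction_after = j
            if j.kind == "merge":
                b.trim_head += j.overlap_len


def circularize(scaffolds: list[Scaffold], graph: LinkageGraph,
                link_params: LinkParams, contigs: dict[str, Contig],
                merge_params: MergeParams) -> None:
    """Flag scaffolds whose two terminal ends carry a surviving link.

    The closing junction is resolved like any other; a merge closure trims
    the terminal overlap from the scaffold's sequence end. Output sequences
    remain linear — circularity is reported in the data model and summary.
    """
    pool = getattr(graph, "resolved_pool", graph.links)
    for s in scaffolds:
        closing = s.closing_link
        if closing is None and s.parts:
            key = canonical_key(s.right_terminal(), s.left_terminal())
            cand = pool.get(key)
            if cand is not None and cand.support >= link_params.min_support \
                    and len(s.parts) > 1:
                closing = cand
        if closing is None:
            continue
        s.circular = True
        s.closing_link = closing
        first, last = s.parts[0], s.parts[-1]
        ca, cb = contigs[last.contig_id], contigs[first.contig_id]
        est = estimate_gap(closing)
        window = max(0, -est) + merge_params.merge_band
        j = resolve_junction(
            est,
            _oriented_window(ca, last.orientation, "tail", window),
            _oriented_window(cb, first.orientation, "head", window),
            merge_params,
            support=closing.support,
            max_overlap=min(ca.length, cb.length) - 1,
        )
        s.closing_junction = j
        if j.kind == "merge":
            last.trim_tail += j.overlap_len
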