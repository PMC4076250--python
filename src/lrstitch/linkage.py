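"""Contig linkage from the order of placements along each long read.

Each read's surviving placements, sorted by read position, form a *read
path*. Consecutive path steps vote for an adjacency between two oriented
contig ends, with a signed gap estimate taken from the distance between the
projected (extended) contig spans on the read — negative means the contigs
overlap. Paths of three or more contigs are stored whole (and as every
contiguous sub-path) because they carry information a single pairing does
not: they shortcut transitive links, disambiguate conflicting pairings, and
later place repeats.

Repeats announce themselves as contig ends with several well-supported,
mutually exclusive partners. When neither the support ratio between the two
best alternatives nor the multi-contig paths single out one partner, the
contig is flagged as a repeated element and its adjacencies are instead
expressed as *span links* between its flanking unique contigs, so that the
unique backbone can still be chained and the repeat re-inserted afterwards.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .alignment_filter import Placement

log = logging.getLogger(__name__)

__all__ = [
    "End", "ReadPath", "Link", "LinkageGraph", "LinkParams",
    "build_read_paths", "derive_links", "remove_transitive_links",
    "resolve_ambiguities", "estimate_gap", "write_linkage_tsv",
    "right_end", "left_end", "canonical_key", "canonical_path",
]

# An oriented contig end: (contig_id, "head"|"tail").
End = tuple[str, str]

_FLIP = {"F": "R", "R": "F"}


def right_end(contig_id: str, strand: str) -> End:
    """End of the contig facing *forward* along the read for this strand."""
    return (contig_id, "tail" if strand == "F" else "head")


def left_end(contig_id: str, strand: str) -> End:
    """End of the contig facing *backward* along the read for this strand."""
    return (contig_id, "head" if strand == "F" else "tail")


def canonical_key(e1: End, e2: End) -> tuple[End, End]:
    """Orientation-free key for a physical junction between two contig ends."""
    return (e1, e2) if e1 <= e2 else (e2, e1)


def canonical_path(steps: tuple[tuple[str, str], ...]) -> tuple[tuple[str, str], ...]:
    """Canonical form of an oriented contig tuple: min of itself and its
    reverse complement (reversed order, flipped strands)."""
    rev = tuple((cid, _FLIP[s]) for cid, s in reversed(steps))
    return steps if steps <= rev else rev


@dataclass
class ReadPath:
    """The ordered, oriented contig placements surviving on one read."""

    read_id: str
    steps: list[Placement]

    def oriented(self) -> tuple[tuple[str, str], ...]:
        return tuple((p.contig_id, p.strand) for p in self.steps)


@dataclass
class Link:
    """An oriented contig-adjacency hypothesis with per-read gap estimates."""

    a_end: End
    b_end: End
    gap_estimates: list[int] = field(default_factory=list)

    @property
    def support(self) -> int:
        return len(self.gap_estimates)

    @property
    def key(self) -> tuple[End, End]:
        return (self.a_end, self.b_end)


@dataclass
class LinkParams:
    """min_support: reads required before a link is believed (suppresses
    single chimeric reads); ratio_threshold: second-best/best support ratio
    at or below which the best alternative wins outright."""

    min_support: int = 3
    ratio_threshold: float = 0.7

    def __post_init__(self):
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if not (0.0 < self.ratio_threshold <= 1.0):
            raise ValueError("ratio_threshold must be in (0,1]")


@dataclass
class LinkageGraph:
    """Oriented-contig-end graph plus the multi-contig path store.

    links holds the pairwise adjacencies keyed canonically; span_links holds
    skip-one adjacencies keyed by (junction key, skipped contig) and is only
    consulted when the skipped contig is flagged as a repeat; paths is a
    multiset of canonical oriented tuples of length >= 3.
    """

    links: dict[tuple[End, End], Link] = field(default_factory=dict)
    span_links: dict[tuple[tuple[End, End], str], Link] = field(default_factory=dict)
    paths: Counter = field(default_factory=Counter)
    repeat_flags: set[str] = field(default_factory=set)

    def contigs(self) -> set[str]:
        out = set()
        for (a, b) in self.links:
            out.add(a[0])
            out.add(b[0])
        for p in self.paths:
            out.update(cid for cid, _ in p)
        return out


def build_read_paths(placement_map: dict[str, list[Placement]]) -> list[ReadPath]:
    """One ReadPath per read, steps ordered by aligned read position."""
    paths = []
    for read_id in sorted(placement_map):
        steps = sorted(placement_map[read_id],
                       key=lambda p: (p.aln_read_start, p.contig_id))
        if steps:
            paths.append(ReadPath(read_id, steps))
    return paths


def _add_estimate(store: dict, key, e1: End, e2: End, gap: int) -> None:
    link = store.get(key)
    if link is None:
        a, b = canonical_key(e1, e2)
        link = store[key] = Link(a, b)
    link.gap_estimates.append(gap)


def derive_links(read_paths: list[ReadPath]) -> LinkageGraph:
    """Aggregate pairwise links, span links and multi-contig paths.

    For consecutive steps (A, B) the link joins the read-facing end of A to
    the read-entering end of B, with gap estimate B.ext_read_start -
    A.ext_read_end (signed; negative = implied overlap). For consecutive
    triples (A, B, C) a span link A--C keyed by intermediate B is recorded
    with the analogous A-to-C gap. Every contiguous sub-path of length >= 3
    is stored in the path multiset.
    """
    g = LinkageGraph()
    for rp in read_paths:
        steps = rp.steps
        for a, b in zip(steps, steps[1:]):
            e1 = right_end(a.contig_id, a.strand)
            e2 = left_end(b.contig_id, b.strand)
            _add_estimate(g.links, canonical_key(e1, e2), e1, e2,
                          b.ext_read_start - a.ext_read_end)
        for a, mid, c in zip(steps, steps[1:], steps[2:]):
            e1 = right_end(a.contig_id, a.strand)
            e2 = left_end(c.contig_id, c.strand)
            _add_estimate(g.span_links,
                          (canonical_key(e1, e2), mid.contig_id),
                          e1, e2,
                          c.ext_read_start - a.ext_read_end)
        n = len(steps)
        if n >= 3:
            oriented = rp.oriented()
            for i in range(n - 2):
                for j in range(i + 3, n + 1):
                    g.paths[canonical_path(oriented[i:j])] += 1
    return g


def remove_transitive_links(graph: LinkageGraph) -> LinkageGraph:
    """Delete direct links shortcut by a stored multi-contig path.

    A direct link X--Y is removed when some stored path contains X and Y in
    the same junction frame with at least one intervening contig. Deletions
    are computed against the original link set (simultaneous, not cascading).
    The path store itself is untouched.
    """
    shortcut: set[tuple[End, End]] = set()
    for p in graph.paths:
        n = len(p)
        for i in range(n):
            for j in range(i + 2, n):
                e1 = right_end(*p[i])
                e2 = left_end(*p[j])
                shortcut.add(canonical_key(e1, e2))
    removed = [k for k in graph.links if k in shortcut]
    for k in removed:
        del graph.links[k]
    if removed:
        log.debug("transitive reduction removed %d links", len(removed))
    return graph


def _adjacent_junctions(graph: LinkageGraph) -> set[tuple[End, End]]:
    """Junction keys that appear as *consecutive* pairs inside stored paths."""
    out: set[tuple[End, End]] = set()
    for p in graph.paths:
        for a, b in zip(p, p[1:]):
            out.add(canonical_key(right_end(*a), left_end(*b)))
    return out


def resolve_ambiguities(graph: LinkageGraph, params: LinkParams
                        ) -> tuple[dict[tuple[End, End], Link], set[str]]:
    """Accept at most one link per contig end; flag unresolved contigs as repeats.

    Links below min_support are discarded first. For an end with several
    candidates, the multi-contig paths are consulted first: exactly one
    candidate junction occurring as a consecutive pair inside a stored path
    wins outright, while two or more path-corroborated candidates mark a
    genuine repeat (support ratios at repeat ends fluctuate around 1 and
    cannot be trusted). Only when no candidate has path evidence does the
    support ratio decide: best wins when second/best is at or below the
    ratio threshold. Ends that stay unresolved flag their contig as a repeat;
    flagged contigs drop out of the candidate pool and their span links (the
    skip-one adjacencies of their flanking contigs) are promoted in their
    place, after which resolution re-runs to a fixed point.

    Returns (accepted links, repeat flags) and records both on the graph. A
    link is accepted only when it is the chosen partner at *both* of its ends.
    """
    flags: set[str] = set(graph.repeat_flags)
    path_junctions = _adjacent_junctions(graph)

    for _ in range(len(graph.contigs()) + 2):  # fixed point; bounded
        pool: dict[tuple[End, End], Link] = {
            k: l for k, l in graph.links.items()
            if l.a_end[0] not in flags and l.b_end[0] not in flags
        }
        # Promote span links across flagged repeats between unflagged flanks.
        for (key, mid), sl in graph.span_links.items():
            if mid in flags and sl.a_end[0] not in flags and sl.b_end[0] not in flags:
                have = pool.get(key)
                if have is None:
                    pool[key] = Link(sl.a_end, sl.b_end, list(sl.gap_estimates))
                elif have is graph.links.get(key):
                    merged = Link(have.a_end, have.b_end,
                                  list(have.gap_estimates) + list(sl.gap_estimates))
                    pool[key] = merged

        by_end: dict[End, list[Link]] = {}
        for k in sorted(pool):
            link = pool[k]
            if link.support < params.min_support:
                continue
            by_end.setdefault(link.a_end, []).append(link)
            by_end.setdefault(link.b_end, []).append(link)

        chosen: dict[End, Link] = {}
        new_flags: set[str] = set()
        for end in sorted(by_end):
            cands = sorted(by_end[end], key=lambda l: (-l.support, l.key))
            if len(cands) == 1:
                chosen[end] = cands[0]
                continue
            # Multi-contig paths outrank the support ratio: two candidates
            # each corroborated by read paths means both junctions are real
            # — the signature of a repeat, however lopsided the counts.
            in_paths = [l for l in cands if l.key in path_junctions]
            if len(in_paths) == 1:
                chosen[end] = in_paths[0]
            elif len(in_paths) >= 2:
                new_flags.add(end[0])
            else:
                best, second = cands[0], cands[1]
                if second.support / best.support <= params.ratio_threshold:
                    chosen[end] = best
                else:
                    new_flags.add(end[0])

        if new_flags - flags:
            flags |= new_flags
            continue

        accepted = {
            link.key: link
            for link in {id(l): l for l in chosen.values()}.values()
            if chosen.get(link.a_end) is link and chosen.get(link.b_end) is link
        }
        graph.repeat_flags = flags
        graph.resolved_pool = pool  # final candidate pool, reused by rejoin
        return dict(sorted(accepted.items())), flags

    raise RuntimeError("ambiguity resolution did not converge")  # pragma: no cover


def estimate_gap(link: Link) -> int:
    """Point estimate of a junction's gap: the lower median of the per-read
    estimates (robust to a stray chimeric outlier; negative = overlap)."""
    est = sorted(link.gap_estimates)
    if not est:
        raise ValueError("link has no gap estimates")
    return est[(len(est) - 1) // 2]


def write_linkage_tsv(graph: LinkageGraph, path) -> None:
    """Debug dump: one row per pairwise link."""
    with open(path, "w") as fh:
        fh.write("a_contig\ta_end\tb_contig\tb_end\tsupport\tmedian_gap\n")
        for k in sorted(graph.links):
            l = graph.links[k]
            fh.write("\t".join(map(str, (
                l.a_end[0], l.a_end[1], l.b_end[0], l.b_end[1],
                l.support, estimate_gap(l),
            ))) + "\n")
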