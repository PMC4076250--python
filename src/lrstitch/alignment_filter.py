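"""Turn raw local alignments into cleaned, extended contig placements per read.

A *placement* is one read-to-contig alignment projected onto the read's
coordinate system and extended to the full contig span: the unaligned contig
tails are projected past the aligned interval at the alignment's own
read/contig length ratio, which is what makes inter-contig gap estimation on
the read possible. Extended coordinates are deliberately unclamped — a contig
whose start lies "before" the read begins gets a negative extended start.

Low-quality and redundant placements are then removed per read: placements
are ranked by score and a lower-ranked placement is dropped when its aligned
read interval overlaps a kept one by more than ``g`` bases (default 200), the
minimum overlap considered evidence of a false-positive alignment rather than
two genuinely adjacent contigs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import Contig, RawAlignment

__all__ = ["Placement", "FilterParams", "extend_placement",
           "filter_read_placements", "collect_placements"]


@dataclass(frozen=True)
class Placement:
    read_id: str
    contig_id: str
    strand: str  # 'F' or 'R': orientation of the contig as read along the read
    aln_read_start: int
    aln_read_end: int
    ext_read_start: int
    ext_read_end: int
    score: int
    identity: float

    def __post_init__(self):
        if self.strand not in ("F", "R"):
            raise ValueError(f"strand must be F or R, got {self.strand!r}")
        if not (self.ext_read_start <= self.aln_read_start
                < self.aln_read_end <= self.ext_read_end):
            raise ValueError(
                f"{self.read_id}->{self.contig_id}: extended span "
                f"[{self.ext_read_start},{self.ext_read_end}) does not contain "
                f"aligned span [{self.aln_read_start},{self.aln_read_end})"
            )


@dataclass(frozen=True)
class FilterParams:
    """Placement-filter knobs.

    g: minimum aligned-interval overlap (bp) that triggers removal of the
       lower-scoring placement (-g; raise to ~500 for drafts that carry
       repeats on contig edges).
    min_identity / min_aln_len: pre-filters on individual alignments.
    """

    g: int = 200
    min_identity: float = 0.70
    min_aln_len: int = 100

    def __post_init__(self):
        if self.g < 0:
            raise ValueError("g must be >= 0")
        if not (0.0 <= self.min_identity <= 1.0):
            raise ValueError("min_identity must be in [0,1]")


def extend_placement(a: RawAlignment, contig_len: int) -> Placement:
    """Project a local alignment to a full-contig span on read coordinates.

    The unaligned contig tails are scaled by s = aligned-read-span /
    aligned-contig-span and appended on the appropriate side: for a
    forward-strand hit the contig's unaligned prefix projects left of the
    aligned read interval; for a reverse-strand hit the tails swap sides.
    """
    cspan = a.contig_end - a.contig_start
    if cspan <= 0:
        raise ValueError(f"{a.read_id}->{a.contig_id}: empty contig interval")
    s = (a.read_end - a.read_start) / cspan
    left_tail = a.contig_start            # unaligned contig bases before the hit
    right_tail = contig_len - a.contig_end
    if a.strand == "+":
        ext_start = a.read_start - round(s * left_tail)
        ext_end = a.read_end + round(s * right_tail)
    else:
        ext_start = a.read_start - round(s * right_tail)
        ext_end = a.read_end + round(s * left_tail)
    return Placement(
        read_id=a.read_id,
        contig_id=a.contig_id,
        strand="F" if a.strand == "+" else "R",
        aln_read_start=a.read_start,
        aln_read_end=a.read_end,
        ext_read_start=ext_start,
        ext_read_end=ext_end,
        score=a.score,
        identity=a.identity,
    )


def _rank_key(p: Placement):
    return (-p.score, -p.identity, p.contig_id, p.aln_read_start)


def _overlap(a: Placement, b: Placement) -> int:
    return min(a.aln_read_end, b.aln_read_end) - max(a.aln_read_start, b.aln_read_start)


def filter_read_placements(placements: list[Placement],
                           params: FilterParams) -> list[Placement]:
    """Keep only the best-scoring mutually non-overlapping placements.

    Placements are ranked by (score desc, identity desc, contig id, read
    position) and walked from the top; each one is removed when its aligned
    read interval overlaps any higher-ranked placement's by more than ``g``
    bases. Removal compares against all higher-ranked placements — including
    ones that were themselves removed — which makes the survivor set grow
    monotonically with ``g`` and keeps any two survivors within ``g`` of
    aligned overlap. A contig may legitimately survive several times on one
    read at disjoint positions — that is the signature of a repeat copy.
    Survivors are returned in read-position order.
    """
    ranked = sorted(placements, key=_rank_key)
    kept: list[Placement] = []
    for i, p in enumerate(ranked):
        if all(_overlap(q, p) <= params.g for q in ranked[:i]):
            kept.append(p)
    kept.sort(key=lambda p: (p.aln_read_start, p.contig_id, p.aln_read_end,
                             -p.score))
    return kept


def collect_placements(alignments: list[RawAlignment],
                       contigs: dict[str, Contig] | None,
                       params: FilterParams) -> dict[str, list[Placement]]:
    """Build the per-read filtered placement map from raw alignments.

    Alignments failing the identity/length pre-filters are dropped first;
    the overlap filter then runs independently per read. The result is
    deterministic regardless of input record order. Reads with a single
    surviving placement are retained (they contribute no links but count
    toward coverage bookkeeping); reads with none are dropped.
    """
    by_read: dict[str, list[Placement]] = {}
    for a in sorted(alignments, key=lambda a: (a.read_id, a.contig_id,
                                               a.read_start, a.contig_start)):
        if contigs is not None:
            contig = contigs.get(a.contig_id)
            if contig is None:
                raise ValueError(f"alignment references unknown contig {a.contig_id}")
            contig_len = contig.length
        else:
            contig_len = a.contig_len
        if a.identity < params.min_identity:
            continue
        if a.read_end - a.read_start < params.min_aln_len:
            continue
        if a.contig_end <= a.contig_start:
            continue
        by_read.setdefault(a.read_id, []).append(extend_placement(a, contig_len))
    out: dict[str, list[Placement]] = {}
    for read_id in sorted(by_read):
        kept = filter_read_placements(by_read[read_id], params)
        if kept:
            out[read_id] = kept
    return out
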