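"""Readers and writers for the external formats the scaffolder touches.

All alignment coordinates are held internally as 0-based half-open intervals
on the *forward* strand of the contig, regardless of the convention of the
source format (PAF is already forward-strand; BLASR m4 reports reverse-strand
target hits in reverse-strand coordinates and is flipped on input). AGP output
converts to its native 1-based inclusive coordinates at the single point of
serialization.
"""

from __future__ import annotations

import gzip
import logging
import sys
from dataclasses import dataclass, field
from typing import IO, Iterator, Optional, Sequence

from Bio.Seq import reverse_complement as _bio_rc

log = logging.getLogger(__name__)

__all__ = [
    "Contig",
    "RawAlignment",
    "AgpRow",
    "read_fasta",
    "read_reads",
    "parse_alignments",
    "alignment_to_paf",
    "alignment_to_m4",
    "write_scaffolds_fasta",
    "write_agp",
    "parse_agp",
    "write_summary",
    "scaffold_sequence",
    "assign_scaffold_ids",
    "revcomp",
    "n50",
]


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware via Biopython)."""
    return _bio_rc(seq)


def n50(lengths: Sequence[int]) -> int:
    """N50: the largest L such that pieces of length >= L hold >= 50% of the bases."""
    if not lengths:
        return 0
    total = sum(lengths)
    acc = 0
    for x in sorted(lengths, reverse=True):
        acc += x
        if 2 * acc >= total:
            return x
    return 0  # pragma: no cover


@dataclass(frozen=True)
class Contig:
    """One gapless draft-assembly sequence.

    ``sequence`` may be None in alignment-only workflows where no output FASTA
    is requested; ``length`` is then taken from the alignment file's target
    length column.
    """

    id: str
    length: int
    sequence: Optional[str] = None

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"contig {self.id}: non-positive length {self.length}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"contig {self.id}: length {self.length} != sequence length "
                f"{len(self.sequence)}"
            )


@dataclass(frozen=True)
class RawAlignment:
    """A single read-to-contig local alignment, normalized.

    read and contig intervals are 0-based half-open; contig coordinates are on
    the contig's forward strand. ``strand`` is '+' when the read aligns to the
    forward strand of the contig. ``score`` is the aligner's score stored as a
    positive magnitude (m4 scores are negative-is-better and are negated on
    input); ``identity`` is a fraction in [0, 1]. ``block_len`` and ``mapq``
    are carried through untouched so records can be re-serialized exactly.
    """

    read_id: str
    read_len: int
    read_start: int
    read_end: int
    contig_id: str
    contig_len: int
    contig_start: int
    contig_end: int
    strand: str
    score: int
    identity: float
    block_len: int = 0
    mapq: int = 255

    def __post_init__(self):
        if not (0 <= self.read_start < self.read_end <= self.read_len):
            raise ValueError(
                f"{self.read_id}: bad read interval "
                f"[{self.read_start},{self.read_end}) len {self.read_len}"
            )
        if not (0 <= self.contig_start < self.contig_end <= self.contig_len):
            raise ValueError(
                f"{self.read_id}->{self.contig_id}: bad contig interval "
                f"[{self.contig_start},{self.contig_end}) len {self.contig_len}"
            )
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError(f"identity {self.identity} outside [0,1]")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


# ---------------------------------------------------------------------------
# FASTA / FASTQ input
# ---------------------------------------------------------------------------


def _open_maybe_gzip(path) -> IO[str]:
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path) -> list[Contig]:
    """Read an assembly FASTA into a list of Contig.

    Record ids are the first whitespace-delimited token of the header;
    sequences are uppercased. Duplicate ids and empty files are errors.
    """
    contigs: list[Contig] = []
    seen: set[str] = set()
    with _open_maybe_gzip(path) as fh:
        name = None
        chunks: list[str] = []

        def flush():
            if name is None:
                return
            seq = "".join(chunks).upper()
            if not seq:
                raise ValueError(f"empty sequence for record {name} in {path}")
            contigs.append(Contig(name, len(seq), seq))

        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise ValueError(f"record with empty header in {path}")
                if name in seen:
                    raise ValueError(f"duplicate id {name} in {path}")
                seen.add(name)
                chunks = []
            else:
                if name is None:
                    raise ValueError(f"{path}: sequence before first header")
                chunks.append(line)
        flush()
    if not contigs:
        raise ValueError(f"no FASTA records in {path}")
    return contigs


def read_reads(path) -> Iterator[tuple[str, int, Optional[str]]]:
    """Stream long reads from FASTA or FASTQ (optionally gzipped).

    Yields (read_id, length, sequence). The format is auto-detected from the
    first byte; FASTQ qualities are checked for length and discarded.
    """
    fh = _open_maybe_gzip(path)
    try:
        first = fh.read(1)
        if not first:
            return
        rest = fh
        if first == ">":
            yield from _stream_fasta_reads(rest)
        elif first == "@":
            yield from _stream_fastq_reads(rest)
        else:
            raise ValueError(f"{path}: not FASTA or FASTQ (first byte {first!r})")
    finally:
        fh.close()


def _stream_fasta_reads(fh: IO[str]) -> Iterator[tuple[str, int, str]]:
    # first '>' already consumed
    name = fh.readline().split()[0]
    chunks: list[str] = []
    for line in fh:
        line = line.rstrip("\n")
        if line.startswith(">"):
            yield name, sum(map(len, chunks)), "".join(chunks).upper()
            name = line[1:].split()[0]
            chunks = []
        elif line:
            chunks.append(line)
    yield name, sum(map(len, chunks)), "".join(chunks).upper()


def _stream_fastq_reads(fh: IO[str]) -> Iterator[tuple[str, int, str]]:
    # first '@' already consumed; assumes 4-line records (long-read FASTQ is)
    header = fh.readline().rstrip("\n")
    while True:
        name = header.split()[0]
        seq = fh.readline().rstrip("\n")
        plus = fh.readline()
        qual = fh.readline().rstrip("\n")
        if not plus or not plus.startswith("+"):
            raise ValueError(f"truncated record {name}")
        if not qual and seq:
            raise ValueError(f"truncated record {name}")
        if len(seq) != len(qual):
            raise ValueError(
                f"record {name}: sequence length {len(seq)} != quality length {len(qual)}"
            )
        yield name, len(seq), seq.upper()
        nxt = fh.readline()
        if not nxt:
            return
        if not nxt.startswith("@"):
            raise ValueError(f"truncated record after {name}")
        header = nxt[1:].rstrip("\n")


# ---------------------------------------------------------------------------
# Alignment input (PAF / BLASR m4)
# ---------------------------------------------------------------------------


def parse_alignments(path, format: str) -> list[RawAlignment]:
    """Parse read-to-contig alignments from PAF or BLASR m4 into RawAlignment.

    PAF (minimap2 dialect, columns 1-12): score = residue matches (col 10),
    identity = col10/col11. m4 (13 whitespace columns: qname tname score
    pctsimilarity qstrand qstart qend qseqlength tstrand tstart tend
    tseqlength mapqv): strand is the product of qstrand/tstrand, coordinates
    reported on a reverse strand are flipped to forward, identity =
    pctsimilarity/100 and score is the magnitude of the (negative-is-better)
    m4 score.
    """
    if format not in ("paf", "m4"):
        raise ValueError(f"unknown alignment format {format!r}")
    out: list[RawAlignment] = []
    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            try:
                if format == "paf":
                    out.append(_parse_paf_cols(cols))
                else:
                    out.append(_parse_m4_cols(cols))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed {format} record: {exc}") from exc
    if not out:
        log.warning("no alignments parsed from %s", path)
    return out


def _parse_paf_cols(c: list[str]) -> RawAlignment:
    if len(c) < 12:
        raise ValueError(f"PAF needs >= 12 columns, got {len(c)}")
    block = int(c[10])
    # Without a base-level alignment (-c), col 10 underestimates matches;
    # prefer the per-base divergence tags when the aligner provides them.
    identity = int(c[9]) / block if block else 0.0
    for tag in c[12:]:
        if tag.startswith(("de:f:", "dv:f:")):
            identity = max(0.0, 1.0 - float(tag[5:]))
            break
    return RawAlignment(
        read_id=c[0],
        read_len=int(c[1]),
        read_start=int(c[2]),
        read_end=int(c[3]),
        strand=c[4],
        contig_id=c[5],
        contig_len=int(c[6]),
        contig_start=int(c[7]),
        contig_end=int(c[8]),
        score=int(c[9]),
        identity=identity,
        block_len=block,
        mapq=int(c[11]),
    )


def _parse_m4_cols(c: list[str]) -> RawAlignment:
    if len(c) < 13:
        raise ValueError(f"m4 needs 13 columns, got {len(c)}")
    (qname, tname, score, pctsim, qstrand, qstart, qend, qlen,
     tstrand, tstart, tend, tlen, mapqv) = c[:13]
    qstrand, tstrand = int(qstrand), int(tstrand)
    qs, qe, qlen = int(qstart), int(qend), int(qlen)
    ts, te, tlen = int(tstart), int(tend), int(tlen)
    if qstrand == 1:
        qs, qe = qlen - qe, qlen - qs
    if tstrand == 1:
        ts, te = tlen - te, tlen - ts
    return RawAlignment(
        read_id=qname,
        read_len=qlen,
        read_start=qs,
        read_end=qe,
        strand="+" if qstrand == tstrand else "-",
        contig_id=tname,
        contig_len=tlen,
        contig_start=ts,
        contig_end=te,
        score=abs(int(score)),
        identity=float(pctsim) / 100.0,
        block_len=max(qe - qs, te - ts),
        mapq=int(mapqv),
    )


def alignment_to_paf(a: RawAlignment) -> str:
    """Serialize back to a 12-column PAF line (inverse of the PAF parser)."""
    return "\t".join(
        str(x)
        for x in (
            a.read_id, a.read_len, a.read_start, a.read_end, a.strand,
            a.contig_id, a.contig_len, a.contig_start, a.contig_end,
            a.score, a.block_len, a.mapq,
        )
    )


def alignment_to_m4(a: RawAlignment) -> str:
    """Serialize back to a 13-column m4 line using the qstrand=0 convention."""
    if a.strand == "+":
        ts, te, tstrand = a.contig_start, a.contig_end, 0
    else:
        ts, te = a.contig_len - a.contig_end, a.contig_len - a.contig_start
        tstrand = 1
    pct = a.identity * 100.0
    pct_s = f"{pct:.4f}".rstrip("0").rstrip(".") if pct != int(pct) else str(int(pct))
    return " ".join(
        str(x)
        for x in (
            a.read_id, a.contig_id, -a.score, pct_s, 0,
            a.read_start, a.read_end, a.read_len,
            tstrand, ts, te, a.contig_len, a.mapq,
        )
    )


# ---------------------------------------------------------------------------
# Scaffold output (FASTA / AGP / summary)
# ---------------------------------------------------------------------------


@dataclass
class AgpRow:
    """One AGP v2.1 row; 1-based inclusive object/component coordinates."""

    object_id: str
    object_beg: int
    object_end: int
    part_number: int
    component_type: str  # 'W' or 'N'
    component_id: Optional[str] = None
    component_beg: Optional[int] = None
    component_end: Optional[int] = None
    orientation: Optional[str] = None
    gap_length: Optional[int] = None
    gap_type: str = "scaffold"
    linkage: str = "yes"
    linkage_evidence: str = "align_genus"

    def to_line(self) -> str:
        if self.component_type == "W":
            tail = (self.component_id, self.component_beg, self.component_end,
                    self.orientation)
        else:
            tail = (self.gap_length, self.gap_type, self.linkage,
                    self.linkage_evidence)
        return "\t".join(
            str(x)
            for x in (self.object_id, self.object_beg, self.object_end,
                      self.part_number, self.component_type, *tail)
        )


def _part_emit_range(part, contig_len: int) -> tuple[int, int]:
    """0-based half-open range of the original contig emitted for this part.

    Merge junctions trim the *leading* bases of the downstream part's oriented
    sequence; ``trim_head``/``trim_tail`` count trimmed oriented bases.
    """
    th = getattr(part, "trim_head", 0)
    tt = getattr(part, "trim_tail", 0)
    if part.orientation == "+":
        return th, contig_len - tt
    return tt, contig_len - th


def scaffold_sequence(scaffold, contig_map: dict[str, Contig]) -> str:
    """Assemble the emitted nucleotide sequence of a scaffold.

    Reverse-oriented parts are reverse-complemented; merge overlaps have
    already been converted to per-part head trims; gaps become runs of N.
    """
    pieces: list[str] = []
    for part in scaffold.parts:
        contig = contig_map.get(part.contig_id)
        if contig is None or contig.sequence is None:
            raise ValueError(f"missing sequence for contig {part.contig_id}")
        beg, end = _part_emit_range(part, contig.length)
        seq = contig.sequence[beg:end]
        if part.orientation == "-":
            seq = revcomp(seq)
        pieces.append(seq)
        j = part.junction_after
        if j is not None and j.kind == "gap" and j.gap_len > 0:
            pieces.append("N" * j.gap_len)
    return "".join(pieces)


def assign_scaffold_ids(scaffolds, contig_map: dict[str, Contig]) -> None:
    """Name scaffolds scaffold_1..n by descending emitted length, ties by first contig id."""
    def key(s):
        return (-s.emitted_length(contig_map), s.parts[0].contig_id)

    scaffolds.sort(key=key)
    for i, s in enumerate(scaffolds, 1):
        s.id = f"scaffold_{i}"


def write_scaffolds_fasta(scaffolds, contig_map: dict[str, Contig], path,
                          width: int = 70) -> None:
    """Write the final linear assembly FASTA (one record per scaffold)."""
    with open(path, "w") as fh:
        for s in scaffolds:
            seq = scaffold_sequence(s, contig_map)
            fh.write(f">{s.id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def scaffold_agp_rows(scaffold, contig_map: dict[str, Contig]) -> list[AgpRow]:
    rows: list[AgpRow] = []
    pos = 0  # 0-based running cursor on the object
    part_no = 0
    for part in scaffold.parts:
        contig = contig_map[part.contig_id]
        beg, end = _part_emit_range(part, contig.length)
        span = end - beg
        part_no += 1
        rows.append(AgpRow(
            object_id=scaffold.id,
            object_beg=pos + 1,
            object_end=pos + span,
            part_number=part_no,
            component_type="W",
            component_id=part.contig_id,
            component_beg=beg + 1,
            component_end=end,
            orientation=part.orientation,
        ))
        pos += span
        j = part.junction_after
        if j is not None and j.kind == "gap" and j.gap_len > 0:
            part_no += 1
            rows.append(AgpRow(
                object_id=scaffold.id,
                object_beg=pos + 1,
                object_end=pos + j.gap_len,
                part_number=part_no,
                component_type="N",
                gap_length=j.gap_len,
            ))
            pos += j.gap_len
    return rows


def write_agp(scaffolds, contig_map: dict[str, Contig], path) -> None:
    """Write AGP v2.1 describing contig order/orientation and gaps.

    Merged junctions produce no N row (the downstream component simply starts
    past its overlap); object extents match the FASTA sequence exactly.
    """
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for s in scaffolds:
            for row in scaffold_agp_rows(s, contig_map):
                fh.write(row.to_line() + "\n")


def parse_agp(path) -> dict[str, list[AgpRow]]:
    """Parse an AGP file into rows grouped by object, validating the tiling."""
    objects: dict[str, list[AgpRow]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            c = line.split("\t")
            row = AgpRow(
                object_id=c[0], object_beg=int(c[1]), object_end=int(c[2]),
                part_number=int(c[3]), component_type=c[4],
            )
            if row.component_type == "N":
                row.gap_length = int(c[5])
                row.gap_type, row.linkage = c[6], c[7]
                row.linkage_evidence = c[8] if len(c) > 8 else "na"
            else:
                row.component_id = c[5]
                row.component_beg, row.component_end = int(c[6]), int(c[7])
                row.orientation = c[8]
            objects.setdefault(row.object_id, []).append(row)
    for oid, rows in objects.items():
        pos = 0
        for i, row in enumerate(rows, 1):
            if row.part_number != i or row.object_beg != pos + 1:
                raise ValueError(f"{path}: object {oid} rows do not tile")
            pos = row.object_end
    return objects


def write_summary(run_stats: dict, path) -> None:
    """Write the plain-text run summary."""
    lines = ["lrstitch assembly summary", "=" * 40]

    def section(title, items):
        lines.append("")
        lines.append(title)
        lines.append("-" * len(title))
        for k, v in items:
            lines.append(f"  {k}: {v}")

    section("Input contigs", [
        ("count", run_stats.get("input_contigs", 0)),
        ("total bases", run_stats.get("input_bases", 0)),
        ("N50", run_stats.get("input_n50", 0)),
    ])
    section("Final scaffolds", [
        ("count", run_stats.get("scaffold_count", 0)),
        ("total bases", run_stats.get("scaffold_bases", 0)),
        ("N50", run_stats.get("scaffold_n50", 0)),
        ("circular", run_stats.get("circular_scaffolds", 0)),
    ])
    section("Junctions", [
        ("gap bases inserted", run_stats.get("gap_bases", 0)),
        ("merged junctions", run_stats.get("merged_junctions", 0)),
    ])
    section("Repeats", [
        ("contigs flagged repeat", run_stats.get("repeat_contigs", 0)),
        ("repeat placements", run_stats.get("repeat_placements", 0)),
    ])
    for key in ("alignments_read", "placements_kept", "links", "accepted_links"):
        if key in run_stats:
            lines.append(f"  {key.replace('_', ' ')}: {run_stats[key]}")
    with open(path, "w") as fh:
        fh.write("\n".join(str(x) for x in lines) + "\n")
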