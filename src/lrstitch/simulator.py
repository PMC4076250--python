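"""Synthetic genomes, draft contigs, CLR-like long reads and ground truth.

The generator emulates the study conditions of bacterial draft-scaffolding:
desk-scale genomes (0.1-5 Mb), optionally carrying planted repeat families
whose near-identical copies fragment the draft, contigs broken either at
repeat boundaries (the behaviour of repeat-aware assemblers) or at random
positions, and uncorrected long reads with lognormal lengths around 2.5 kb
and ~15% indel-dominated error.

Two read products are offered. ``simulate_reads`` writes actual noisy
sequences (FASTQ) for alignment-based workflows and error-model checks.
``simulate_placements`` bypasses sequence space entirely: it emits the
placement records an ideal aligner would recover from the same sampled read
intervals, with read-coordinate distortion drawn from the configured indel
mix, so linkage and scaffolding can be exercised deterministically and fast.

All randomness flows through numpy Generators seeded as
``default_rng([seed, stream])`` with a fixed stream id per stage, so every
product is reproducible from the single config seed and the read intervals
used by ``simulate_reads`` and ``simulate_placements`` are identical.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .alignment_filter import Placement
from .io_formats import Contig, n50, revcomp
from .scaffolder import Scaffold

log = logging.getLogger(__name__)

__all__ = [
    "SimConfig", "TruthPlacement", "TruthLayout",
    "simulate_genome", "fragment_contigs", "simulate_read_intervals",
    "simulate_reads", "write_reads_fastq", "simulate_placements",
    "evaluate", "EvalReport",
]

# RNG stream ids (stable protocol; see module docstring)
_S_GENOME, _S_FRAGMENT, _S_INTERVALS, _S_ERRORS, _S_PLACE = 0, 1, 2, 3, 4

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the long-read regime the method targets: mean CLR length
    2.5 kb (lognormal, shape 0.4), 15% total error split 50/35/15 between
    insertions, deletions and substitutions, and true inter-contig gaps
    uniform on [gap_min, gap_max] (negative gap_min creates genuinely
    overlapping contigs, exercising the merge path).
    """

    genome_len: int = 200_000
    repeat_families: list[tuple[int, int]] = field(default_factory=list)
    n_contigs: int = 20
    break_at_repeats: bool = False
    coverage: float = 20.0
    read_len_mean: int = 2500
    read_len_sigma: float = 0.4
    error_rate: float = 0.15
    error_mix: tuple[float, float, float] = (0.50, 0.35, 0.15)
    gap_min: int = 0
    gap_max: int = 500
    circular: bool = False
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.error_mix) - 1.0) > 1e-9:
            raise ValueError("error_mix must sum to 1")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0,1)")
        if self.gap_min > self.gap_max:
            raise ValueError("gap_min > gap_max")


@dataclass(frozen=True)
class TruthPlacement:
    contig_id: str
    start: int
    end: int
    orientation: str = "+"


@dataclass
class TruthLayout:
    """Ground-truth contig layout on the simulated genome."""

    genome_len: int
    placements: list[TruthPlacement]
    circular: bool = False

    def multiplicity(self) -> Counter:
        return Counter(p.contig_id for p in self.placements)

    def adjacencies(self) -> list[tuple[str, str, str, str, int]]:
        """(A, orientA, B, orientB, gap) for every true junction, in order."""
        out = []
        ps = self.placements
        for a, b in zip(ps, ps[1:]):
            out.append((a.contig_id, a.orientation, b.contig_id, b.orientation,
                        b.start - a.end))
        if self.circular and len(ps) > 1:
            a, b = ps[-1], ps[0]
            out.append((a.contig_id, a.orientation, b.contig_id, b.orientation,
                        self.genome_len - a.end + b.start))
        return out

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#genome_len={self.genome_len}\tcircular={int(self.circular)}\n")
            fh.write("contig\tstart\tend\torientation\n")
            for p in self.placements:
                fh.write(f"{p.contig_id}\t{p.start}\t{p.end}\t{p.orientation}\n")

    @classmethod
    def from_tsv(cls, path) -> "TruthLayout":
        placements = []
        genome_len, circular = 0, False
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    for tok in line[1:].split("\t"):
                        k, _, v = tok.partition("=")
                        if k == "genome_len":
                            genome_len = int(v)
                        elif k == "circular":
                            circular = bool(int(v))
                    continue
                if not line or line.startswith("contig\t"):
                    continue
                cid, s, e, o = line.split("\t")
                placements.append(TruthPlacement(cid, int(s), int(e), o))
        return cls(genome_len, placements, circular)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def simulate_genome(config: SimConfig) -> tuple[str, list[tuple[int, int, int, int]]]:
    """Uniform-random genome with planted repeat families.

    Returns (sequence, annotation) where annotation rows are
    (family_index, copy_index, start, end). Copies of a family are pasted at
    non-overlapping positions with 1% substitution divergence (>= 97%
    identical by construction).
    """
    rng = _rng(config, _S_GENOME)
    G = config.genome_len
    seq = np.frombuffer(_random_seq(rng, G).encode(), dtype=np.uint8).copy()
    annotation: list[tuple[int, int, int, int]] = []
    occupied: list[tuple[int, int]] = []
    total_repeat = sum(u * c for u, c in config.repeat_families)
    if total_repeat > G // 2:
        raise ValueError("repeats exceed genome capacity")
    margin = max(1000, min(5000, G // 20))
    for fam, (unit_len, copies) in enumerate(config.repeat_families):
        unit = np.frombuffer(_random_seq(rng, unit_len).encode(), dtype=np.uint8)
        for copy in range(copies):
            for _attempt in range(500):
                pos = int(rng.integers(margin, G - unit_len - margin))
                if all(pos + unit_len + margin <= s or pos >= e + margin
                       for s, e in occupied):
                    break
            else:
                raise ValueError("repeats exceed genome capacity (placement failed)")
            variant = unit.copy()
            nsub = rng.binomial(unit_len, 0.01)
            if nsub:
                sites = rng.choice(unit_len, size=nsub, replace=False)
                variant[sites] = _BASES[(np.searchsorted(
                    _BASES, variant[sites]) + rng.integers(1, 4, nsub)) % 4]
            seq[pos:pos + unit_len] = variant
            occupied.append((pos, pos + unit_len))
            annotation.append((fam, copy, pos, pos + unit_len))
    annotation.sort(key=lambda r: r[2])
    return seq.tobytes().decode(), annotation


def fragment_contigs(genome: str, annotation: list[tuple[int, int, int, int]],
                     config: SimConfig) -> tuple[list[Contig], TruthLayout]:
    """Break the genome into draft contigs and record the truth layout.

    break_at_repeats: every repeat copy becomes one placement of a single
    shared repeat contig (sequence taken from the first copy) and the unique
    segments between copies become contigs; gaps are carved out of the unique
    side of each boundary. Otherwise n_contigs jittered-even breakpoints are
    used and each junction loses a uniform [gap_min, gap_max] stretch of
    genome (negative values make adjacent contigs overlap).
    """
    rng = _rng(config, _S_FRAGMENT)
    G = config.genome_len

    def gap() -> int:
        return int(rng.integers(config.gap_min, config.gap_max + 1))

    placements: list[TruthPlacement] = []
    contigs: dict[str, Contig] = {}

    if config.break_at_repeats and annotation:
        fam_id = {fam: f"R{fam:02d}" for fam, *_ in annotation}
        bounds = [(s, e, fam) for fam, _c, s, e in annotation]
        cursor, u = 0, 0
        for s, e, fam in bounds:
            g_right = max(0, gap())
            u_start, u_end = cursor, s - g_right
            if u_end - u_start >= 200:
                cid = f"U{u:02d}"
                u += 1
                contigs[cid] = Contig(cid, u_end - u_start, genome[u_start:u_end])
                placements.append(TruthPlacement(cid, u_start, u_end))
            rid = fam_id[fam]
            if rid not in contigs:
                contigs[rid] = Contig(rid, e - s, genome[s:e])
            placements.append(TruthPlacement(rid, s, e))
            cursor = e + max(0, gap())
        if G - cursor >= 200:
            cid = f"U{u:02d}"
            contigs[cid] = Contig(cid, G - cursor, genome[cursor:G])
            placements.append(TruthPlacement(cid, cursor, G))
    else:
        n = config.n_contigs
        if n < 1 or G // n <= 2 * (abs(config.gap_min) + config.gap_max + 300):
            raise ValueError(f"{n} contigs infeasible for genome of {G} bp")
        step = G / n
        jitter = int(step * 0.2)
        bps = [0]
        for i in range(1, n):
            b = round(step * i) + int(rng.integers(-jitter, jitter + 1))
            bps.append(b)
        bps.append(G)
        n_gaps = n if config.circular else n - 1
        gaps = [gap() for _ in range(n_gaps)]
        width = len(str(n))
        for i in range(n):
            start = bps[i]
            end = bps[i + 1] - (gaps[i] if i < len(gaps) else 0)
            cid = f"contig_{i + 1:0{width}d}"
            contigs[cid] = Contig(cid, end - start, genome[start:end])
            placements.append(TruthPlacement(cid, start, end))

    layout = TruthLayout(G, placements, circular=config.circular)
    ordered = [contigs[cid] for cid in sorted(contigs)]
    return ordered, layout


def simulate_read_intervals(config: SimConfig, rng: np.random.Generator
                            ) -> list[tuple[str, int, int, str]]:
    """Sampled read intervals: (read_id, genome_start, genome_end, strand).

    The read count is fixed up front as round(coverage * G / mean length);
    lengths are lognormal truncated to [300, G]; starts are uniform; on a
    circular genome reads wrap (end may exceed G).
    """
    G = config.genome_len
    n = round(config.coverage * G / config.read_len_mean)
    mu = math.log(config.read_len_mean) - config.read_len_sigma ** 2 / 2
    out = []
    for i in range(n):
        L = int(round(rng.lognormal(mu, config.read_len_sigma)))
        L = max(300, min(L, G))
        if config.circular:
            start = int(rng.integers(0, G))
            end = start + L
        else:
            start = int(rng.integers(0, G - L + 1))
            end = start + L
        strand = "+" if rng.random() < 0.5 else "-"
        out.append((f"read_{i:06d}", start, end, strand))
    return out


def _apply_errors(seq: str, config: SimConfig, rng: np.random.Generator) -> str:
    e = config.error_rate
    if e == 0:
        return seq
    ins_f, del_f, sub_f = config.error_mix
    out: list[str] = []
    hit = rng.random(len(seq)) < e
    kind = rng.random(len(seq))
    extra = _BASES[rng.integers(0, 4, len(seq))].tobytes().decode()
    for i, base in enumerate(seq):
        if not hit[i]:
            out.append(base)
        elif kind[i] < ins_f:
            out.append(base)
            out.append(extra[i])
        elif kind[i] < ins_f + del_f:
            pass
        else:
            sub = extra[i]
            out.append(sub if sub != base else {"A": "C", "C": "G",
                                                "G": "T", "T": "A"}[base])
    return "".join(out)


def simulate_reads(genome: str, config: SimConfig) -> Iterator[tuple[str, str]]:
    """Yield (read_id, noisy sequence) for the sampled intervals."""
    intervals = simulate_read_intervals(config, _rng(config, _S_INTERVALS))
    err_rng = _rng(config, _S_ERRORS)
    G = len(genome)
    for rid, start, end, strand in intervals:
        if end <= G:
            seq = genome[start:end]
        else:
            seq = genome[start:] + genome[:end - G]
        if strand == "-":
            seq = revcomp(seq)
        yield rid, _apply_errors(seq, config, err_rng)


def write_reads_fastq(genome: str, config: SimConfig, path) -> int:
    n = 0
    with open(path, "w") as fh:
        for rid, seq in simulate_reads(genome, config):
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n


def simulate_placements(layout: TruthLayout, config: SimConfig
                        ) -> dict[str, list[Placement]]:
    """Placement records an ideal aligner would produce for the sampled reads.

    Read coordinates are distorted by the indel mix: each genomic segment of
    length m between truth boundaries maps to m + Binom(m, e*ins) -
    Binom(m, e*del) read bases, so gap estimates carry realistic noise while
    contig order and orientation stay exact. With error_rate 0 the mapping is
    the identity and every coordinate is exact. Repeat copies all map to the
    one shared repeat contig — copy ambiguity included.
    """
    intervals = simulate_read_intervals(config, _rng(config, _S_INTERVALS))
    rng = _rng(config, _S_PLACE)
    e = config.error_rate
    ins_f, del_f, _ = config.error_mix
    scale = 1.0 + e * (ins_f - del_f)
    G = layout.genome_len
    out: dict[str, list[Placement]] = {}

    # truth placements sorted by start for interval lookup
    truth = sorted(layout.placements, key=lambda p: p.start)
    starts = np.array([p.start for p in truth])

    for rid, rstart, rend, strand in intervals:
        span = rend - rstart
        segments = [(rstart, min(rend, G), -rstart)]
        if rend > G:  # circular wrap
            segments.append((0, rend - G, G - rstart))
        hits = []  # (aln_off_s, aln_off_e, ext_off_s, ext_off_e, cid)
        for seg_s, seg_e, off in segments:
            lo = int(np.searchsorted(starts, seg_s, side="left"))
            i = max(0, lo - 1)
            while i < len(truth) and truth[i].start < seg_e:
                p = truth[i]
                ov_s, ov_e = max(seg_s, p.start), min(seg_e, p.end)
                if ov_e - ov_s >= 20:
                    hits.append((ov_s + off, ov_e + off,
                                 p.start + off, p.end + off, p.contig_id))
                i += 1
        if not hits:
            continue
        # monotone coordinate distortion at the aligned boundaries
        bounds = sorted({0, span} | {h[0] for h in hits} | {h[1] for h in hits})
        bounds = [b for b in bounds if 0 <= b <= span]
        dmap = {bounds[0]: _distort_len(bounds[0], e, ins_f, del_f, rng)
                if bounds[0] > 0 else 0}
        for p, q in zip(bounds, bounds[1:]):
            dmap[q] = dmap[p] + _distort_len(q - p, e, ins_f, del_f, rng)
        noisy_span = dmap[span]

        def mapped(x: int) -> int:
            if x in dmap:
                return dmap[x]
            if x < 0:
                return int(round(x * scale))
            return noisy_span + int(round((x - span) * scale))

        placements = []
        for aln_s, aln_e, ext_s, ext_e, cid in hits:
            a_s, a_e = mapped(aln_s), mapped(aln_e)
            x_s, x_e = mapped(ext_s), mapped(ext_e)
            if a_e <= a_s:
                continue
            x_s, x_e = min(x_s, a_s), max(x_e, a_e)
            if strand == "-":
                a_s, a_e = noisy_span - a_e, noisy_span - a_s
                x_s, x_e = noisy_span - x_e, noisy_span - x_s
            placements.append(Placement(
                read_id=rid, contig_id=cid,
                strand="F" if strand == "+" else "R",
                aln_read_start=a_s, aln_read_end=a_e,
                ext_read_start=x_s, ext_read_end=x_e,
                score=a_e - a_s, identity=round(1.0 - e, 4),
            ))
        if placements:
            placements.sort(key=lambda p: (p.aln_read_start, p.contig_id))
            out[rid] = placements
    return out


def _distort_len(m: int, e: float, ins_f: float, del_f: float,
                 rng: np.random.Generator) -> int:
    if e == 0 or m <= 0:
        return m
    return int(m + rng.binomial(m, e * ins_f) - rng.binomial(m, e * del_f))


# ---------------------------------------------------------------------------
# Truth-based evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    scaffold_count: int
    scaffold_n50: int
    total_gap_bases: int
    correct_joins: int
    missed_joins: int
    misjoins: int
    repeat_placements_correct: int
    repeat_placements_incorrect: int
    gap_errors: list[int]
    circular_detected: int

    @property
    def max_gap_error(self) -> int:
        return max(self.gap_errors) if self.gap_errors else 0

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "scaffold_count", "scaffold_n50", "total_gap_bases",
            "correct_joins", "missed_joins", "misjoins",
            "repeat_placements_correct", "repeat_placements_incorrect",
            "circular_detected")}
        d["max_gap_error"] = self.max_gap_error
        d["mean_gap_error"] = (sum(self.gap_errors) / len(self.gap_errors)
                               if self.gap_errors else 0.0)
        return d


def _norm_junction(a: str, oa: str, b: str, ob: str):
    flip = {"+": "-", "-": "+"}
    j1 = (a, oa, b, ob)
    j2 = (b, flip[ob], a, flip[oa])
    return min(j1, j2)


def evaluate(scaffolds: list[Scaffold], layout: TruthLayout,
             contig_map: dict[str, Contig]) -> EvalReport:
    """Score a scaffolding run against the simulated truth.

    A predicted junction is *correct* when its (contig, orientation) pair
    matches a true adjacency (orientation-normalized; multi-copy truth
    junctions may each be matched once); anything else is a misjoin. Gap
    error is |emitted - true| per correct junction, where a merge counts as
    a negative emitted gap. Repeat placements are occurrences of multi-copy
    contigs inside multi-contig scaffolds, judged by their flanking junctions.
    """
    known = {p.contig_id for p in layout.placements}
    for s in scaffolds:
        for part in s.parts:
            if part.contig_id not in known:
                raise ValueError(f"contig {part.contig_id} unknown to truth")

    truth_pool: dict[tuple, list[int]] = {}
    for a, oa, b, ob, gap in layout.adjacencies():
        truth_pool.setdefault(_norm_junction(a, oa, b, ob), []).append(gap)
    total_truth = sum(len(v) for v in truth_pool.values())

    multi = {cid for cid, n in layout.multiplicity().items() if n > 1}

    correct = misjoins = 0
    gap_errors: list[int] = []
    rep_ok = rep_bad = 0
    total_gap_bases = 0
    lengths = []
    circular_detected = 0

    for s in scaffolds:
        lengths.append(s.emitted_length(contig_map))
        if s.circular:
            circular_detected += 1
        pairs = list(zip(s.parts, s.parts[1:]))
        junction_ok: list[bool] = []
        for x, y in pairs:
            j = x.junction_after
            emitted = (j.gap_len if j.kind == "gap" else -j.overlap_len) \
                if j is not None else 0
            if j is not None and j.kind == "gap":
                total_gap_bases += j.gap_len
            key = _norm_junction(x.contig_id, x.orientation,
                                 y.contig_id, y.orientation)
            gaps = truth_pool.get(key)
            if gaps:
                best = min(range(len(gaps)), key=lambda i: abs(gaps[i] - emitted))
                gap_errors.append(abs(gaps.pop(best) - emitted))
                correct += 1
                junction_ok.append(True)
            else:
                misjoins += 1
                junction_ok.append(False)
        if s.circular and s.closing_junction is not None and len(s.parts) > 1:
            x, y = s.parts[-1], s.parts[0]
            j = s.closing_junction
            emitted = j.gap_len if j.kind == "gap" else -j.overlap_len
            key = _norm_junction(x.contig_id, x.orientation,
                                 y.contig_id, y.orientation)
            gaps = truth_pool.get(key)
            if gaps:
                best = min(range(len(gaps)), key=lambda i: abs(gaps[i] - emitted))
                gap_errors.append(abs(gaps.pop(best) - emitted))
                correct += 1
            else:
                misjoins += 1
        if len(s.parts) > 1:
            for i, part in enumerate(s.parts):
                if part.contig_id in multi:
                    left_ok = junction_ok[i - 1] if i > 0 else True
                    right_ok = junction_ok[i] if i < len(pairs) else True
                    if left_ok and right_ok:
                        rep_ok += 1
                    else:
                        rep_bad += 1

    return EvalReport(
        scaffold_count=len(scaffolds),
        scaffold_n50=n50(lengths),
        total_gap_bases=total_gap_bases,
        correct_joins=correct,
        missed_joins=total_truth - correct,
        misjoins=misjoins,
        repeat_placements_correct=rep_ok,
        repeat_placements_incorrect=rep_bad,
        gap_errors=gap_errors,
        circular_detected=circular_detected,
    )
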