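# Methods

## Problem setting and model

`lrstitch` scaffolds a draft assembly — contigs produced by a short-read
assembler, assumed internally accurate — using uncorrected long reads as
ordering evidence. The underlying model is combinatorial rather than
probabilistic: every long read that aligns across a contig junction is an
independent witness of (i) which two contig ends are adjacent, (ii) their
relative orientation, and (iii) the distance between them. Because CLR-class
reads carry ~15% indel-dominated error, no single witness is trusted;
junctions are accepted only with multi-read support, and distances are taken
as medians over witnesses.

Coordinates are held internally as 0-based half-open intervals on the contig
forward strand; AGP output converts to 1-based inclusive at serialization.

## Pipeline stages

**Placement extension.** A local alignment covering contig interval
`[cs, ce)` of a contig of length `L` and read interval `[rs, re)` is
extended to the full contig span at the alignment's own scale
`s = (re-rs)/(ce-cs)`: the unaligned contig prefix projects `round(s*cs)`
bases before `rs` (after `re` for reverse-strand hits), and symmetrically
for the suffix. Extended coordinates are unclamped — they may be negative or
exceed the read length — because they exist solely so that the difference
between two projected spans on the same read estimates the inter-contig gap.

**Best-placement filtering.** Placements on one read are ranked by
(score, identity, contig id, position) and a placement is discarded when its
*aligned* interval overlaps any higher-ranked placement's by more than `g`
bases (default 200 bp; raise to ~500 for drafts that carry repeats on contig
edges). Two properties motivated comparing against all higher-ranked
placements rather than only surviving ones: the survivor set is then
monotone in `g`, and any two survivors overlap by at most `g`. Overlap is
measured on aligned, never extended, intervals — extended spans of contigs
flanking a true gap overlap routinely and would falsely trigger removal.

**Linkage.** Surviving placements sorted along each read produce pairwise
links between oriented contig ends (gap estimate = distance between the
projected spans, signed; negative means the contigs overlap) and, for every
run of ≥ 3 contigs, a multi-contig path (stored with all its contiguous
sub-paths, so a four-contig read also answers three-contig questions). Links
and paths are keyed canonically so the same physical junction observed on
either read strand collapses onto one key. For every consecutive triple
A→B→C a *span link* A–C keyed by intermediate B is also recorded; it lies
dormant unless B is later flagged as a repeat.

**Transitive reduction.** A direct link X–Y is deleted when a stored path
contains X and Y in the same junction frame with at least one intervening
contig; deletions are computed simultaneously against the original link set.
Such shortcuts arise when the aligner fails to place the middle contig on
some reads.

**Ambiguity resolution and repeat flagging.** Links with support below `k`
(default 3, suppressing isolated chimeric evidence) are dropped. For a
contig end with several surviving candidates, path evidence is consulted
first: exactly one candidate junction occurring inside a stored multi-contig
path wins; two or more path-corroborated candidates flag the end's contig as
a repeat. Only when no candidate has path evidence does the support ratio
decide (best wins if second/best ≤ 0.7). Path evidence deliberately outranks
the ratio: at a true two-copy repeat end *both* alternatives are real and
their support ratio fluctuates around 1 with coverage noise, so a lucky
60/40 split would otherwise "resolve" the repeat and strand a flanking
contig. Once a contig is flagged, its links leave the candidate pool, its
span links are promoted in their place (reconnecting the unique flanks
across the repeat), and resolution re-runs to a fixed point. A link is
accepted only when it is the chosen partner at both of its ends.

**Chaining, repeat placement, rejoining.** Accepted links induce chains and
cycles over contigs; chains become scaffolds (deterministic presentation:
the lexicographically smaller terminal contig comes first), cycles are
opened at their weakest-support junction and remembered as circular.
Repeat-flagged contigs are withheld from chaining and re-inserted afterwards
at junctions whose flanks are bridged by ≥ `k` read paths through the
repeat; a tie between two distinct repeats at one junction places neither.
Edge repeats of multi-contig scaffolds are stripped; a rejoin pass then
re-runs link acceptance restricted to the outward terminal ends of distinct
scaffolds and merges mutually chosen pairs, iterating to a fixed point.
Never-placed repeats are emitted once each as singletons so every input
contig is accounted for in the output.

**Junction resolution.** The point estimate for a junction is the lower
median of its per-read gap estimates. Positive → a gap of exactly that many
N's. Zero → exact abutment (no N inserted; the rule "negative → merge,
positive → gap" leaves zero to the implementation, and fabricating an N at a
zero-distance junction would be wrong). Negative → overlap search:
overlap lengths within ±`merge_band` (100 bp) of the estimate's magnitude,
at least `merge_min_overlap` (4 bp, guarding against chance micro-matches),
are scored by end-anchored edit-distance alignment (edlib) of the upstream
part's oriented suffix against the downstream part's oriented prefix, and
the junction becomes a merge when the best identity reaches
`merge_min_identity` (0.85 — safe because contigs are short-read-accurate);
otherwise a minimal gap of `min_gap_n` N's (1) records the unresolved join.
Without contig sequences (alignment-only mode) every junction becomes a gap
of `max(estimate, min_gap_n)`.

**Circularization.** A scaffold whose two terminal ends carry a surviving
link with support ≥ `k` is flagged circular; a merge closure trims the
terminal overlap from the emitted sequence. Output FASTA stays linear —
circularity is reported in the data model and summary only.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `g` | 200 bp | aligned-interval overlap that removes the lower-scoring placement |
| `min_identity` / `min_aln_len` | 0.70 / 100 bp | alignment pre-filters; 15%-error reads align well above 0.70 |
| `k` (`--min-links`) | 3 reads | support needed before a link is believed |
| `r` (`--ratio`) | 0.7 | max second/best support ratio for outright acceptance |
| `merge_min_identity` | 0.85 | identity bar for overlap merges |
| `merge_band` | 100 bp | slack around the estimated overlap length |
| `merge_min_overlap` | 4 bp | smallest overlap accepted as a merge |
| `min_gap_n` | 1 | N-run recorded for unconfirmed negative estimates |

## Synthetic data

The simulator emulates the conditions the method targets: bacterial-scale
genomes (0.1–5 Mb) of uniform-random sequence; planted repeat families whose
copies are ≥ 97% identical (1% substitution divergence); draft contigs cut
either at repeat boundaries (each family collapses to a single shared contig
with recorded multiplicity, as repeat-aware assemblers produce) or at
jittered-even random breakpoints; true inter-contig gaps uniform on
[0, 500] bp by default, sized so 2.5 kb reads span junctions (a negative
range creates genuinely overlapping contigs and exercises the merge path);
reads with lognormal lengths (mean 2.5 kb, shape 0.4), uniform starts
(wrapping on circular genomes), and 15% error split 50/35/15 between
insertion, deletion and substitution, an indel-dominant mix typical of CLR
chemistry.

Two read products share identically seeded intervals. `simulate_reads`
writes noisy sequences (FASTQ) for alignment-based runs and for empirical
checks of the error model. `simulate_placements` emits the placements an
ideal aligner would recover: contig order and orientation are exact, but
read coordinates pass through a monotone distortion in which each genomic
segment of length m maps to `m + Binom(m, e·ins) − Binom(m, e·del)` read
bases, so gap estimates carry realistic indel noise. All randomness flows
through `numpy` Generators seeded `default_rng([seed, stream])` with a fixed
stream id per stage, giving full cross-platform determinism.

What the simulator does *not* model: chimeric and adapter artifacts,
quality-value structure, non-uniform coverage, contig misassemblies, and
sequence-composition bias (real repeats are not random sequence). Passing
the synthetic batteries therefore demonstrates the correctness of the
linkage/scaffolding logic under the stated read geometry and error level,
not robustness to every failure mode of real libraries — the alignment-based
path with a real aligner (minimap2) is exercised separately.

## Study conditions used by the test batteries

Problem sizes were chosen at desk scale: noise-free recovery uses 200 kb /
20 contigs / 20× over 20 seeds; the noisy regime uses 500 kb / 40 contigs /
15% error / 50× over 20 seeds (the coverage at which fragmentation reduction
plateaus); the coverage sweep runs 5–50× over 10 seeds. The repeat battery
(2-copy 2 kb repeat, gaps up to 500 bp on both sides of each copy) uses 3 kb
mean reads at 60×: a read must span repeat plus both gaps plus two ≥ 100 bp
anchors (up to ~3.2 kb) to witness a copy's context, so repeat placement
needs deeper coverage than plain gap-spanning — the same asymmetry reported
for real long-read scaffolding.

## Known limitations

- Repeats longer than the read length cannot be phased to a copy and remain
  singleton scaffolds (flagged, never placed).
- Gap estimates inherit the ~15% coordinate noise of CLR reads; the lower
  median is robust but individual junctions can be tens of bp off.
- The evaluator matches junctions by (contig, orientation) pairs; a repeat
  placed at the wrong one of two *symmetric* junction contexts would be
  scored correct if the flanking pairs coincide.
- No gap filling or consensus polishing: emitted gaps are N-runs, merges use
  contig sequence only.
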