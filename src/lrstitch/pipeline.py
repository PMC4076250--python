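"""End-to-end scaffolding pipeline: placements -> linkage -> scaffolds.

This is the library-level entry point the CLI wraps. It accepts either raw
alignments (PAF/m4 records) or ready-made placement maps (as produced by the
simulator's ideal-aligner mode) and runs the full chain: per-read filtering,
linkage derivation, transitive reduction, ambiguity resolution with repeat
flagging, chaining, repeat placement, edge trimming, rejoining, junction
resolution and circular-replicon detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .alignment_filter import FilterParams, Placement, collect_placements
from .io_formats import Contig, RawAlignment, n50
from .linkage import (LinkageGraph, LinkParams, build_read_paths, derive_links,
                      remove_transitive_links, resolve_ambiguities)
from .scaffolder import (MergeParams, Scaffold, chain_scaffolds, circularize,
                         finalize_repeat_singletons, place_repeats,
                         rejoin_scaffolds, resolve_all_junctions,
                         trim_edge_repeats)
from .io_formats import assign_scaffold_ids

log = logging.getLogger(__name__)

__all__ = ["ScaffoldRun", "scaffold_assembly"]


@dataclass
class ScaffoldRun:
    scaffolds: list[Scaffold]
    graph: LinkageGraph
    repeat_flags: set[str]
    stats: dict = field(default_factory=dict)


def scaffold_assembly(contigs: dict[str, Contig],
                      alignments: list[RawAlignment] | None = None,
                      placements: dict[str, list[Placement]] | None = None,
                      filter_params: FilterParams | None = None,
                      link_params: LinkParams | None = None,
                      merge_params: MergeParams | None = None) -> ScaffoldRun:
    """Run the whole scaffolding chain and return scaffolds plus run stats.

    Exactly one of ``alignments`` / ``placements`` must be given. Contig
    sequences may be absent (alignment-only mode); junctions then resolve to
    gaps without overlap verification.
    """
    if (alignments is None) == (placements is None):
        raise ValueError("provide exactly one of alignments or placements")
    filter_params = filter_params or FilterParams()
    link_params = link_params or LinkParams()
    merge_params = merge_params or MergeParams()

    stats: dict = {
        "input_contigs": len(contigs),
        "input_bases": sum(c.length for c in contigs.values()),
        "input_n50": n50([c.length for c in contigs.values()]),
    }

    if placements is None:
        stats["alignments_read"] = len(alignments)
        placements = collect_placements(alignments, contigs, filter_params)
    else:
        placements = {rid: sorted(
            (p for p in pls
             if p.identity >= filter_params.min_identity
             and p.aln_read_end - p.aln_read_start >= filter_params.min_aln_len),
            key=lambda p: (p.aln_read_start, p.contig_id))
            for rid, pls in sorted(placements.items())}
        placements = {rid: pls for rid, pls in placements.items() if pls}
    stats["reads_with_placements"] = len(placements)
    stats["placements_kept"] = sum(len(v) for v in placements.values())

    read_paths = build_read_paths(placements)
    graph = derive_links(read_paths)
    stats["links"] = len(graph.links)
    remove_transitive_links(graph)
    stats["links_after_reduction"] = len(graph.links)

    accepted, repeat_flags = resolve_ambiguities(graph, link_params)
    stats["accepted_links"] = len(accepted)
    stats["repeat_contigs"] = len(repeat_flags)

    scaffolds = chain_scaffolds(accepted, contigs, repeat_flags)
    placed = place_repeats(scaffolds, graph, link_params, contigs)
    scaffolds = trim_edge_repeats(scaffolds, repeat_flags)
    scaffolds = rejoin_scaffolds(scaffolds, graph, link_params, repeat_flags)
    placed2 = place_repeats(scaffolds, graph, link_params, contigs)
    for cid, cnt in placed2.items():
        placed[cid] = placed.get(cid, 0) + cnt
    scaffolds = finalize_repeat_singletons(scaffolds, repeat_flags)
    stats["repeat_placements"] = sum(placed.values())

    resolve_all_junctions(scaffolds, contigs, merge_params)
    circularize(scaffolds, graph, link_params, contigs, merge_params)
    assign_scaffold_ids(scaffolds, contigs)

    stats["scaffold_count"] = len(scaffolds)
    stats["scaffold_bases"] = sum(s.emitted_length(contigs) for s in scaffolds)
    stats["scaffold_n50"] = n50([s.emitted_length(contigs) for s in scaffolds])
    stats["circular_scaffolds"] = sum(1 for s in scaffolds if s.circular)
    stats["gap_bases"] = sum(
        p.junction_after.gap_len
        for s in scaffolds for p in s.parts
        if p.junction_after is not None and p.junction_after.kind == "gap")
    stats["merged_junctions"] = sum(
        1 for s in scaffolds for p in s.parts
        if p.junction_after is not None and p.junction_after.kind == "merge")

    for key in ("placements_kept", "links", "accepted_links",
                "repeat_contigs", "scaffold_count"):
        log.info("%s: %s", key, stats[key])
    return ScaffoldRun(scaffolds, graph, repeat_flags, stats)
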