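"""Turn support matrices into graph edits and drive the full resolution loop.

Supported (in, out) pairings define a bipartite graph over the repeat's
neighbours.  Each connected component receives its own copy of the repeat
sequence; a perfect matching therefore fully linearises the region, while
larger components still split off what can be separated (partial
simplification).  Flank nodes with no supported partner only lose their
edge into the repeat when another pairing on the same side is supported,
so sequence is never stranded on a missed query.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .assembly_graph import (
    OrientedNode,
    SequenceGraph,
    merge_unambiguous_paths,
)
from .errors import ConfigurationError
from .kmer_bloom import build_read_index, theoretical_fpr
from .path_support import SupportMatrix, evaluate_repeat
from .repeat_finder import AlgorithmParams, RepeatSite, find_repeat_sites


@dataclass
class ResolutionEdit:
    site_id: str
    removed_in: List[OrientedNode] = field(default_factory=list)
    removed_out: List[OrientedNode] = field(default_factory=list)
    # (new node id, ins kept by this copy, outs kept by this copy)
    copies: List[Tuple[str, Tuple[OrientedNode, ...], Tuple[OrientedNode, ...]]] = field(
        default_factory=list
    )

    @property
    def is_full_resolution(self) -> bool:
        return bool(self.copies) and all(
            len(ins) == 1 and len(outs) == 1 for _, ins, outs in self.copies
        )

    def touched_node_ids(self) -> set:
        ids = {self.site_id}
        ids.update(on[0] for on in self.removed_in + self.removed_out)
        for _, ins, outs in self.copies:
            ids.update(on[0] for on in ins)
            ids.update(on[0] for on in outs)
        return ids


@dataclass
class IterationReport:
    read_length: int
    k_rresolver: int
    iteration: int
    sites_found: int = 0
    sites_skipped: int = 0
    skip_reasons: Dict[str, int] = field(default_factory=dict)
    sites_resolved: int = 0
    sites_simplified: int = 0
    sites_unchanged: int = 0
    edits_deferred: int = 0
    edges_removed: int = 0
    nodes_merged: int = 0
    bloom_bits: int = 0
    bloom_inserted: int = 0
    bloom_fpr: float = 0.0


@dataclass
class RunReport:
    rows: List[IterationReport] = field(default_factory=list)

    HEADER = (
        "read_length\tk_rresolver\titeration\tsites_found\tsites_skipped\t"
        "sites_resolved\tsites_simplified\tsites_unchanged\tedits_deferred\t"
        "edges_removed\tnodes_merged\tbloom_bits\tbloom_inserted\tbloom_fpr"
    )

    def to_tsv(self, path) -> None:
        with open(path, "wt") as out:
            out.write(self.HEADER + "\n")
            for r in self.rows:
                out.write(
                    f"{r.read_length}\t{r.k_rresolver}\t{r.iteration}\t"
                    f"{r.sites_found}\t{r.sites_skipped}\t{r.sites_resolved}\t"
                    f"{r.sites_simplified}\t{r.sites_unchanged}\t{r.edits_deferred}\t"
                    f"{r.edges_removed}\t{r.nodes_merged}\t{r.bloom_bits}\t"
                    f"{r.bloom_inserted}\t{r.bloom_fpr:.3e}\n"
                )

    def total_edits(self) -> int:
        return sum(
            r.sites_resolved + r.sites_simplified + r.edges_removed for r in self.rows
        )


def _components(
    supported: Sequence[Tuple[OrientedNode, OrientedNode]],
) -> List[Tuple[Tuple[OrientedNode, ...], Tuple[OrientedNode, ...]]]:
    """Connected components of the bipartite support graph, deterministic order."""
    parent: Dict[Tuple[str, OrientedNode], Tuple[str, OrientedNode]] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for inn, out in supported:
        for key in (("i", inn), ("o", out)):
            parent.setdefault(key, key)
        union(("i", inn), ("o", out))
    groups: Dict[object, Tuple[List[OrientedNode], List[OrientedNode]]] = {}
    for key in sorted(parent):
        side, on = key
        root = find(key)
        ins, outs = groups.setdefault(root, ([], []))
        (ins if side == "i" else outs).append(on)
    return [
        (tuple(sorted(ins)), tuple(sorted(outs)))
        for _, (ins, outs) in sorted(groups.items())
    ]


def plan_resolution(
    site: RepeatSite, matrix: SupportMatrix, params: AlgorithmParams
) -> Optional[ResolutionEdit]:
    """Build the edit for one site, or None when nothing can safely change."""
    if matrix.site_skipped:
        return None
    supported = sorted(
        pair for pair, ev in matrix.entries.items() if ev.supported
    )
    if not supported:
        return None  # no side has any support: removing everything strands sequence
    sup_ins = {inn for inn, _ in supported}
    sup_outs = {out for _, out in supported}
    edit = ResolutionEdit(site.repeat[0])
    # a flank with zero supported partners loses its repeat edge only because
    # at least one other pairing on its side is supported (guaranteed here by
    # `supported` being non-empty)
    edit.removed_in = sorted(set(site.ins) - sup_ins)
    edit.removed_out = sorted(set(site.outs) - sup_outs)
    comps = _components(supported)
    if len(comps) > 1:
        edit.copies = [
            (f"{site.repeat[0]}.{i}", ins, outs)
            for i, (ins, outs) in enumerate(comps)
        ]
    elif not edit.removed_in and not edit.removed_out:
        return None  # single component, nothing removed: no information gained
    return edit


def apply_edits(
    graph: SequenceGraph, edits: Sequence[ResolutionEdit]
) -> Tuple[SequenceGraph, List[ResolutionEdit], int, int]:
    """Apply non-conflicting edits atomically per site, then merge chains.

    Edits touching a node already modified in this pass are deferred to the
    next iteration.  Returns (graph, applied edits, deferred count,
    edges removed).
    """
    touched: set = set()
    applied: List[ResolutionEdit] = []
    deferred = 0
    edges_removed = 0
    for edit in edits:
        ids = edit.touched_node_ids()
        if ids & touched or edit.site_id not in graph.nodes:
            deferred += 1
            continue
        rep = (edit.site_id, "+")
        for inn in edit.removed_in:
            graph.remove_edge(inn, rep)
            edges_removed += 1
        for out in edit.removed_out:
            graph.remove_edge(rep, out)
            edges_removed += 1
        if edit.copies:
            orig = graph.nodes[edit.site_id]
            seq, cov = orig.sequence, orig.cov_sum / len(edit.copies)
            graph.remove_node(edit.site_id)
            for cid, ins, outs in edit.copies:
                graph.add_node(cid, seq, cov)
                for inn in ins:
                    graph.add_edge(inn, (cid, "+"))
                for out in outs:
                    graph.add_edge((cid, "+"), out)
        touched |= ids
        applied.append(edit)
    return graph, applied, deferred, edges_removed


def choose_k_rresolver(
    k_assembly: int, read_length: int, params: AlgorithmParams
) -> int:
    """User override, else k_assembly + 60 capped so t k-mers fit in a read."""
    if read_length <= k_assembly:
        raise ConfigurationError(
            f"read length {read_length} must exceed k_assembly {k_assembly}"
        )
    if params.k_rresolver is not None:
        k_rr = params.k_rresolver
    else:
        k_rr = min(k_assembly + 60, read_length - params.t + 1)
    if k_rr <= k_assembly:
        raise ConfigurationError(
            f"k_rresolver ({k_rr}) must exceed k_assembly ({k_assembly})"
        )
    if k_rr > read_length - params.t + 1:
        raise ConfigurationError(
            f"k_rresolver ({k_rr}) leaves fewer than t={params.t} k-mers "
            f"in a {read_length} bp read"
        )
    return k_rr


def resolve_graph(
    graph: SequenceGraph,
    libraries: Sequence,
    params: AlgorithmParams | None = None,
) -> Tuple[SequenceGraph, RunReport]:
    """Run the whole pipeline: per read size (shortest first), two passes each.

    Each pass finds repeat sites, evaluates their junction paths against the
    Bloom index of that library's reads, applies the planned edits and merges
    the resulting unambiguous chains.  Deterministic given ``params.seed``.
    """
    params = params or AlgorithmParams()
    params.validate()
    if not libraries:
        raise ConfigurationError("at least one read library is required")
    report = RunReport()
    rng = random.Random(params.seed)
    for library in sorted(libraries, key=lambda lib: lib.read_length):
        k_rr = choose_k_rresolver(graph.k_assembly, library.read_length, params)
        index, stats = build_read_index(library, k_rr, params)
        for iteration in range(1, params.iterations + 1):
            row = IterationReport(
                read_length=library.read_length,
                k_rresolver=k_rr,
                iteration=iteration,
                bloom_bits=getattr(index, "num_bits", 0),
                bloom_inserted=index.n_inserted,
                bloom_fpr=getattr(index, "fpr", 0.0),
            )
            sites = find_repeat_sites(graph)
            row.sites_found = len(sites)
            edits: List[ResolutionEdit] = []
            planned_sites = 0
            for site in sites:
                matrix = evaluate_repeat(
                    graph, site, index, library, k_rr, params, rng
                )
                if matrix.site_skipped:
                    row.sites_skipped += 1
                    for ev in matrix.entries.values():
                        if ev.verdict.is_skip:
                            row.skip_reasons[ev.verdict.value] = (
                                row.skip_reasons.get(ev.verdict.value, 0) + 1
                            )
                    continue
                edit = plan_resolution(site, matrix, params)
                if edit is None:
                    row.sites_unchanged += 1
                else:
                    edits.append(edit)
                    planned_sites += 1
            graph, applied, deferred, removed = apply_edits(graph, edits)
            row.edits_deferred = deferred
            row.edges_removed = removed
            row.sites_unchanged += deferred
            for edit in applied:
                if edit.is_full_resolution:
                    row.sites_resolved += 1
                else:
                    row.sites_simplified += 1
            graph, merges = merge_unambiguous_paths(graph)
            row.nodes_merged = merges
            report.rows.append(row)
    return graph, report
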