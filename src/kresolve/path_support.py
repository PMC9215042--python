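"""Sliding-window path evaluation against the read k-mer index.

For every (in, repeat, out) junction path the k_rresolver-sized window is
slid 1 bp at a time; each position queries the index for the canonical
window k-mer.  A path is supported once the hit count reaches the threshold
``t``.  When a flank node is too short for the window's reach, the paths
branching out of it are enumerated (breadth-first, capped per side) and the
path is supported if any combination is.
"""

from __future__ import annotations

import random
from collections import deque
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from .assembly_graph import OrientedNode, SequenceGraph, spell_path
from .errors import PathError
from .kmer_bloom import KmerBloomFilter, canonical_kmer_hashes
from .repeat_finder import (
    AlgorithmParams,
    RepeatSite,
    TestPlan,
    Verdict,
    plan_tests,
)

_ACGT = set("ACGT")


@dataclass
class PathEvaluation:
    path: Tuple[OrientedNode, ...]
    tests_done: int
    hits: int
    supported: Optional[bool]  # None when the verdict is a skip
    verdict: Verdict


@dataclass
class SupportMatrix:
    site: RepeatSite
    entries: Dict[Tuple[OrientedNode, OrientedNode], PathEvaluation]

    @property
    def site_skipped(self) -> bool:
        return any(ev.verdict.is_skip for ev in self.entries.values())


def count_window_hits(
    path_seq: str,
    start_low: int,
    start_high: int,
    index,
    k: int,
) -> Tuple[int, int]:
    """Query every window start in ``[start_low, start_high]`` (step 1 bp)."""
    if start_low < 0 or start_high < start_low or start_high + k > len(path_seq):
        raise PathError(
            f"window range [{start_low}, {start_high}] + k={k} exceeds "
            f"sequence of length {len(path_seq)}"
        )
    n = start_high - start_low + 1
    sub = path_seq[start_low : start_high + k]
    hits = 0
    if isinstance(index, KmerBloomFilter):
        for hashes in canonical_kmer_hashes(sub, k, index.h, index.salt):
            if index.query(hashes):
                hits += 1
    else:  # exact-set oracle: query canonical k-mer strings
        for i in range(n):
            if index.query_kmer(sub[i : i + k]):
                hits += 1
    return hits, n


def _side_paths(
    graph: SequenceGraph,
    anchor: OrientedNode,
    needed: int,
    forward: bool,
    cap: int,
) -> List[Tuple[OrientedNode, ...]]:
    """Enumerate flank extensions of ``anchor`` supplying ``needed`` extra bases.

    Breadth-first in id-sorted neighbour order so the result is deterministic
    under the per-side cap.  Branches stop as soon as their accumulated bases
    meet the requirement, or when no further extension exists.
    """
    if needed <= 0:
        return [(anchor,)]
    ov = graph.k_assembly - 1
    results: List[Tuple[OrientedNode, ...]] = []
    queue: deque = deque([((anchor,), 0)])
    while queue and len(results) < cap:
        path, bases = queue.popleft()
        frontier = path[-1] if forward else path[0]
        nbrs = (
            graph.out_neighbors(frontier) if forward else graph.in_neighbors(frontier)
        )
        used = {p[0] for p in path}
        nbrs = [x for x in nbrs if x[0] not in used]
        if not nbrs:
            results.append(path)  # dead end: take what the flank offers
            continue
        for nb in nbrs:
            ext = path + (nb,) if forward else (nb,) + path
            gained = bases + len(graph.nodes[nb[0]].sequence) - ov
            if gained >= needed:
                results.append(ext)
                if len(results) >= cap:
                    break
            else:
                queue.append((ext, gained))
    return results


def expand_complex_paths(
    graph: SequenceGraph,
    site: RepeatSite,
    inn: OrientedNode,
    out: OrientedNode,
    needed_left: int,
    needed_right: int,
    params: AlgorithmParams,
) -> List[Tuple[OrientedNode, ...]]:
    """All (capped) left x right flank-extension combinations of the triple."""
    lefts = _side_paths(graph, inn, needed_left, forward=False, cap=params.max_side_paths)
    rights = _side_paths(graph, out, needed_right, forward=True, cap=params.max_side_paths)
    rep = site.repeat
    # keep the repeat unique within each combination so window placement
    # relative to it is unambiguous
    lefts = [p for p in lefts if all(s[0] != rep[0] for s in p)]
    rights = [p for p in rights if all(s[0] != rep[0] for s in p)]
    return [left + (rep,) + right for left in lefts for right in rights]


def subsample_combinations(
    paths: List[Tuple[OrientedNode, ...]],
    params: AlgorithmParams,
    rng: random.Random,
) -> List[Tuple[OrientedNode, ...]]:
    """Uniformly subsample down to the combination cap when exceeded."""
    if len(paths) <= params.max_combinations:
        return paths
    return rng.sample(paths, params.max_combinations)


def _window_range_on(
    graph: SequenceGraph,
    combo: Tuple[OrientedNode, ...],
    repeat_index: int,
    k_rresolver: int,
    margin: int,
) -> Tuple[int, int, int]:
    """(start_low, start_high, spelled length) of valid windows on a combination."""
    ov = graph.k_assembly - 1
    rep_start = sum(len(graph.nodes[s[0]].sequence) - ov for s in combo[:repeat_index])
    L_rep = len(graph.nodes[combo[repeat_index][0]].sequence)
    total = sum(len(graph.nodes[s[0]].sequence) for s in combo) - (len(combo) - 1) * ov
    low = max(rep_start + L_rep + margin - k_rresolver, 0)
    high = min(rep_start - margin, total - k_rresolver)
    return low, high, total


def evaluate_path(
    graph: SequenceGraph,
    site: RepeatSite,
    inn: OrientedNode,
    out: OrientedNode,
    index,
    library,
    k_rresolver: int,
    params: AlgorithmParams,
    rng: random.Random,
) -> PathEvaluation:
    """Plan, expand if necessary, and slide the window over one junction path."""
    triple = (inn, site.repeat, out)
    plan = plan_tests(graph, site, inn, out, library, k_rresolver, params)
    if plan.verdict.is_skip:
        return PathEvaluation(triple, 0, 0, None, plan.verdict)

    ka = graph.k_assembly
    ov = ka - 1
    L_rep = len(graph.nodes[site.repeat[0]].sequence)
    need = k_rresolver - L_rep - params.margin
    avail_l = len(graph.nodes[inn[0]].sequence) - ov
    avail_r = len(graph.nodes[out[0]].sequence) - ov
    if avail_l >= need and avail_r >= need:
        combos = [triple]
    else:
        combos = expand_complex_paths(
            graph, site, inn, out, need - avail_l, need - avail_r, params
        )
        combos = subsample_combinations(combos, params, rng)

    best_hits = 0
    tests_done = 0
    for combo in combos:
        rep_idx = combo.index(site.repeat)
        low, high, _total = _window_range_on(
            graph, combo, rep_idx, k_rresolver, params.margin
        )
        if high < low:
            continue
        n_take = min(plan.tests, high - low + 1)
        seq = spell_path(graph, combo)
        if not set(seq) <= _ACGT:
            continue  # unhashable sequence: unsupported by construction
        hits, done = count_window_hits(seq, low, low + n_take - 1, index, k_rresolver)
        tests_done = max(tests_done, done)
        if hits > best_hits:
            best_hits = hits
        if best_hits >= params.t:
            break  # one supported combination suffices
    return PathEvaluation(
        triple, tests_done, best_hits, best_hits >= params.t, Verdict.PROCEED
    )


def evaluate_repeat(
    graph: SequenceGraph,
    site: RepeatSite,
    index,
    library,
    k_rresolver: int,
    params: AlgorithmParams,
    rng: random.Random,
) -> SupportMatrix:
    """Evaluate every (in, out) pairing of the site."""
    entries = {}
    for inn in site.ins:
        for out in site.outs:
            entries[(inn, out)] = evaluate_path(
                graph, site, inn, out, index, library, k_rresolver, params, rng
            )
    return SupportMatrix(site, entries)
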