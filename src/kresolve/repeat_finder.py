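"""Candidate repeat detection and coverage-adaptive test planning.

A repeat site is an oriented node with at least two predecessors and at
least two successors.  For each 3-node junction path through it, the number
of sliding-window membership tests is derived from the local read coverage:

    tests = ceil(max(m, s * f + t))      with  s = (L - l + 1) / R_p

where ``R_p`` is the estimated number of reads that contributed to the path
(its total k-mer multiplicity sum divided by the k-mers one read provides)
and ``L`` the spelled path length.  Repeats whose window cannot perform the
required number of moves, or that would need more than ``M`` tests, are
skipped entirely — partial information risks misjoins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import List, Optional, Tuple

from .assembly_graph import OrientedNode, SequenceGraph, path_length
from .errors import ConfigurationError


@dataclass
class AlgorithmParams:
    """Tunable constants; the defaults are the recommended values."""

    t: int = 4  # support threshold = k-mers stored per read
    m: int = 18  # minimum number of sliding-window tests
    M: int = 40  # maximum number of tests; above this the repeat is skipped
    f: float = 4.0  # inaccuracy correction factor on the spacing estimate
    margin: int = 2  # minimum window overlap on each adjacent node, bp
    h: int = 7  # Bloom filter hash functions
    max_side_paths: int = 75  # branch cap per side at complex repeats
    max_combinations: int = 5625  # total combination cap (= side cap squared)
    iterations: int = 2  # evaluation/resolution passes per read size
    k_rresolver: Optional[int] = None  # None = auto (k_assembly + 60, capped)
    bloom_bits: int = 1 << 29  # 64 MiB bit-vector budget
    seed: int = 0

    def validate(self) -> None:
        if self.t < 1:
            raise ConfigurationError("t must be >= 1")
        if self.m < self.t:
            raise ConfigurationError("m must be >= t")
        if self.M < self.m:
            raise ConfigurationError("M must be >= m")
        if self.f < 1:
            raise ConfigurationError("f must be >= 1")
        if self.margin < 0:
            raise ConfigurationError("margin must be >= 0")
        if self.max_combinations != self.max_side_paths**2:
            raise ConfigurationError("max_combinations must equal max_side_paths^2")
        if self.h < 1 or self.iterations < 1:
            raise ConfigurationError("h and iterations must be >= 1")


class Verdict(str, Enum):
    PROCEED = "proceed"
    SKIP_LOW_COVERAGE = "skip_low_coverage"
    SKIP_EXCEEDS_CAP = "skip_exceeds_cap"
    SKIP_TOO_FEW_POSITIONS = "skip_too_few_positions"

    @property
    def is_skip(self) -> bool:
        return self is not Verdict.PROCEED


@dataclass(frozen=True)
class RepeatSite:
    repeat: OrientedNode
    ins: Tuple[OrientedNode, ...]
    outs: Tuple[OrientedNode, ...]


@dataclass
class TestPlan:
    tests: int
    s: float
    R_p: float
    verdict: Verdict
    positions: int = 0  # window starts available after best-case flank extension


def find_repeat_sites(graph: SequenceGraph) -> List[RepeatSite]:
    """One site per node with in-degree >= 2 and out-degree >= 2.

    Each node is reported once in forward orientation (a node and its strand
    mirror are the same site).  Nodes adjacent to themselves are degenerate
    and excluded.
    """
    sites = []
    for nid in graph.node_ids():
        on = (nid, "+")
        ins = graph.in_neighbors(on)
        outs = graph.out_neighbors(on)
        if len(ins) < 2 or len(outs) < 2:
            continue
        if any(x[0] == nid for x in ins + outs):
            continue
        sites.append(RepeatSite(on, tuple(ins), tuple(outs)))
    return sites


def reads_on_path(
    graph: SequenceGraph, steps, read_length: int, k_assembly: int
) -> float:
    """Estimated reads contributing to the path: cov_sum / (l - k + 1)."""
    if read_length <= k_assembly:
        raise ConfigurationError(
            f"read length {read_length} must exceed k_assembly {k_assembly}"
        )
    cov = sum(graph.nodes[s[0]].cov_sum for s in steps)
    return cov / (read_length - k_assembly + 1)


def read_spacing(L: int, read_length: int, R_p: float) -> float:
    """Average bases between neighbouring read starts along the path."""
    if R_p <= 0:
        raise ValueError("R_p must be positive; zero coverage is a skip upstream")
    if L < read_length:
        return 0.0  # denser than one read span; the m-floor still applies
    return (L - read_length + 1) / R_p


def required_tests(s: float, params: AlgorithmParams) -> Tuple[int, Verdict]:
    """``ceil(max(m, s*f + t))``; above ``M`` the repeat must be skipped."""
    tests = math.ceil(max(params.m, s * params.f + params.t))
    if tests > params.M:
        return tests, Verdict.SKIP_EXCEEDS_CAP
    return tests, Verdict.PROCEED


def window_position_count(
    avail_left: int, L_repeat: int, avail_right: int, k_rresolver: int, margin: int
) -> int:
    """Number of window starts overlapping all three nodes by >= margin.

    Coordinates place the repeat at [0, L_repeat) on the spelled path with
    ``avail_left``/``avail_right`` flanking bases on each side.
    """
    low = max(L_repeat + margin - k_rresolver, -avail_left)
    high = min(-margin, L_repeat + avail_right - k_rresolver)
    return max(0, high - low + 1)


def repeat_eligible(
    L_repeat: int, k_rresolver: int, tests: int, margin: int
) -> bool:
    """L_repeat <= k_rresolver - (tests - 1) - 2*margin."""
    return L_repeat <= k_rresolver - (tests - 1) - 2 * margin


def max_flank_extension(
    graph: SequenceGraph,
    anchor: OrientedNode,
    needed: int,
    forward: bool,
    node_budget: int = 1000,
) -> int:
    """Best-case extra bases reachable beyond ``anchor``, capped at ``needed``.

    Bounded breadth-first search through predecessors (``forward=False``) or
    successors; used only to decide whether complex-path expansion could
    supply enough flank for the required tests.
    """
    if needed <= 0:
        return 0
    ov = graph.k_assembly - 1
    best = 0
    queue: List[Tuple[OrientedNode, int, frozenset]] = [
        (anchor, 0, frozenset([anchor[0]]))
    ]
    visited_budget = node_budget
    while queue and visited_budget > 0:
        on, gained, seen = queue.pop()
        nbrs = (
            graph.out_neighbors(on) if forward else graph.in_neighbors(on)
        )
        for nb in nbrs:
            if nb[0] in seen:
                continue
            visited_budget -= 1
            gain = gained + len(graph.nodes[nb[0]].sequence) - ov
            if gain >= needed:
                return needed
            if gain > best:
                best = gain
            queue.append((nb, gain, seen | {nb[0]}))
    return best


def plan_tests(
    graph: SequenceGraph,
    site: RepeatSite,
    inn: OrientedNode,
    out: OrientedNode,
    library,
    k_rresolver: int,
    params: AlgorithmParams,
) -> TestPlan:
    """Compose the coverage estimate, test count and position check for one path."""
    steps = (inn, site.repeat, out)
    ka = graph.k_assembly
    l = library.read_length
    R_p = reads_on_path(graph, steps, l, ka)
    if R_p <= 0:
        return TestPlan(0, 0.0, R_p, Verdict.SKIP_LOW_COVERAGE)
    L = path_length(graph, steps)
    s = read_spacing(L, l, R_p)
    tests, verdict = required_tests(s, params)
    if verdict.is_skip:
        return TestPlan(tests, s, R_p, verdict)
    L_rep = len(graph.nodes[site.repeat[0]].sequence)
    ov = ka - 1
    avail_l = len(graph.nodes[inn[0]].sequence) - ov
    avail_r = len(graph.nodes[out[0]].sequence) - ov
    need = k_rresolver - L_rep - params.margin  # deepest useful flank reach
    ext_l = max_flank_extension(graph, inn, need - avail_l, forward=False)
    ext_r = max_flank_extension(graph, out, need - avail_r, forward=True)
    positions = window_position_count(
        avail_l + ext_l, L_rep, avail_r + ext_r, k_rresolver, params.margin
    )
    if positions < tests:
        return TestPlan(tests, s, R_p, Verdict.SKIP_TOO_FEW_POSITIONS, positions)
    return TestPlan(tests, s, R_p, Verdict.PROCEED, positions)
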