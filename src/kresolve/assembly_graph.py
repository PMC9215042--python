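"""Oriented unitig-graph model: nodes, mirrored edges, path spelling, chain merging.

The graph is double-stranded: every node has a forward (``+``) and reverse
(``-``) reading, and every edge ``u -> v`` implies its reverse-complement
mirror ``flip(v) -> flip(u)``.  One physical record is kept per node; the
mirror edge is materialised automatically so that traversal code never has
to special-case strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Set, Tuple

from .errors import PathError

# An oriented node is (node_id, orientation) with orientation "+" or "-".
OrientedNode = Tuple[str, str]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def flip(on: OrientedNode) -> OrientedNode:
    """The same node read on the opposite strand."""
    return (on[0], "-" if on[1] == "+" else "+")


@dataclass
class GraphNode:
    id: str
    sequence: str
    cov_sum: float = 0.0  # sum of multiplicities of the node's k_assembly k-mers


@dataclass(frozen=True)
class PathSpec:
    """An ordered walk through the graph; consecutive steps must share an edge."""

    steps: Tuple[OrientedNode, ...]

    def __len__(self) -> int:
        return len(self.steps)


class SequenceGraph:
    """Unitig graph with a fixed edge overlap of ``k_assembly - 1`` bases."""

    def __init__(self, k_assembly: int):
        if k_assembly < 2:
            raise ValueError("k_assembly must be >= 2")
        self.k_assembly = int(k_assembly)
        self.nodes: Dict[str, GraphNode] = {}
        self._out: Dict[OrientedNode, Set[OrientedNode]] = {}

    # -- construction -----------------------------------------------------

    def add_node(self, node_id: str, sequence: str, cov_sum: float = 0.0) -> GraphNode:
        if node_id in self.nodes:
            raise ValueError(f"duplicate node id {node_id!r}")
        node = GraphNode(node_id, sequence.upper(), cov_sum)
        self.nodes[node_id] = node
        return node

    def add_edge(self, source: OrientedNode, target: OrientedNode) -> None:
        """Add ``source -> target`` together with its strand mirror."""
        for on in (source, target):
            if on[0] not in self.nodes:
                raise PathError(f"edge endpoint {on} references a missing node")
        self._out.setdefault(source, set()).add(target)
        self._out.setdefault(flip(target), set()).add(flip(source))

    def remove_edge(self, source: OrientedNode, target: OrientedNode) -> None:
        self._out.get(source, set()).discard(target)
        self._out.get(flip(target), set()).discard(flip(source))

    def remove_node(self, node_id: str) -> None:
        """Delete a node and every edge incident to it (both strands)."""
        for orient in ("+", "-"):
            on = (node_id, orient)
            for tgt in list(self._out.get(on, ())):
                self.remove_edge(on, tgt)
            for src in list(self.in_neighbors(on)):
                self.remove_edge(src, on)
            self._out.pop(on, None)
        del self.nodes[node_id]

    # -- queries ----------------------------------------------------------

    def out_neighbors(self, on: OrientedNode) -> List[OrientedNode]:
        return sorted(self._out.get(on, ()))

    def in_neighbors(self, on: OrientedNode) -> List[OrientedNode]:
        # in-edges of v are the mirrors of out-edges of flip(v)
        return sorted(flip(w) for w in self._out.get(flip(on), ()))

    def has_edge(self, source: OrientedNode, target: OrientedNode) -> bool:
        return target in self._out.get(source, ())

    def edges(self) -> Iterator[Tuple[OrientedNode, OrientedNode]]:
        """All directed edges, mirrors included."""
        for src, tgts in self._out.items():
            for tgt in tgts:
                yield (src, tgt)

    def physical_edges(self) -> List[Tuple[OrientedNode, OrientedNode]]:
        """One canonical representative per edge/mirror pair, sorted."""
        seen = set()
        out = []
        for e in self.edges():
            mirror = (flip(e[1]), flip(e[0]))
            rep = min(e, mirror)
            if rep not in seen:
                seen.add(rep)
                out.append(rep)
        return sorted(out)

    def oriented_sequence(self, on: OrientedNode) -> str:
        seq = self.nodes[on[0]].sequence
        return seq if on[1] == "+" else revcomp(seq)

    def node_ids(self) -> List[str]:
        return sorted(self.nodes)

    def total_cov_sum(self) -> float:
        return sum(n.cov_sum for n in self.nodes.values())

    def copy(self) -> "SequenceGraph":
        g = SequenceGraph(self.k_assembly)
        for nid in self.nodes:
            n = self.nodes[nid]
            g.add_node(n.id, n.sequence, n.cov_sum)
        g._out = {on: set(tgts) for on, tgts in self._out.items()}
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SequenceGraph):
            return NotImplemented
        return (
            self.k_assembly == other.k_assembly
            and {i: (n.sequence, n.cov_sum) for i, n in self.nodes.items()}
            == {i: (n.sequence, n.cov_sum) for i, n in other.nodes.items()}
            and {on: s for on, s in self._out.items() if s}
            == {on: s for on, s in other._out.items() if s}
        )


def spell_path(graph: SequenceGraph, path: PathSpec | Iterable[OrientedNode]) -> str:
    """Concatenate oriented node sequences, trimming the (k-1)-base overlaps."""
    steps = tuple(path.steps if isinstance(path, PathSpec) else path)
    if not steps:
        return ""
    ov = graph.k_assembly - 1
    pieces = [graph.oriented_sequence(steps[0])]
    for prev, cur in zip(steps, steps[1:]):
        if not graph.has_edge(prev, cur):
            raise PathError(f"no edge {prev} -> {cur}")
        pieces.append(graph.oriented_sequence(cur)[ov:])
    return "".join(pieces)


def path_length(graph: SequenceGraph, steps: Iterable[OrientedNode]) -> int:
    steps = tuple(steps)
    ov = graph.k_assembly - 1
    return sum(len(graph.nodes[s[0]].sequence) for s in steps) - (len(steps) - 1) * ov


def _unique_successor(graph: SequenceGraph, on: OrientedNode) -> OrientedNode | None:
    """Successor v of u such that the link u->v is safely mergeable."""
    outs = graph.out_neighbors(on)
    if len(outs) != 1:
        return None
    v = outs[0]
    if v[0] == on[0]:  # self-loop / hairpin: never merged
        return None
    if len(graph.in_neighbors(v)) != 1:
        return None
    return v


def merge_unambiguous_paths(graph: SequenceGraph) -> Tuple[SequenceGraph, int]:
    """Compact every maximal chain of nodes with unique in/out links.

    Returns the mutated graph and the number of chains merged.  Merged nodes
    get the chain's spelled sequence and the sum of member ``cov_sum``.
    Idempotent: a second invocation merges nothing.
    """
    handled: Set[str] = set()
    merges = 0
    for nid in sorted(graph.nodes):
        if nid not in graph.nodes or nid in handled:
            continue
        start: OrientedNode = (nid, "+")
        seen = {nid}
        while True:
            ins = graph.in_neighbors(start)
            if len(ins) != 1:
                break
            pred = ins[0]
            if pred[0] in seen or _unique_successor(graph, pred) != start:
                break
            start = pred
            seen.add(pred[0])
        chain: List[OrientedNode] = [start]
        chain_ids = {start[0]}
        cur = start
        while True:
            nxt = _unique_successor(graph, cur)
            if nxt is None or nxt[0] in chain_ids:
                break
            chain.append(nxt)
            chain_ids.add(nxt[0])
            cur = nxt
        handled |= chain_ids
        if len(chain) == 1:
            continue

        seq = spell_path(graph, chain)
        cov = sum(graph.nodes[c[0]].cov_sum for c in chain)
        new_id = "_".join(c[0] for c in chain)
        while new_id in graph.nodes:
            new_id += "m"
        first, last = chain[0], chain[-1]

        def _map_in(on: OrientedNode) -> OrientedNode:
            if on[0] not in chain_ids:
                return on
            if on == last:
                return (new_id, "+")
            if on == flip(first):
                return (new_id, "-")
            raise PathError(f"non-linear chain neighbour {on}")

        def _map_out(on: OrientedNode) -> OrientedNode:
            if on[0] not in chain_ids:
                return on
            if on == first:
                return (new_id, "+")
            if on == flip(last):
                return (new_id, "-")
            raise PathError(f"non-linear chain neighbour {on}")

        ext_in = [p for p in graph.in_neighbors(first)]
        ext_out = [s for s in graph.out_neighbors(last)]
        for cid in chain_ids:
            graph.remove_node(cid)
        graph.add_node(new_id, seq, cov)
        for p in ext_in:
            graph.add_edge(_map_in(p), (new_id, "+"))
        for s in ext_out:
            graph.add_edge((new_id, "+"), _map_out(s))
        merges += 1
    return graph, merges


def validate_graph(graph: SequenceGraph) -> List[str]:
    """Return a description of every violated structural invariant."""
    violations: List[str] = []
    ov = graph.k_assembly - 1
    for nid, node in sorted(graph.nodes.items()):
        if len(node.sequence) < graph.k_assembly:
            violations.append(f"node {nid}: sequence shorter than k_assembly")
        if node.cov_sum < 0:
            violations.append(f"node {nid}: negative cov_sum")
    for src, tgt in sorted(graph.edges()):
        for on in (src, tgt):
            if on[0] not in graph.nodes:
                violations.append(f"edge {src}->{tgt}: dangling endpoint {on}")
                break
        else:
            s = graph.oriented_sequence(src)
            t = graph.oriented_sequence(tgt)
            if s[-ov:] != t[:ov]:
                violations.append(f"edge {src}->{tgt}: overlap mismatch")
            if not graph.has_edge(flip(tgt), flip(src)):
                violations.append(f"edge {src}->{tgt}: missing mirror edge")
    return violations
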