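"""FASTA/FASTQ read input and GFA1 unitig-graph input/output.

GFA dialect: GFA1 with ``S`` lines carrying the segment sequence and a
``KC:i`` k-mer multiplicity sum, and ``L`` lines whose CIGAR is the fixed
``(k_assembly - 1)M`` overlap.  Qualities in FASTQ are ignored.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, List, Sequence, Tuple

from Bio import SeqIO

from .assembly_graph import SequenceGraph
from .errors import GraphFormatError, ParseError

_ACGT = set("ACGT")


@dataclass
class ReadLibrary:
    """All input reads of one exact length."""

    read_length: int
    reads: List[str] = field(default_factory=list)
    source_names: List[str] = field(default_factory=list)

    def __post_init__(self):
        for r in self.reads:
            if len(r) != self.read_length:
                raise ValueError(
                    f"read of length {len(r)} in a {self.read_length} bp library"
                )

    def __len__(self) -> int:
        return len(self.reads)


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_sequences(
    paths: Sequence, fmt: str
) -> Iterator[Tuple[str, str]]:
    """Yield ``(identifier, uppercase sequence)`` records in file order."""
    if fmt not in ("fasta", "fastq"):
        raise ParseError(f"unsupported format {fmt!r}")
    for path in paths:
        with _open_text(path) as handle:
            i = 0
            try:
                for i, rec in enumerate(SeqIO.parse(handle, fmt), 1):
                    yield rec.id, str(rec.seq).upper()
            except ValueError as exc:
                raise ParseError(f"{path}: record {i + 1}: {exc}") from exc


@dataclass
class GroupResult:
    libraries: List[ReadLibrary]
    n_dropped: int
    n_input: int


def group_reads_by_length(
    records: Iterable[Tuple[str, str]], source_names: Sequence[str] = ()
) -> GroupResult:
    """Partition records into one ReadLibrary per length, shortest first.

    Reads containing any non-ACGT symbol are dropped (and counted) rather
    than split: only the first few k-mers of each read are ever used, so
    salvaging partial reads is not worth the complexity.
    """
    by_len: dict[int, List[str]] = {}
    dropped = 0
    total = 0
    for _ident, seq in records:
        total += 1
        if not set(seq) <= _ACGT:
            dropped += 1
            continue
        by_len.setdefault(len(seq), []).append(seq)
    libs = [
        ReadLibrary(length, reads, list(source_names))
        for length, reads in sorted(by_len.items())
    ]
    return GroupResult(libs, dropped, total)


def _parse_tags(fields: Sequence[str]) -> dict:
    tags = {}
    for f in fields:
        parts = f.split(":", 2)
        if len(parts) == 3:
            tags[parts[0]] = (parts[1], parts[2])
    return tags


def load_graph_gfa(path, k_assembly: int) -> SequenceGraph:
    """Load a GFA1 unitig graph, enforcing the fixed (k-1)M link overlap."""
    graph = SequenceGraph(k_assembly)
    ov = k_assembly - 1
    links = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line[0] in ("#", "H", "C", "P"):
                continue
            fields = line.split("\t")
            if fields[0] == "S":
                if len(fields) < 3:
                    raise GraphFormatError(f"{path}:{lineno}: short S line")
                name, seq = fields[1], fields[2].upper()
                tags = _parse_tags(fields[3:])
                if "KC" in tags:
                    cov = float(int(tags["KC"][1]))
                else:
                    cov = 0.0
                graph.add_node(name, seq, cov)
            elif fields[0] == "L":
                if len(fields) < 6:
                    raise GraphFormatError(f"{path}:{lineno}: short L line")
                links.append((lineno, fields[1], fields[2], fields[3], fields[4], fields[5]))
    for lineno, src, so, tgt, to, cigar in links:
        if cigar != f"{ov}M":
            raise GraphFormatError(
                f"{path}:{lineno}: link overlap {cigar!r} != {ov}M "
                f"(k_assembly={k_assembly})"
            )
        for name in (src, tgt):
            if name not in graph.nodes:
                raise GraphFormatError(
                    f"{path}:{lineno}: link references missing segment {name!r}"
                )
        graph.add_edge((src, so), (tgt, to))
    return graph


def write_graph_gfa(graph: SequenceGraph, path) -> None:
    """Write GFA1; round-trips losslessly through :func:`load_graph_gfa`."""
    ov = graph.k_assembly - 1
    with open(path, "wt") as out:
        out.write("H\tVN:Z:1.0\n")
        for nid in graph.node_ids():
            node = graph.nodes[nid]
            out.write(f"S\t{nid}\t{node.sequence}\tKC:i:{int(round(node.cov_sum))}\n")
        for (src, so), (tgt, to) in graph.physical_edges():
            out.write(f"L\t{src}\t{so}\t{tgt}\t{to}\t{ov}M\n")


def write_contigs_fasta(graph: SequenceGraph, path) -> None:
    """One record per node, id-sorted for determinism."""
    with open(path, "wt") as out:
        for nid in graph.node_ids():
            seq = graph.nodes[nid].sequence
            out.write(f">{nid}\n")
            for i in range(0, len(seq), 80):
                out.write(seq[i : i + 80] + "\n")
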