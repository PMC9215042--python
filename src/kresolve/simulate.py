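"""Synthetic fixtures: repeat-bearing genomes, short reads, a unitig DBG
builder standing in for the upstream assembler stage, and truth-based scoring.

Genomes alternate unique segments with interspersed repeat copies
(``U0 R U1 R U2 ...``).  Unique segments are rejection-sampled so that no
k-mer (canonically) occurs twice outside the planted repeats, which makes
the truth table exact.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .assembly_graph import SequenceGraph, revcomp, validate_graph
from .errors import GenerationError
from .kmer_bloom import canonical
from .seq_io import ReadLibrary


@dataclass
class SyntheticGenomeSpec:
    unique_segment_length: int = 5000
    repeat_length: int = 80
    repeat_copies: int = 2
    n_repeats: int = 1  # distinct repeat families
    gc: float = 0.5
    seed: int = 0
    kmer_disjoint_k: int = 51  # k at which unique segments must not collide


@dataclass
class ReadSimSpec:
    read_length: int = 151
    fold_coverage: float = 40.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.fold_coverage <= 0:
            raise ValueError("fold_coverage must be positive")
        if not 0 <= self.error_rate < 0.05:
            raise ValueError("error_rate must be in [0, 0.05)")


@dataclass
class TruthTable:
    genome: str
    # (start, end, family index, copy index) for every planted repeat copy
    repeat_intervals: List[Tuple[int, int, int, int]] = field(default_factory=list)
    # (left unique-segment index, right unique-segment index, family) per copy
    junctions: List[Tuple[int, int, int]] = field(default_factory=list)


def _random_seq(rng: random.Random, length: int, gc: float) -> str:
    out = []
    for _ in range(length):
        if rng.random() < gc:
            out.append("G" if rng.random() < 0.5 else "C")
        else:
            out.append("A" if rng.random() < 0.5 else "T")
    return "".join(out)


def _kmer_set(seq: str, k: int) -> set:
    return {canonical(seq[i : i + k]) for i in range(len(seq) - k + 1)}


def _sample_disjoint(
    rng: random.Random, length: int, gc: float, k: int, forbidden: set, tries: int = 50
) -> Tuple[str, set]:
    """A random segment whose canonical k-mers are all new and internally unique."""
    for _ in range(tries):
        seq = _random_seq(rng, length, gc)
        kmers = _kmer_set(seq, k)
        if len(kmers) == length - k + 1 and not (kmers & forbidden):
            return seq, kmers
    raise GenerationError(
        f"could not sample a {length} bp segment k-mer-disjoint at k={k}; "
        "try longer segments or a different seed"
    )


def make_repeat_genome(spec: SyntheticGenomeSpec) -> Tuple[str, TruthTable]:
    """Build ``U0 R U1 R U2 ...`` with families cycling through the slots."""
    rng = random.Random(spec.seed)
    k = spec.kmer_disjoint_k
    forbidden: set = set()
    repeats: List[str] = []
    for _ in range(spec.n_repeats):
        rep, kmers = _sample_disjoint(rng, spec.repeat_length, spec.gc, k, forbidden)
        repeats.append(rep)
        forbidden |= kmers
    n_slots = spec.n_repeats * spec.repeat_copies
    uniques: List[str] = []
    for _ in range(n_slots + 1):
        seg, kmers = _sample_disjoint(
            rng, spec.unique_segment_length, spec.gc, k, forbidden
        )
        uniques.append(seg)
        forbidden |= kmers

    pieces = [uniques[0]]
    truth = TruthTable(genome="")
    copies_seen = [0] * spec.n_repeats
    pos = len(uniques[0])
    for slot in range(n_slots):
        fam = slot % spec.n_repeats
        rep = repeats[fam]
        truth.repeat_intervals.append((pos, pos + len(rep), fam, copies_seen[fam]))
        truth.junctions.append((slot, slot + 1, fam))
        copies_seen[fam] += 1
        pieces.append(rep)
        pos += len(rep)
        pieces.append(uniques[slot + 1])
        pos += len(uniques[slot + 1])
    truth.genome = "".join(pieces)
    return truth.genome, truth


def simulate_reads(genome: str, spec: ReadSimSpec) -> ReadLibrary:
    """Uniform single-end sampling from both strands at the requested fold."""
    l = spec.read_length
    if l > len(genome):
        raise ValueError("read length exceeds genome length")
    rng = random.Random(spec.seed)
    n_reads = math.ceil(spec.fold_coverage * len(genome) / l)
    reads = []
    bases = "ACGT"
    for _ in range(n_reads):
        start = rng.randrange(len(genome) - l + 1)
        read = genome[start : start + l]
        if rng.random() < 0.5:
            read = revcomp(read)
        if spec.error_rate > 0:
            chars = list(read)
            for i in range(l):
                if rng.random() < spec.error_rate:
                    chars[i] = rng.choice([b for b in bases if b != chars[i]])
            read = "".join(chars)
        reads.append(read)
    return ReadLibrary(l, reads, ["simulated"])


def count_kmers(reads, k: int) -> Dict[str, int]:
    """Canonical k-mer multiplicities across a read collection."""
    counts: Dict[str, int] = {}
    acgt = set("ACGT")
    for read in reads:
        if not set(read) <= acgt:
            continue
        rc = revcomp(read)
        n = len(read)
        for i in range(n - k + 1):
            fwd = read[i : i + k]
            rev = rc[n - k - i : n - i]
            km = fwd if fwd <= rev else rev
            counts[km] = counts.get(km, 0) + 1
    return counts


def _succs(present: Dict[str, int], w: str) -> List[str]:
    body = w[1:]
    return [body + b for b in "ACGT" if canonical(body + b) in present]


def _preds(present: Dict[str, int], w: str) -> List[str]:
    body = w[:-1]
    return [b + body for b in "ACGT" if canonical(b + body) in present]


def build_unitig_graph(
    reads: ReadLibrary | List[str], k_assembly: int, kc_min: int = 1
) -> SequenceGraph:
    """Count k-mers, filter by multiplicity, compact the DBG into unitigs.

    ``cov_sum`` of each unitig is the sum of its member k-mer multiplicities,
    matching the KC convention of unitig-graph GFA.
    """
    seqs = reads.reads if isinstance(reads, ReadLibrary) else reads
    if isinstance(reads, ReadLibrary) and k_assembly >= reads.read_length:
        raise ValueError("k_assembly must be smaller than the read length")
    counts = count_kmers(seqs, k_assembly)
    if kc_min > 1:
        counts = {km: c for km, c in counts.items() if c >= kc_min}
    if not counts:
        raise GenerationError("no k-mers left after the multiplicity filter")

    def is_start(w: str) -> bool:
        ps = _preds(counts, w)
        if len(ps) != 1:
            return True
        p = ps[0]
        return len(_succs(counts, p)) != 1 or canonical(p) == canonical(w)

    visited: set = set()
    unitigs: List[Tuple[str, str, str, int]] = []  # (spelled, first, last, cov)

    def walk(start: str) -> None:
        chain = [start]
        visited.add(canonical(start))
        cov = counts[canonical(start)]
        cur = start
        while True:
            ss = _succs(counts, cur)
            if len(ss) != 1:
                break
            nxt = ss[0]
            if len(_preds(counts, nxt)) != 1:
                break
            cn = canonical(nxt)
            if cn in visited:
                break
            chain.append(nxt)
            visited.add(cn)
            cov += counts[cn]
            cur = nxt
        spelled = chain[0] + "".join(c[-1] for c in chain[1:])
        unitigs.append((spelled, chain[0], chain[-1], cov))

    for km in sorted(counts):
        if km in visited:
            continue
        for w in (km, revcomp(km)):
            if is_start(w):
                walk(w)
                break
    for km in sorted(counts):  # leftover pure cycles
        if km not in visited:
            walk(km)

    graph = SequenceGraph(k_assembly)
    terminal: Dict[str, List[Tuple[str, str, str]]] = {}
    for idx, (spelled, first, last, cov) in enumerate(unitigs):
        uid = f"u{idx}"
        graph.add_node(uid, spelled, float(cov))
        for km in {canonical(first), canonical(last)}:
            terminal.setdefault(km, []).append((uid, first, last))

    def resolve(y: str) -> List[Tuple[str, str]]:
        hits = []
        for uid, first, last in terminal.get(canonical(y), ()):
            if y == first:
                hits.append((uid, "+"))
            if y == revcomp(last):
                hits.append((uid, "-"))
        return hits

    for idx, (spelled, first, last, cov) in enumerate(unitigs):
        uid = f"u{idx}"
        for y in _succs(counts, last):
            for tgt in resolve(y):
                graph.add_edge((uid, "+"), tgt)
        for y in _succs(counts, revcomp(first)):
            for tgt in resolve(y):
                graph.add_edge((uid, "-"), tgt)
    return graph


@dataclass
class ResolutionScore:
    contig_count: int
    largest_fraction: float
    chimeric_junctions: int
    resolved_repeats: int
    total_repeats: int


def score_resolution(
    graph: SequenceGraph, truth: TruthTable, k_assembly: int
) -> ResolutionScore:
    """Desk-scale truth scoring: chimeric 2k-windows and resolved junctions."""
    genome = truth.genome
    w = 2 * k_assembly
    genome_windows = {canonical(genome[i : i + w]) for i in range(len(genome) - w + 1)}
    chimeras = 0
    contigs = [graph.nodes[nid].sequence for nid in graph.node_ids()]
    for contig in contigs:
        for i in range(max(0, len(contig) - w + 1)):
            if canonical(contig[i : i + w]) not in genome_windows:
                chimeras += 1
    resolved = 0
    for start, end, _fam, _copy in truth.repeat_intervals:
        lo = max(0, start - k_assembly)
        hi = min(len(genome), end + k_assembly)
        junction = genome[lo:hi]
        if any(junction in c or revcomp(junction) in c for c in contigs):
            resolved += 1
    largest = max((len(c) for c in contigs), default=0)
    return ResolutionScore(
        contig_count=len(contigs),
        largest_fraction=largest / len(genome) if genome else 0.0,
        chimeric_junctions=chimeras,
        resolved_repeats=resolved,
        total_repeats=len(truth.repeat_intervals),
    )


def write_truth_files(truth: TruthTable, prefix: str) -> None:
    """BED-like repeat intervals and a junction TSV next to the fixture."""
    with open(f"{prefix}.repeats.bed", "wt") as out:
        for start, end, fam, copy in truth.repeat_intervals:
            out.write(f"genome\t{start}\t{end}\trepeat{fam}.{copy}\n")
    with open(f"{prefix}.junctions.tsv", "wt") as out:
        out.write("left_unique\tright_unique\tfamily\n")
        for left, right, fam in truth.junctions:
            out.write(f"U{left}\tU{right}\t{fam}\n")
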